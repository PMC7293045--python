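# bremsc

Joint model-based clustering of paired single-cell transcriptomic and
surface-protein count data.

CITE-seq profiles each cell twice: RNA abundance as UMI counts over genes,
and surface-protein abundance as ADT (antibody-derived tag) counts over a
small marker panel. The two measurements carry complementary information
about cell identity, but clustering each source separately wastes power and
ignores their correlation. This package clusters both matrices at once with
a Bayesian random-effects mixture of Dirichlet-multinomials, for analysts
who want probabilistic cluster assignments (with per-cell uncertainty)
rather than hard partitions.

## Model

Cell *j* with cluster label *z_j = k* has counts

- x_j⁽¹⁾ | p_j⁽¹⁾ ~ Multinomial(T_j⁽¹⁾, p_j⁽¹⁾), p_j⁽¹⁾ ~ Dir(α_(k)⁽¹⁾ · b_j)  (RNA, G genes)
- x_j⁽²⁾ | p_j⁽²⁾ ~ Multinomial(T_j⁽²⁾, p_j⁽²⁾), p_j⁽²⁾ ~ Dir(α_(k)⁽²⁾ · b_j)  (ADT, D markers)
- b_j ~ LogNormal(0, σ_b²)

Integrating the proportions out gives Dirichlet-multinomial densities; the
cell-specific multiplier b_j rescales both clusters' Dirichlet blocks and so
couples the two sources (larger b_j means tighter, more multinomial-like
counts in both). Inference is Metropolis-within-Gibbs MCMC: exact Gibbs
draws for the labels, multiplicative log-normal random-walk Metropolis
steps for the α blocks and b, and a conjugate inverse-gamma draw for σ_b².
Several chains run from distinct K-means + Ronning moment initialisations
and the chain with the highest recorded log-posterior is summarised into a
C×K matrix of posterior cluster probabilities ("soft clustering"); the
least confident cells can be flagged as *vague*.

Also included:

- **jointDIMM-SC**: the independence variant (no random effects) fitted by
  EM — much faster, appropriate when among-cell variability is low, and the
  likelihood used for AIC/BIC selection of the number of clusters K.
- **Simulators**: the model's own generative process (with ground-truth
  labels, random effects and α blocks) and a gamma-Poisson
  misspecification generator with controllable differential-expression
  probability.
- **Metrics**: adjusted Rand index and adjusted mutual information,
  implemented from their definitions.
- **I/O + CLI**: 10x-style Matrix Market triplet directories (with
  "Gene Expression" / "Antibody Capture" splitting) and dense CSV.

## Worked example

```python
import numpy as np
from bremsc import (MCMCConfig, adjusted_rand_index, adjusted_mutual_information,
                    run_bremsc, flag_vague_cells, scenario_config, simulate_bremsc)

config = scenario_config(K=3, cells_per_cluster=100, sigma_b=0.5, seed=1)
data, truth = simulate_bremsc(config)
result = run_bremsc(data, K=3, config=MCMCConfig(n_iter=500, n_chains=3, seed=1))

ari = adjusted_rand_index(result.labels, truth.z_true)
ami = adjusted_mutual_information(result.labels, truth.z_true)
burn = result.diagnostics["n_burn"]
sigma_b = np.mean(np.sqrt(result.diagnostics["sigma_b2_samples"][burn:]))
vague = flag_vague_cells(result, 0.05)

print(f"cells: {data.n_cells}, genes: {data.n_genes}, markers: {data.n_markers}")
print(f"selected chain: {result.selected_chain}")
print(f"ARI vs truth: {ari:.3f}   AMI vs truth: {ami:.3f}")
print(f"posterior mean sigma_b: {sigma_b:.3f} (generating value 0.5)")
print(f"vague cells flagged: {vague.sum()} of {data.n_cells}")
```

Output:

```
cells: 300, genes: 60, markers: 10
selected chain: 1
ARI vs truth: 1.000   AMI vs truth: 1.000
posterior mean sigma_b: 0.507 (generating value 0.5)
vague cells flagged: 15 of 300
```

ARI/AMI of 1.0 mean the recovered partition is identical to the generating
one; the posterior mean of σ_b sits within 2% of the value used to
generate the data; and with every assignment near-certain the 5% vague-cell
flag reduces to its guaranteed count of ⌊0.05·300⌋ = 15 cells.

The same pipeline from a shell:

```sh
bremsc simulate --preset both_strong --seed 1 --out sim/
bremsc cluster --rna sim/rna_counts.csv --adt sim/adt_counts.csv \
       --k 3 --chains 3 --iters 500 --seed 1 --out run/
bremsc evaluate --truth sim/truth.csv --pred run/labels.csv
bremsc select-k --rna sim/rna_counts.csv --adt sim/adt_counts.csv \
       --k-grid 2,3,4,5 --out ksel.csv
```

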