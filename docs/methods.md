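# Methods

## Model

Both data sources are compositional counts: cell *j* contributes a UMI
vector x_j⁽¹⁾ over G genes with total T_j⁽¹⁾ and an ADT vector x_j⁽²⁾ over
D markers with total T_j⁽²⁾. Within cluster k each source follows a
Dirichlet-multinomial (DM): a multinomial whose proportion vector is drawn
from Dir(α_(k)), which captures the overdispersion of droplet counts that
a plain multinomial misses. The log-density used everywhere is

    log P(x | α) = log[T!/∏ x_i!] + Σ_i [lnΓ(x_i+α_i) − lnΓ(α_i)]
                 + lnΓ(|α|) − lnΓ(T+|α|).

The multinomial coefficient is included, so `dm_logpmf` is a true log-pmf
(exactly normalised — this is what makes enumeration and closed-form
oracle tests possible); it is constant in all parameters and therefore
irrelevant to inference.

Cross-source correlation enters through a cell-specific random effect
b_j ~ LogNormal(0, σ_b²) that multiplies **both** cluster blocks:
α_j(k)⁽ˢ⁾ = α_(k)⁽ˢ⁾ · b_j. Because a Dirichlet's mean depends only on the
normalised parameters, b_j moves the *precision* of cell j's proportions
in both sources jointly — a cell that is noisy in RNA tends to be noisy in
ADT — without moving cluster means. The complete-data log-posterior is the
sum of the per-cell DM terms at the scaled parameters plus, per cell,
−ln b_j − (ln b_j)²/(2σ_b²) − ½ ln σ_b².

Two deliberate modelling choices where the objective itself is silent:

- **Uniform prior over labels.** The complete-data objective carries no
  mixing-proportion term, so the Gibbs full conditional of z_j is the
  softmax of the per-cluster DM log-densities. The EM variant (below)
  *does* carry mixing proportions π, the standard mixture formulation for
  a maximised likelihood; the asymmetry is intentional and documented.
- **No identifiability constraint on (α, b).** Scaling all α rows by c and
  all b by 1/c changes only the prior term; the LogNormal(0, σ_b²) prior
  anchors the geometric mean of b near 1 and that soft anchoring is relied
  upon rather than a hard constraint.

## Sampler

Each sweep, in fixed order for reproducibility:

1. **z** — exact Gibbs draw per cell (cells are conditionally independent
   given α, b, so the vectorised joint draw equals a sweep).
2. **α⁽¹⁾, α⁽²⁾** — per cluster row, a multiplicative random-walk proposal
   α′ = α·exp(ε), ε ~ N(0, step²) element-wise, accepted with
   min(1, exp(Δ + Σ ln(α′/α))) where Δ is the log-posterior change (only
   cells currently in that cluster contribute). The log-normal proposal
   keeps parameters strictly positive; the Jacobian term corrects its
   asymmetry. Rows of currently-empty clusters are frozen — their
   conditional is flat and an unfrozen row would drift on the asymmetry
   term alone.
3. **b** — the same multiplicative proposal per cell, all cells in
   parallel (their conditionals are independent). A test exploits the
   zero-count limit, where the exact stationary law of b_j is its
   log-normal prior, to verify the asymmetry correction.
4. **σ_b²** — conjugate draw from InvGamma(a₀ + C/2, b₀ + Σ(ln b_j)²/2),
   a₀ = b₀ = 0.01 (weak); a fixed-σ_b² mode exists for ablations.

Step sizes adapt only during burn-in (Robbins–Monro on the acceptance
indicator, target 0.30, gain t^−0.6 capped at 0.5; per α row, scalar for
b), then freeze, so the retained chain is time-homogeneous. Defaults:
500 sweeps, 3 chains, 50% burn-in, initial steps 0.08 (α) and 0.15 (b);
post-burn-in acceptance on simulated data lands in the 0.15–0.50 band.

Chains are initialised independently: per-source K-means on
log1p(counts-per-10k) columns, ADT labels matched to RNA labels by
Hungarian assignment on the contingency table (ADT, the lower-dimensional
and typically more type-discriminative source, supplies the merged
labels), then Ronning-style moment estimation of each cluster's α — mean
proportions times a precision from the first coordinate's moment identity
ŝ = p̄₁(1−p̄₁)/var(p₁) − 1, falling back to 1/min positive p̄ when the
variance is degenerate, floored at 1e-6. The chain with the largest
recorded log-posterior is kept; its post-burn-in label frequencies form
the C×K posterior matrix. No within-chain relabelling is attempted: with
informative data and K-means starts, label switching within a chain is
rare, and only one chain is summarised so cross-chain alignment is moot.
Soft-clustering output: `flag_vague_cells` marks the ⌊fraction·C⌋ cells
with the smallest row-maximum posterior probability (ties by cell index).

## EM variant (jointDIMM-SC)

Dropping the random effects and assuming source independence gives a
K-component DM mixture with proportions π, fitted by EM. The E-step is the
log-space softmax of log π_k plus the two DM log-densities; the M-step
sets π to mean responsibilities and maximises each row's weighted DM
likelihood by the Minka fixed point

    α_i ← α_i · Σ_j w_j[ψ(x_ij+α_i) − ψ(α_i)] / Σ_j w_j[ψ(T_j+|α|) − ψ(|α|)],

warm-started from the current value (≤100 inner steps, rtol 1e-8 per
outer iteration). The update is undamped: it is an MM step with a
monotonicity guarantee that log-space damping would forfeit; the
observed-data log-likelihood is asserted non-decreasing in tests.
Convergence: relative log-likelihood change < 1e-6 (≤200 outer
iterations). Model selection fits this variant per K and evaluates
AIC = −2ℓ̂ + 2ν and BIC = −2ℓ̂ + ν ln C with ν = K(G+D) + (K−1) free
parameters; EM supplies a maximised observed-data likelihood, the quantity
the criteria formally require, at a fraction of the sampler's cost.

## Simulators

`simulate_bremsc` draws from the model's own process (b_j, then Dirichlet
proportions at α_(k)·b_j, then multinomial counts at truncated-normal
library sizes; column sums equal the drawn totals exactly). Study
conditions are block-structured α matrices: a shared baseline (1.0 per
gene, 5.0 per marker) with each cluster's contiguous feature block boosted
by 10× ("strong" signal) or 2× ("weak"). Library sizes: RNA
(mean 2500, sd 800, lower 500), ADT (5000, 1500, 100), rounded and floored
— synthetic stand-ins chosen once to resemble typical droplet data, not
estimates from any real data set. Preset scenarios vary one axis at a
time around the base condition (K=3, 100 cells/cluster, G=60, D=10,
both strong, σ_b=0.5): σ_b ∈ {0, 0.5, 1, 2}, the four strong/weak signal
combinations, 50/100/200 cells per cluster, K ∈ {3, 5, 8}.

`simulate_misspecified` probes robustness under a process the model does
not match: log-normal baseline feature means, a `de_prob` fraction of
features per cluster multiplied or divided by `de_fold`, gamma-Poisson
counts (NB size `dispersion`; ∞ = Poisson) rescaled to truncated-normal
library sizes, ADT generated identically at larger totals. No Dirichlet
ground truth exists under this process, so its `SimTruth.params_true` is
None.

What the generators do **not** emulate: dropout/zero inflation beyond what
DM or gamma-Poisson produce, batch effects, doublets, ambient
contamination, or the mean–variance structure of real gene panels. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated processes, not performance on real tissue.

## Numerical choices

- All densities in log space via `gammaln`/`betaln`; cluster weights and
  responsibilities normalised by max-subtraction before exponentiation
  (totals in the thousands overflow Γ otherwise).
- Acceptance uses log(1−u) ≤ Δ so a zero-step proposal (Δ = 0 exactly) is
  always accepted and the parameter provably unchanged.
- Ties: hard labels are the posterior row argmax with lowest index
  winning; vague-cell ranking and HVG selection break ties by index
  (stable sorts), making every output deterministic given the seed.
- Seeds: one root `SeedSequence` per run spawns independent
  initialisation and chain streams, so results are bit-reproducible and
  chains are statistically independent.
- Degenerate inputs: empty clusters freeze their α rows (sampler) or are
  skipped with a warning (EM, responsibility mass < 1e-8); zero-total
  cells get uniform proportions in the moment estimator; ARI/AMI return 1
  when both partitions are trivial (they then coincide) and 0 when only
  one is.

## Test problem sizes

Heavier checks run at deliberately modest sizes chosen as this package's
desk-scale study conditions: label/parameter recovery at the base
condition over five seeds (3 chains × 500 sweeps); σ_b recovery at C=300;
the σ_b = 2 vs 0 accuracy ordering and the sampler-vs-EM comparison at
30–60 cells/cluster with single shorter chains. The full suite runs in a
few minutes on one CPU.

## Known limitations

- MCMC cost is linear in cells × features per sweep; the package targets
  panel-sized inputs (use `filter_hvg` to reduce G first). No GPU path.
- Measurement error, dropout and PCR effects are not modelled; counts are
  taken at face value.
- The number of clusters is user-supplied or chosen by AIC/BIC on the EM
  surrogate; no nonparametric K.
- Posterior summaries come from a single selected chain; across-chain
  pooling would require relabelling machinery that is out of scope.
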