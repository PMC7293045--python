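"""Metropolis-within-Gibbs sampler for the random-effects mixture model.

Each sweep updates, in fixed order: the cluster labels z (exact Gibbs
draw from their full conditionals), the cluster-level Dirichlet blocks
for each source and the cell random effects b (multiplicative log-normal
random-walk Metropolis steps, which preserve positivity; the proposal
asymmetry is corrected in the acceptance ratio), and finally the
random-effect variance sigma_b2 (a conjugate inverse-gamma draw, or held
fixed). Step sizes adapt toward a 0.30 acceptance rate during burn-in
only, so the post-burn-in chain is a valid time-homogeneous sampler.
Several chains are run from distinct K-means initialisations and the one
with the largest recorded log-posterior is summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    cluster_logweights_all,
    complete_log_posterior,
    dm_logpmf_rows,
    softmax_rows,
)
from .datatypes import ModelParams, PairedCounts
from .initialization import initial_params

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "ChainTrace",
    "ClusterResult",
    "gibbs_update_z",
    "mh_update_alpha",
    "mh_update_b",
    "update_sigma_b2",
    "alpha_proposal_logratio",
    "b_proposal_logratio",
    "run_chain",
    "run_bremsc",
    "flag_vague_cells",
]

# weak hyperparameters of the conjugate inverse-gamma update for sigma_b2
SIGMA_B2_PRIOR_SHAPE = 0.01
SIGMA_B2_PRIOR_RATE = 0.01
_ACCEPT_TARGET = 0.30


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the recommended 3 chains of 500 sweeps."""

    n_iter: int = 500
    n_chains: int = 3
    burn_in_fraction: float = 0.5
    rw_step_alpha: float = 0.08
    rw_step_b: float = 0.15
    adapt: bool = True
    seed: int = 0
    sigma_b2_mode: str = "sample"  # "sample" or "fixed"
    sigma_b2_fixed: float = 1.0
    sigma_b2_init: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in (0, 1)")
        if self.n_iter - int(self.n_iter * self.burn_in_fraction) < 1:
            raise ValueError("burn-in must leave at least one retained sweep")
        if self.rw_step_alpha < 0 or self.rw_step_b < 0:
            raise ValueError("random-walk step sizes must be non-negative")
        if self.sigma_b2_mode not in ("sample", "fixed"):
            raise ValueError("sigma_b2_mode must be 'sample' or 'fixed'")
        if self.sigma_b2_fixed <= 0 or self.sigma_b2_init <= 0:
            raise ValueError("sigma_b2 values must be positive")

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_fraction)


@dataclass
class ChainTrace:
    """Per-iteration record of one MCMC chain."""

    z_samples: np.ndarray  # n_iter x C
    log_post: np.ndarray  # n_iter
    sigma_b2_samples: np.ndarray  # n_iter
    accept_alpha_rna: float
    accept_alpha_adt: float
    accept_b: float
    final_params: ModelParams


@dataclass
class ClusterResult:
    """Final labels, per-cell posterior cluster probabilities, diagnostics."""

    labels: np.ndarray  # C, values in 1..K
    posterior: np.ndarray  # C x K, rows sum to 1
    selected_chain: int
    log_post_trace: np.ndarray
    params_hat: ModelParams
    chain_max_log_post: np.ndarray = field(default_factory=lambda: np.array([]))
    diagnostics: dict = field(default_factory=dict)


def gibbs_update_z(
    data: PairedCounts, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw every z_j from its full conditional in one sweep.

    The labels are conditionally independent given (alpha, b), so the
    joint draw over cells equals a fixed-order sweep. Uniform prior over
    clusters.
    """
    logw = cluster_logweights_all(data, params)  # K x C
    probs = softmax_rows(logw, axis=0)
    u = rng.random(data.n_cells)
    cum = np.cumsum(probs, axis=0)
    return (u[None, :] < cum).argmax(axis=0).astype(np.int64) + 1


def _dm_sum(counts, alpha_row, b) -> float:
    """Sum of DM log-densities (no coefficient) of the given cells."""
    return float(
        dm_logpmf_rows(counts, alpha_row[None, :], b=b, include_coef=False).sum()
    )


def alpha_proposal_logratio(
    data: PairedCounts,
    params: ModelParams,
    source: str,
    k: int,
    alpha_prop: np.ndarray,
) -> float:
    """Log MH acceptance ratio for replacing cluster k's alpha row (1-based k).

    Equals the change in the complete log-posterior (only cells currently
    in cluster k contribute) plus the log-normal proposal-asymmetry
    correction sum(log alpha' - log alpha).
    """
    if source not in ("rna", "adt"):
        raise ValueError("source must be 'rna' or 'adt'")
    counts = data.rna_counts if source == "rna" else data.adt_counts
    block = params.alpha_rna if source == "rna" else params.alpha_adt
    cur = block[k - 1]
    alpha_prop = np.asarray(alpha_prop, dtype=float)
    cells = np.flatnonzero(params.z == k)
    delta = 0.0
    if cells.size:
        sub = counts[:, cells]
        b_sub = params.b[cells]
        delta = _dm_sum(sub, alpha_prop, b_sub) - _dm_sum(sub, cur, b_sub)
    return delta + float(np.log(alpha_prop / cur).sum())


def mh_update_alpha(
    data: PairedCounts,
    params: ModelParams,
    source: str,
    rng: np.random.Generator,
    step: float | np.ndarray = 0.08,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative random-walk MH update of each cluster row.

    Proposes ``alpha' = alpha * exp(eps)`` element-wise with
    eps ~ Normal(0, step_k^2), row by row. Rows of clusters that are
    currently empty are frozen (no proposal), avoiding a prior-free drift
    of unidentified parameters. Returns (new block, accepted mask,
    proposed mask) with one entry per row.
    """
    block = (params.alpha_rna if source == "rna" else params.alpha_adt).copy()
    n_clusters = block.shape[0]
    step = np.broadcast_to(np.asarray(step, dtype=float), (n_clusters,))
    accepted = np.zeros(n_clusters, dtype=bool)
    proposed = np.zeros(n_clusters, dtype=bool)
    for k in range(1, n_clusters + 1):
        if not np.any(params.z == k):
            # draw nothing for frozen rows: keep the random stream aligned
            # only with what is actually proposed
            continue
        proposed[k - 1] = True
        eps = rng.normal(0.0, step[k - 1], size=block.shape[1])
        prop = block[k - 1] * np.exp(eps)
        log_ratio = alpha_proposal_logratio(data, params, source, k, prop)
        if np.log1p(-rng.random()) <= log_ratio:
            block[k - 1] = prop
            accepted[k - 1] = True
        # keep params in sync so later rows see accepted earlier rows
        if source == "rna":
            params.alpha_rna = block
        else:
            params.alpha_adt = block
    return block, accepted, proposed


def b_proposal_logratio(
    data: PairedCounts, params: ModelParams, b_prop: np.ndarray
) -> np.ndarray:
    """Per-cell log MH acceptance ratios for replacing b with b_prop.

    Cell j's ratio uses only its own DM terms (both sources, at its
    assigned cluster), its log-normal prior term, and the multiplicative
    proposal's asymmetry correction log(b'_j / b_j).
    """
    b_prop = np.asarray(b_prop, dtype=float)
    idx = params.z - 1
    cols = np.arange(data.n_cells)

    def per_cell(bvec):
        lw = dm_logpmf_rows(
            data.rna_counts, params.alpha_rna, b=bvec, include_coef=False
        ) + dm_logpmf_rows(data.adt_counts, params.alpha_adt, b=bvec, include_coef=False)
        return lw[idx, cols]

    log_b, log_bp = np.log(params.b), np.log(b_prop)
    prior_cur = -log_b - log_b**2 / (2.0 * params.sigma_b2)
    prior_prop = -log_bp - log_bp**2 / (2.0 * params.sigma_b2)
    return (
        per_cell(b_prop)
        - per_cell(params.b)
        + prior_prop
        - prior_cur
        + (log_bp - log_b)
    )


def mh_update_b(
    data: PairedCounts,
    params: ModelParams,
    rng: np.random.Generator,
    step: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell multiplicative random-walk MH update of the random effects.

    Cells are conditionally independent given (z, alpha, sigma_b2), so all
    proposals are evaluated and accepted in parallel. Returns (new b,
    accepted mask).
    """
    eps = rng.normal(0.0, step, size=data.n_cells)
    b_prop = params.b * np.exp(eps)
    log_ratio = b_proposal_logratio(data, params, b_prop)
    accept = np.log1p(-rng.random(data.n_cells)) <= log_ratio
    b_new = np.where(accept, b_prop, params.b)
    return b_new, accept


def update_sigma_b2(
    params: ModelParams, rng: np.random.Generator, config: MCMCConfig
) -> float:
    """Conjugate inverse-gamma draw of sigma_b2 (or the fixed value).

    Posterior: InvGamma(a0 + C/2, b0 + sum_j (log b_j)^2 / 2) with weak
    defaults a0 = b0 = 0.01.
    """
    if config.sigma_b2_mode == "fixed":
        return float(config.sigma_b2_fixed)
    c = params.n_cells
    shape = SIGMA_B2_PRIOR_SHAPE + 0.5 * c
    rate = SIGMA_B2_PRIOR_RATE + 0.5 * float(np.sum(np.log(params.b) ** 2))
    return float(rate / rng.gamma(shape))


def run_chain(
    data: PairedCounts,
    K: int,
    init: ModelParams,
    config: MCMCConfig,
    chain_seed,
) -> ChainTrace:
    """Run one chain of ``config.n_iter`` sweeps from the given state.

    Sweep order: z -> alpha(rna) -> alpha(adt) -> b -> sigma_b2. The
    complete log-posterior is recorded after every sweep; the run is fully
    reproducible from ``chain_seed``.
    """
    rng = np.random.default_rng(chain_seed)
    params = init.copy()
    if config.sigma_b2_mode == "fixed":
        params.sigma_b2 = config.sigma_b2_fixed
    else:
        params.sigma_b2 = config.sigma_b2_init
    step_a = {
        "rna": np.full(K, config.rw_step_alpha),
        "adt": np.full(K, config.rw_step_alpha),
    }
    step_b = config.rw_step_b
    n_burn = config.n_burn
    z_samples = np.empty((config.n_iter, data.n_cells), dtype=np.int32)
    log_post = np.empty(config.n_iter)
    sigma_samples = np.empty(config.n_iter)
    acc_counts = {"rna": 0, "adt": 0, "b": 0}
    prop_counts = {"rna": 0, "adt": 0, "b": 0}

    for t in range(config.n_iter):
        params.z = gibbs_update_z(data, params, rng)
        sweep_acc = {}
        for source in ("rna", "adt"):
            block, accepted, proposed = mh_update_alpha(
                data, params, source, rng, step=step_a[source]
            )
            sweep_acc[source] = (accepted, proposed)
            if t >= n_burn:
                acc_counts[source] += int(accepted.sum())
                prop_counts[source] += int(proposed.sum())
        params.b, acc_b = mh_update_b(data, params, rng, step=step_b)
        if t >= n_burn:
            acc_counts["b"] += int(acc_b.sum())
            prop_counts["b"] += data.n_cells
        params.sigma_b2 = update_sigma_b2(params, rng, config)

        lp = complete_log_posterior(data, params)
        if not np.isfinite(lp):
            raise RuntimeError(
                f"log-posterior became non-finite at sweep {t} "
                f"(sigma_b2={params.sigma_b2:.3g}); aborting chain"
            )
        z_samples[t] = params.z
        log_post[t] = lp
        sigma_samples[t] = params.sigma_b2

        if config.adapt and t < n_burn:
            gain = min(0.5, (t + 1) ** -0.6)
            for source in ("rna", "adt"):
                accepted, proposed = sweep_acc[source]
                delta = np.where(accepted, 1.0, 0.0) - _ACCEPT_TARGET
                step_a[source] = step_a[source] * np.exp(
                    gain * np.where(proposed, delta, 0.0)
                )
            step_b *= float(np.exp(gain * (acc_b.mean() - _ACCEPT_TARGET)))
        if (t + 1) % 50 == 0:
            logger.info("sweep %d/%d log-posterior %.2f", t + 1, config.n_iter, lp)

    def frac(key):
        return acc_counts[key] / prop_counts[key] if prop_counts[key] else float("nan")

    return ChainTrace(
        z_samples=z_samples,
        log_post=log_post,
        sigma_b2_samples=sigma_samples,
        accept_alpha_rna=frac("rna"),
        accept_alpha_adt=frac("adt"),
        accept_b=frac("b"),
        final_params=params,
    )


def _summarise(trace: ChainTrace, K: int, n_burn: int) -> tuple[np.ndarray, np.ndarray]:
    kept = trace.z_samples[n_burn:]
    posterior = np.stack(
        [(kept == k).mean(axis=0) for k in range(1, K + 1)], axis=1
    )
    labels = posterior.argmax(axis=1).astype(np.int64) + 1
    return labels, posterior


def run_bremsc(data: PairedCounts, K: int, config: MCMCConfig | None = None) -> ClusterResult:
    """Fit the random-effects mixture: multi-chain MCMC, best-chain summary.

    Runs ``config.n_chains`` chains from independent K-means-seeded
    initialisations, keeps the chain whose maximum recorded log-posterior
    is largest, and summarises its post-burn-in label draws into a C x K
    posterior-probability matrix (hard labels = row argmax, ties to the
    lowest index).
    """
    config = config or MCMCConfig()
    if not 1 <= K <= data.n_cells:
        raise ValueError(f"K={K} must lie in 1..{data.n_cells}")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(2 * config.n_chains)
    traces: list[ChainTrace] = []
    for c in range(config.n_chains):
        init_seed = int(children[2 * c].generate_state(1)[0] % (2**31))
        init = initial_params(data, K, seed=init_seed, sigma_b2=config.sigma_b2_init)
        logger.info("chain %d: initialised from K-means seed %d", c, init_seed)
        traces.append(run_chain(data, K, init, config, children[2 * c + 1]))
    chain_max = np.array([t.log_post.max() for t in traces])
    best = int(chain_max.argmax())
    labels, posterior = _summarise(traces[best], K, config.n_burn)
    trace = traces[best]
    return ClusterResult(
        labels=labels,
        posterior=posterior,
        selected_chain=best,
        log_post_trace=trace.log_post,
        params_hat=trace.final_params,
        chain_max_log_post=chain_max,
        diagnostics={
            "accept_alpha_rna": trace.accept_alpha_rna,
            "accept_alpha_adt": trace.accept_alpha_adt,
            "accept_b": trace.accept_b,
            "sigma_b2_samples": trace.sigma_b2_samples,
            "z_samples": trace.z_samples,
            "n_burn": config.n_burn,
        },
    )


def flag_vague_cells(result: ClusterResult, fraction: float) -> np.ndarray:
    """Flag the given fraction of cells with the least confident assignment.

    Returns a boolean mask marking the floor(fraction * C) cells whose
    row-maximum posterior probability is smallest; ties broken by cell
    index.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    row_max = result.posterior.max(axis=1)
    n_flag = int(np.floor(fraction * row_max.size))
    flags = np.zeros(row_max.size, dtype=bool)
    order = np.argsort(row_max, kind="stable")
    flags[order[:n_flag]] = True
    return flags
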