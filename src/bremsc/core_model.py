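"""Probability computations for the Dirichlet-multinomial mixture model.

Each cell's count vector in each source is modelled as a multinomial whose
proportion vector carries a cluster-specific Dirichlet prior; integrating
the proportions out yields the Dirichlet-multinomial (DM) density

    log P(x | a) = log[T!/prod_i x_i!]
                 + sum_i [lnG(x_i + a_i) - lnG(a_i)]
                 + lnG(|a|) - lnG(T + |a|),

with T = sum_i x_i and |a| = sum_i a_i. The multiplicative cell random
effect b_j rescales the cluster block, ``a -> a * b_j``, which changes the
per-cell dispersion (larger b -> closer to multinomial) without moving the
mean proportions; it is shared between the two sources and so induces
cross-source correlation. All computations are in log space via
``scipy.special.gammaln``; the multinomial coefficient is included, making
every density here a true log-pmf (it is constant in all parameters, so
inference is unaffected).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .datatypes import ModelParams, PairedCounts

__all__ = [
    "dm_logpmf",
    "loglik_independent",
    "complete_log_posterior",
    "cell_cluster_logweights",
]


def dm_logpmf(x, alpha) -> float:
    """Dirichlet-multinomial log-pmf of a single count vector.

    Parameters
    ----------
    x : array-like of non-negative integers, length m
    alpha : array-like of strictly positive reals, length m

    Returns
    -------
    float
        log P(x | alpha), multinomial coefficient included.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape or x.ndim != 1:
        raise ValueError(f"x and alpha must be 1-D with equal length, got {x.shape} vs {alpha.shape}")
    if np.any(x < 0) or not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("x must contain non-negative integers")
    if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
        raise ValueError("alpha must contain finite strictly positive reals")
    t = x.sum()
    a_sum = alpha.sum()
    coef = gammaln(t + 1.0) - gammaln(x + 1.0).sum()
    return float(
        coef
        + (gammaln(x + alpha) - gammaln(alpha)).sum()
        + gammaln(a_sum)
        - gammaln(t + a_sum)
    )


def dm_logpmf_rows(
    counts: np.ndarray,
    alpha_rows: np.ndarray,
    b: np.ndarray | None = None,
    include_coef: bool = True,
) -> np.ndarray:
    """Vectorised DM log-pmf of every cell under every cluster row.

    counts is (m, C) features-by-cells; alpha_rows is (K, m). When ``b`` is
    given, cell j is evaluated under ``alpha_rows[k] * b[j]``. Returns a
    (K, C) array. Workhorse shared by the samplers and the EM fits.
    """
    counts = np.asarray(counts, dtype=float)
    alpha_rows = np.atleast_2d(np.asarray(alpha_rows, dtype=float))
    totals = counts.sum(axis=0)
    xt = counts.T  # C x m
    n_clusters = alpha_rows.shape[0]
    out = np.empty((n_clusters, counts.shape[1]))
    for k in range(n_clusters):
        if b is None:
            a = alpha_rows[k][None, :]
        else:
            a = alpha_rows[k][None, :] * np.asarray(b, dtype=float)[:, None]
        a_sum = a.sum(axis=1)
        out[k] = (
            (gammaln(xt + a) - gammaln(a)).sum(axis=1)
            + gammaln(a_sum)
            - gammaln(totals + a_sum)
        )
    if include_coef:
        out += gammaln(totals + 1.0) - gammaln(counts + 1.0).sum(axis=0)
    return out


def _check(data: PairedCounts, params: ModelParams) -> None:
    params.check_against(data)


def loglik_independent(data: PairedCounts, params: ModelParams) -> float:
    """Joint log-likelihood under full independence of the two sources.

    Sum over cells of the two per-source DM log-densities at each cell's
    assigned cluster, with no random effects (b plays no role here).
    """
    _check(data, params)
    idx = params.z - 1
    cols = np.arange(data.n_cells)
    lw = dm_logpmf_rows(data.rna_counts, params.alpha_rna) + dm_logpmf_rows(
        data.adt_counts, params.alpha_adt
    )
    return float(lw[idx, cols].sum())


def complete_log_posterior(data: PairedCounts, params: ModelParams) -> float:
    """Complete-data log-posterior of the random-effects model.

    DM terms are evaluated at the cell-scaled parameters ``alpha[k] * b_j``;
    the random-effect prior contributes, per cell,
    ``-ln b_j - (ln b_j)^2 / (2 sigma_b2) - 0.5 ln sigma_b2``.
    """
    _check(data, params)
    idx = params.z - 1
    cols = np.arange(data.n_cells)
    lw = dm_logpmf_rows(data.rna_counts, params.alpha_rna, b=params.b) + dm_logpmf_rows(
        data.adt_counts, params.alpha_adt, b=params.b
    )
    log_b = np.log(params.b)
    prior = np.sum(-log_b - log_b**2 / (2.0 * params.sigma_b2))
    prior += -0.5 * data.n_cells * np.log(params.sigma_b2)
    return float(lw[idx, cols].sum() + prior)


def cluster_logweights_all(data: PairedCounts, params: ModelParams) -> np.ndarray:
    """(K, C) unnormalised Gibbs log-weights for every cell at once.

    Entry (k, j) is the DM log-density of cell j's two count vectors under
    cluster k's blocks scaled by b_j; a uniform prior over clusters adds
    only a constant per column. Multinomial coefficients are omitted (they
    cancel under column normalisation).
    """
    _check(data, params)
    return dm_logpmf_rows(
        data.rna_counts, params.alpha_rna, b=params.b, include_coef=False
    ) + dm_logpmf_rows(data.adt_counts, params.alpha_adt, b=params.b, include_coef=False)


def cell_cluster_logweights(data: PairedCounts, params: ModelParams, j: int) -> np.ndarray:
    """Unnormalised log-weights of the Gibbs full conditional of z_j.

    ``j`` is a 0-based cell index. Exponentiating and normalising the
    returned length-K vector gives the full-conditional probabilities
    under a uniform prior over clusters.
    """
    _check(data, params)
    if not 0 <= j < data.n_cells:
        raise ValueError(f"cell index {j} out of range for C={data.n_cells}")
    bj = params.b[j : j + 1]
    w = dm_logpmf_rows(
        data.rna_counts[:, j : j + 1], params.alpha_rna, b=bj, include_coef=False
    ) + dm_logpmf_rows(
        data.adt_counts[:, j : j + 1], params.alpha_adt, b=bj, include_coef=False
    )
    return w[:, 0]


def softmax_rows(logw: np.ndarray, axis: int = 0) -> np.ndarray:
    """Normalise log-weights to probabilities with max-subtraction."""
    shifted = logw - logw.max(axis=axis, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=axis, keepdims=True)
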