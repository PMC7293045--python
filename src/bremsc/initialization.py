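"""Initial labels and Dirichlet parameters, plus AIC/BIC model selection.

Initialisation follows the scheme of per-source K-means on normalised
log counts, merging of the two label sets, and Ronning-style moment
estimation of each cluster's Dirichlet parameters. The number of clusters
can be chosen by AIC/BIC over a grid, using the EM-fitted independence
model as the maximised likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .datatypes import ModelParams, PairedCounts

__all__ = [
    "kmeans_labels",
    "ronning_alpha",
    "combine_source_labels",
    "initial_params",
    "select_k",
]

_ALPHA_FLOOR = 1e-6


def _log_normalised(matrix: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log1p of per-cell total-normalised counts (columns sum to `scale`)."""
    matrix = np.asarray(matrix, dtype=float)
    totals = matrix.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(matrix / totals * scale)


def kmeans_labels(matrix: np.ndarray, K: int, seed: int) -> np.ndarray:
    """K-means labels (1..K) of cells from one features x cells count matrix."""
    matrix = np.asarray(matrix)
    n_cells = matrix.shape[1]
    if not 1 <= K <= n_cells:
        raise ValueError(f"K={K} must lie in 1..{n_cells}")
    y = _log_normalised(matrix).T  # cells x features
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed))
    return km.fit_predict(y).astype(np.int64) + 1


def ronning_alpha(matrix: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """Moment estimate of per-cluster Dirichlet parameters.

    For each cluster, cell proportion vectors p_j = x_j / T_j are averaged;
    the common precision s is estimated from the first coordinate's moment
    identity s = pbar_1 (1 - pbar_1) / var(p_1) - 1. When the variance is
    degenerate or the identity yields s <= 0, a conservative start
    s = 1 / min positive mean proportion is used instead. Entries are
    floored at 1e-6, so the result is always strictly positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    m = matrix.shape[0]
    out = np.empty((K, m))
    for k in range(1, K + 1):
        cols = np.flatnonzero(labels == k)
        if cols.size == 0:
            raise ValueError(f"cluster {k} is empty; cannot estimate alpha")
        sub = matrix[:, cols]
        totals = sub.sum(axis=0)
        totals[totals == 0] = 1.0
        props = sub / totals  # m x n_k
        pbar = props.mean(axis=1)
        var1 = props[0].var(ddof=1) if cols.size > 1 else 0.0
        p1 = pbar[0]
        s = p1 * (1.0 - p1) / var1 - 1.0 if var1 > 1e-12 else -1.0
        if not np.isfinite(s) or s <= 0:
            positive = pbar[pbar > 0]
            s = 1.0 / positive.min() if positive.size else 1.0
        out[k - 1] = np.maximum(pbar * s, _ALPHA_FLOOR)
    return out


def combine_source_labels(labels_rna: np.ndarray, labels_adt: np.ndarray, K: int) -> np.ndarray:
    """Merge per-source K-means labels into one initial assignment.

    ADT clusters are matched to RNA clusters by maximising contingency
    overlap (Hungarian assignment); the ADT-derived labels, relabelled into
    the matched RNA cluster ids, become the initial z. ADT is
    lower-dimensional and typically the more discriminative source for
    major cell types, hence its labels win.
    """
    labels_rna = np.asarray(labels_rna)
    labels_adt = np.asarray(labels_adt)
    table = np.zeros((K, K), dtype=np.int64)
    for a, r in zip(labels_adt - 1, labels_rna - 1):
        table[a, r] += 1
    rows, cols = linear_sum_assignment(-table)
    mapping = np.empty(K, dtype=np.int64)
    mapping[rows] = cols + 1
    return mapping[labels_adt - 1]


def initial_params(
    data: PairedCounts, K: int, seed: int, sigma_b2: float = 1.0
) -> ModelParams:
    """K-means + Ronning initial state for the samplers and EM.

    Random effects start at 1 and sigma_b2 at a moderate value; both are
    refined by the sampler itself.
    """
    if not 1 <= K <= data.n_cells:
        raise ValueError(f"K={K} must lie in 1..{data.n_cells}")
    l_rna = kmeans_labels(data.rna_counts, K, seed)
    l_adt = kmeans_labels(data.adt_counts, K, seed + 1)
    z = combine_source_labels(l_rna, l_adt, K)
    # guard: the Hungarian merge keeps K-means' non-empty clusters, but fall
    # back to the RNA labels should a cluster still come out empty
    if np.unique(z).size < K:
        z = l_rna
    alpha_rna = ronning_alpha(data.rna_counts, z, K)
    alpha_adt = ronning_alpha(data.adt_counts, z, K)
    return ModelParams(
        alpha_rna=alpha_rna,
        alpha_adt=alpha_adt,
        b=np.ones(data.n_cells),
        sigma_b2=sigma_b2,
        z=z,
    )


def n_free_params(K: int, G: int, D: int) -> int:
    """Free-parameter count of the independence mixture: K(G+D) + (K-1)."""
    return K * (G + D) + (K - 1)


@dataclass
class KSelection:
    """Chosen cluster number and the AIC/BIC table behind it."""

    chosen_k: int
    table: pd.DataFrame


def select_k(data: PairedCounts, k_grid, config=None, criterion: str = "BIC") -> KSelection:
    """Pick K on a grid by AIC/BIC of the EM-fitted independence model.

    The EM fit supplies a maximised observed-data log-likelihood, the
    quantity the information criteria formally require; the full sampler is
    not run here.
    """
    from .inference_em import EMConfig, run_jointdimm

    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    k_grid = [int(k) for k in k_grid]
    if any(k < 1 or k > data.n_cells for k in k_grid):
        raise ValueError("grid values must lie in 1..C")
    config = config or EMConfig()
    rows = []
    for k in k_grid:
        result = run_jointdimm(data, k, config)
        ll = result.log_post_trace[-1]
        nu = n_free_params(k, data.n_genes, data.n_markers)
        rows.append(
            {
                "K": k,
                "loglik": ll,
                "n_params": nu,
                "AIC": -2.0 * ll + 2.0 * nu,
                "BIC": -2.0 * ll + nu * np.log(data.n_cells),
            }
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table[criterion].idxmin(), "K"])
    return KSelection(chosen_k=chosen, table=table)
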