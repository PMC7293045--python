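"""Chance-adjusted clustering agreement metrics (ARI and AMI).

Both are computed from the contingency table of two labelings. ARI adjusts
the pair-counting Rand index for chance under the permutation model; AMI
adjusts mutual information by its hypergeometric expectation, normalised
here by the arithmetic mean of the two entropies. Implemented from the
definitions so they can be cross-checked against independent references.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["adjusted_rand_index", "adjusted_mutual_information", "contingency_table"]


def contingency_table(labels_a, labels_b) -> np.ndarray:
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least two items to compare clusterings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index in [-1, 1]; 1 = identical partitions, 0 = chance."""
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(np.array(n))
    maximum = 0.5 * (sum_a + sum_b)
    denom = maximum - expected
    if denom == 0.0:
        # both partitions trivial (all-one-cluster or all-singletons):
        # the partitions coincide, so agreement is perfect
        return 1.0
    return float((sum_ij - expected) / denom)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def expected_mutual_information(table: np.ndarray) -> float:
    """E[MI] under the hypergeometric model of random contingency tables."""
    n = int(table.sum())
    a = table.sum(axis=1).astype(np.int64)
    b = table.sum(axis=0).astype(np.int64)
    log_n = np.log(n)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.int64)
            term = (nij / n) * (log_n + np.log(nij) - np.log(ai) - np.log(bj))
            log_pmf = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + gammaln(n - ai + 1)
                + gammaln(n - bj + 1)
                - gammaln(n + 1)
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float((term * np.exp(log_pmf)).sum())
    return emi


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """Adjusted mutual information with arithmetic-mean normalisation.

    1 indicates identical partitions; 0 is the chance level. Degenerate
    normalisers (a trivial partition on both sides) return 1 when the
    partitions coincide, otherwise the ratio is evaluated with a guarded
    denominator.
    """
    table = contingency_table(labels_a, labels_b)
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    if a.size == 1 and b.size == 1:
        return 1.0
    n = table.sum()
    if a.size == n and b.size == n:  # both all-singletons
        return 1.0
    nz = table > 0
    p = table[nz] / n
    outer = np.outer(a, b)[nz] / (float(n) * n)
    mi = float((p * np.log(p / outer)).sum())
    emi = expected_mutual_information(table)
    normalizer = 0.5 * (_entropy(a) + _entropy(b))
    denom = normalizer - emi
    eps = np.finfo(float).eps
    if denom < 0:
        denom = min(denom, -eps)
    else:
        denom = max(denom, eps)
    return float((mi - emi) / denom)
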