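"""Synthetic paired RNA/ADT count generation with ground truth.

Two generators are provided. ``simulate_bremsc`` draws from the model's own
generative process: cluster-level Dirichlet blocks, a shared log-normal
cell random effect multiplying both blocks, Dirichlet proportion draws and
multinomial counts at truncated-normal library sizes. It is the reference
data source for recovery and calibration tests. ``simulate_misspecified``
draws gamma-Poisson (negative-binomial) counts with cluster-specific
differentially-expressed features — a deliberately different process used
to probe robustness when the fitted model is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import ModelParams, PairedCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_bremsc",
    "simulate_misspecified",
    "make_cluster_alphas",
    "scenario_config",
    "default_scenarios",
]

# Truncated-normal library-size defaults. These are configuration defaults
# chosen to look like typical droplet data (a few thousand UMIs per cell,
# larger ADT totals); they are synthetic stand-ins, not estimates from any
# particular data set.
RNA_TOTAL_DEFAULT = (2500.0, 800.0, 500.0)  # (mean, sd, lower)
ADT_TOTAL_DEFAULT = (5000.0, 1500.0, 100.0)


@dataclass
class SimConfig:
    """Full specification of one generative-model simulation."""

    K: int
    cells_per_cluster: list[int]
    G: int
    D: int
    alpha_rna_true: np.ndarray
    alpha_adt_true: np.ndarray
    sigma_b: float = 0.5
    rna_total: tuple[float, float, float] = RNA_TOTAL_DEFAULT
    adt_total: tuple[float, float, float] = ADT_TOTAL_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_rna_true = np.asarray(self.alpha_rna_true, dtype=float)
        self.alpha_adt_true = np.asarray(self.alpha_adt_true, dtype=float)
        self.cells_per_cluster = [int(c) for c in np.atleast_1d(self.cells_per_cluster)]
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.cells_per_cluster) != self.K:
            raise ValueError("cells_per_cluster must have length K")
        if any(c < 1 for c in self.cells_per_cluster):
            raise ValueError("cells_per_cluster entries must be >= 1")
        if self.alpha_rna_true.shape != (self.K, self.G):
            raise ValueError("alpha_rna_true must be K x G")
        if self.alpha_adt_true.shape != (self.K, self.D):
            raise ValueError("alpha_adt_true must be K x D")
        for name, a in (
            ("alpha_rna_true", self.alpha_rna_true),
            ("alpha_adt_true", self.alpha_adt_true),
        ):
            if np.any(a <= 0) or not np.all(np.isfinite(a)):
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        for name, spec in (("rna_total", self.rna_total), ("adt_total", self.adt_total)):
            mean, sd, lower = spec
            if sd < 0 or lower < 0 or mean <= 0:
                raise ValueError(f"invalid truncated-normal spec for {name}: {spec}")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_cluster))


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated data set."""

    z_true: np.ndarray
    b_true: np.ndarray
    params_true: ModelParams | None
    p_rna: np.ndarray | None = None  # latent proportion draws (C x G), optional
    p_adt: np.ndarray | None = None


def _draw_totals(spec, n, rng) -> np.ndarray:
    mean, sd, lower = spec
    if sd == 0:
        vals = np.full(n, float(mean))
    else:
        a = (lower - mean) / sd
        vals = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    totals = np.maximum(np.rint(vals).astype(np.int64), int(np.ceil(lower)))
    return np.maximum(totals, 1)


def _dirichlet_rows(alpha_matrix: np.ndarray, rng) -> np.ndarray:
    """Row-wise Dirichlet draws via normalised gammas (rows may differ)."""
    g = rng.gamma(shape=alpha_matrix)
    rowsum = g.sum(axis=1, keepdims=True)
    # guard against total underflow at very small concentrations
    bad = rowsum[:, 0] <= 0
    if np.any(bad):
        g[bad] = alpha_matrix[bad]
        rowsum = g.sum(axis=1, keepdims=True)
    return g / rowsum


def simulate_bremsc(config: SimConfig) -> tuple[PairedCounts, SimTruth]:
    """Draw paired counts from the random-effects Dirichlet-multinomial model.

    Per cell j in cluster k: b_j ~ LogNormal(0, sigma_b^2); proportions
    p ~ Dir(alpha_k * b_j) for each source; totals from a rounded truncated
    normal; counts ~ Multinomial(T_j, p). Column sums equal the drawn totals
    exactly, and everything is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    z = np.repeat(np.arange(1, config.K + 1), config.cells_per_cluster)
    n = z.size
    b = np.exp(rng.normal(0.0, config.sigma_b, size=n)) if config.sigma_b > 0 else np.ones(n)

    a_rna = config.alpha_rna_true[z - 1] * b[:, None]  # C x G
    a_adt = config.alpha_adt_true[z - 1] * b[:, None]  # C x D
    p_rna = _dirichlet_rows(a_rna, rng)
    p_adt = _dirichlet_rows(a_adt, rng)

    t_rna = _draw_totals(config.rna_total, n, rng)
    t_adt = _draw_totals(config.adt_total, n, rng)

    x_rna = np.empty((config.G, n), dtype=np.int64)
    x_adt = np.empty((config.D, n), dtype=np.int64)
    for j in range(n):
        x_rna[:, j] = rng.multinomial(t_rna[j], p_rna[j])
        x_adt[:, j] = rng.multinomial(t_adt[j], p_adt[j])

    data = PairedCounts(rna_counts=x_rna, adt_counts=x_adt)
    params_true = ModelParams(
        alpha_rna=config.alpha_rna_true,
        alpha_adt=config.alpha_adt_true,
        b=b,
        sigma_b2=max(config.sigma_b**2, 1e-12),
        z=z,
    )
    truth = SimTruth(z_true=z, b_true=b, params_true=params_true, p_rna=p_rna, p_adt=p_adt)
    return data, truth


def simulate_misspecified(
    K: int,
    cells_per_cluster,
    G: int,
    D: int,
    de_prob: float,
    de_fold: float = 4.0,
    dispersion: float = 2.0,
    rna_total: tuple[float, float, float] = RNA_TOTAL_DEFAULT,
    adt_total: tuple[float, float, float] = ADT_TOTAL_DEFAULT,
    seed: int = 0,
) -> tuple[PairedCounts, SimTruth]:
    """Gamma-Poisson counts with cluster-specific DE features.

    Baseline feature means are log-normal; per cluster a ``de_prob``
    fraction of features is multiplied or divided by ``de_fold``. Each
    count is Poisson with a gamma-distributed rate whose mean vector is
    rescaled so the expected cell total matches a truncated-normal library
    size; ``dispersion`` is the negative-binomial size parameter
    (variance = mu + mu^2/dispersion; ``np.inf`` gives Poisson). ADT uses
    the same recipe with D features and larger totals.
    """
    if not 0.0 <= de_prob <= 1.0:
        raise ValueError("de_prob must lie in [0, 1]")
    if de_fold < 1.0:
        raise ValueError("de_fold must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive (np.inf allowed)")
    cells_per_cluster = [int(c) for c in np.atleast_1d(cells_per_cluster)]
    if len(cells_per_cluster) != K or any(c < 1 for c in cells_per_cluster):
        raise ValueError("cells_per_cluster must hold K positive integers")

    rng = np.random.default_rng(seed)
    z = np.repeat(np.arange(1, K + 1), cells_per_cluster)
    n = z.size

    def one_source(m, totals_spec):
        base = np.exp(rng.normal(0.0, 0.5, size=m))
        cluster_means = np.tile(base, (K, 1))
        for k in range(K):
            de_mask = rng.random(m) < de_prob
            direction = rng.random(m) < 0.5
            factor = np.where(direction, de_fold, 1.0 / de_fold)
            cluster_means[k, de_mask] *= factor[de_mask]
        totals = _draw_totals(totals_spec, n, rng)
        mu = cluster_means[z - 1]
        mu = mu / mu.sum(axis=1, keepdims=True) * totals[:, None]
        if np.isinf(dispersion):
            lam = mu
        else:
            lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
        counts = rng.poisson(lam).T.astype(np.int64)  # m x C
        return counts, cluster_means

    x_rna, _ = one_source(G, rna_total)
    x_adt, _ = one_source(D, adt_total)
    data = PairedCounts(rna_counts=x_rna, adt_counts=x_adt)
    truth = SimTruth(z_true=z, b_true=np.ones(n), params_true=None)
    return data, truth


def make_cluster_alphas(
    n_features: int, K: int, base: float, boost: float
) -> np.ndarray:
    """Block-structured cluster Dirichlet rows: shared baseline plus a
    cluster-specific boosted feature block.

    Features are split into K contiguous blocks; cluster k's block entries
    are ``base * boost`` and all others ``base``. ``boost`` controls the
    separation between clusters (1 = no signal).
    """
    if n_features < K:
        raise ValueError("need at least one feature per cluster block")
    alphas = np.full((K, n_features), float(base))
    edges = np.linspace(0, n_features, K + 1).astype(int)
    for k in range(K):
        alphas[k, edges[k] : edges[k + 1]] = base * boost
    return alphas


_BOOST = {"strong": 10.0, "weak": 2.0}


def scenario_config(
    K: int = 3,
    cells_per_cluster: int | list[int] = 100,
    G: int = 60,
    D: int = 10,
    rna_signal: str = "strong",
    adt_signal: str = "strong",
    sigma_b: float = 0.5,
    rna_total: tuple[float, float, float] = RNA_TOTAL_DEFAULT,
    adt_total: tuple[float, float, float] = ADT_TOTAL_DEFAULT,
    seed: int = 0,
) -> SimConfig:
    """Build a SimConfig from high-level knobs (signal strength per source)."""
    if rna_signal not in _BOOST or adt_signal not in _BOOST:
        raise ValueError("signal levels must be 'strong' or 'weak'")
    if np.isscalar(cells_per_cluster):
        cells_per_cluster = [int(cells_per_cluster)] * K
    return SimConfig(
        K=K,
        cells_per_cluster=list(cells_per_cluster),
        G=G,
        D=D,
        alpha_rna_true=make_cluster_alphas(G, K, base=1.0, boost=_BOOST[rna_signal]),
        alpha_adt_true=make_cluster_alphas(D, K, base=5.0, boost=_BOOST[adt_signal]),
        sigma_b=sigma_b,
        rna_total=rna_total,
        adt_total=adt_total,
        seed=seed,
    )


def default_scenarios() -> dict[str, SimConfig]:
    """Named study conditions varying one design axis at a time.

    Axes: among-cell variability sigma_b in {0, 0.5, 1, 2}; per-source
    signal strength (strong/weak combinations); cells per cluster in
    {50, 100, 200}; number of clusters K in {3, 5, 8}. The base condition
    is K=3, 100 cells/cluster, G=60 genes, D=10 markers, both sources
    strong, sigma_b=0.5.
    """
    scenarios: dict[str, SimConfig] = {}
    for sb in (0.0, 0.5, 1.0, 2.0):
        scenarios[f"sigma_b_{sb:g}"] = scenario_config(sigma_b=sb)
    for name, (rs, as_) in {
        "both_strong": ("strong", "strong"),
        "adt_weak_rna_strong": ("strong", "weak"),
        "adt_strong_rna_weak": ("weak", "strong"),
        "both_weak": ("weak", "weak"),
    }.items():
        scenarios[name] = scenario_config(rna_signal=rs, adt_signal=as_)
    for cells in (50, 100, 200):
        scenarios[f"cells_{cells}"] = scenario_config(cells_per_cluster=cells)
    for k in (3, 5, 8):
        scenarios[f"k_{k}"] = scenario_config(K=k)
    return scenarios
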