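"""Core containers for paired count data and model parameters.

The model observes two aligned count matrices over the same cells: an
RNA UMI matrix (genes x cells) and an ADT surface-marker matrix
(markers x cells). Cluster-level Dirichlet parameter blocks, cell-level
multiplicative random effects and hard cluster labels make up the model
state. Cluster labels are 1-based (1..K) throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PairedCounts", "ModelParams"]


def _as_count_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative entries")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"{name} contains non-integer entries")
    return np.asarray(arr, dtype=np.int64)


@dataclass
class PairedCounts:
    """Aligned RNA and ADT count matrices (features x cells) with ids."""

    rna_counts: np.ndarray
    adt_counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rna_counts = _as_count_matrix(self.rna_counts, "rna_counts")
        self.adt_counts = _as_count_matrix(self.adt_counts, "adt_counts")
        if self.rna_counts.shape[1] != self.adt_counts.shape[1]:
            raise ValueError(
                "rna_counts and adt_counts must share the cell dimension: "
                f"{self.rna_counts.shape[1]} vs {self.adt_counts.shape[1]}"
            )
        if min(self.rna_counts.shape + self.adt_counts.shape) < 1:
            raise ValueError("empty count matrix")
        g, c = self.rna_counts.shape
        d = self.adt_counts.shape[0]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i:05d}" for i in range(g)]
        if not self.marker_ids:
            self.marker_ids = [f"adt_{i:03d}" for i in range(d)]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j:05d}" for j in range(c)]
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match rna_counts")
        if len(self.marker_ids) != d:
            raise ValueError("marker_ids length does not match adt_counts")
        if len(self.cell_ids) != c:
            raise ValueError("cell_ids length does not match cell dimension")

    @property
    def n_genes(self) -> int:
        return self.rna_counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.adt_counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[1]

    @property
    def rna_totals(self) -> np.ndarray:
        """Per-cell UMI totals T_j of the RNA matrix."""
        return self.rna_counts.sum(axis=0)

    @property
    def adt_totals(self) -> np.ndarray:
        return self.adt_counts.sum(axis=0)


@dataclass
class ModelParams:
    """Model state: Dirichlet blocks, random effects, labels.

    alpha_rna : (K, G) strictly positive cluster-level Dirichlet parameters
        for the RNA source; alpha_adt likewise (K, D) for ADT.
    b : (C,) strictly positive cell random effects, LogNormal(0, sigma_b2)
        a priori; the effective per-cell Dirichlet parameters are
        ``alpha[k] * b[j]``.
    sigma_b2 : variance of log b.
    z : (C,) hard cluster labels in 1..K.
    """

    alpha_rna: np.ndarray
    alpha_adt: np.ndarray
    b: np.ndarray
    sigma_b2: float
    z: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_rna = np.asarray(self.alpha_rna, dtype=float)
        self.alpha_adt = np.asarray(self.alpha_adt, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.alpha_rna.ndim != 2 or self.alpha_adt.ndim != 2:
            raise ValueError("alpha blocks must be 2-D (K x features)")
        if self.alpha_rna.shape[0] != self.alpha_adt.shape[0]:
            raise ValueError("alpha_rna and alpha_adt must agree on K")
        for name, a in (("alpha_rna", self.alpha_rna), ("alpha_adt", self.alpha_adt)):
            if not np.all(np.isfinite(a)) or np.any(a <= 0):
                raise ValueError(f"{name} entries must be finite and > 0")
        if self.b.ndim != 1 or not np.all(np.isfinite(self.b)) or np.any(self.b <= 0):
            raise ValueError("b must be a 1-D vector of finite positive reals")
        if not np.isfinite(self.sigma_b2) or self.sigma_b2 <= 0:
            raise ValueError("sigma_b2 must be a finite positive real")
        if self.z.shape != self.b.shape:
            raise ValueError("z and b must have the same length (one per cell)")
        k = self.alpha_rna.shape[0]
        if self.z.size and (self.z.min() < 1 or self.z.max() > k):
            raise ValueError(f"z labels must lie in 1..{k}")

    @property
    def n_clusters(self) -> int:
        return self.alpha_rna.shape[0]

    @property
    def n_cells(self) -> int:
        return self.b.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(
            alpha_rna=self.alpha_rna.copy(),
            alpha_adt=self.alpha_adt.copy(),
            b=self.b.copy(),
            sigma_b2=float(self.sigma_b2),
            z=self.z.copy(),
        )

    def check_against(self, data: PairedCounts) -> None:
        """Raise if the parameter shapes do not match a data set."""
        if self.alpha_rna.shape[1] != data.n_genes:
            raise ValueError(
                f"alpha_rna has {self.alpha_rna.shape[1]} features, data has "
                f"{data.n_genes} genes"
            )
        if self.alpha_adt.shape[1] != data.n_markers:
            raise ValueError(
                f"alpha_adt has {self.alpha_adt.shape[1]} features, data has "
                f"{data.n_markers} markers"
            )
        if self.n_cells != data.n_cells:
            raise ValueError(
                f"params describe {self.n_cells} cells, data has {data.n_cells}"
            )
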