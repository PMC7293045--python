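"""Readers and writers for paired single-cell count data.

Two on-disk layouts are supported: a 10x-style Matrix Market triplet
directory (matrix.mtx[.gz], features.tsv[.gz], barcodes.tsv[.gz], with an
optional feature-type column separating "Gene Expression" from "Antibody
Capture") and dense CSV with feature rows and cell columns. Gzipped text
is read transparently. Cells are columns everywhere.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import PairedCounts
from .simulator import SimTruth

__all__ = [
    "read_paired_counts",
    "read_counts_csv",
    "read_10x_dir",
    "write_counts_csv",
    "write_10x_dir",
    "write_paired_counts",
    "write_sim_truth",
    "read_labels_csv",
    "write_labels_csv",
    "filter_hvg",
]

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_counts_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense CSV, feature rows x cell columns, first column = feature ids."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    bad = ~np.equal(np.mod(values, 1), 0) | (values < 0) | ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-count entry {values[r, c]!r} at feature "
            f"{df.index[r]!r}, cell {df.columns[c]!r}"
        )
    return values.astype(np.int64), [str(i) for i in df.index], [str(c) for c in df.columns]


def read_10x_dir(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Matrix Market triplet directory; returns (dense counts, features, barcodes)."""
    directory = Path(path)
    with _open_text(_find(directory, "matrix.mtx")) as fh:
        mat = spio.mmread(fh)
    counts = np.asarray(sparse.coo_matrix(mat).todense())
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError(f"{directory}: matrix contains non-count entries")
    features = pd.read_csv(
        _find(directory, "features.tsv"), sep="\t", header=None, dtype=str
    )
    barcodes = pd.read_csv(
        _find(directory, "barcodes.tsv"), sep="\t", header=None, dtype=str
    )[0].tolist()
    if features.shape[0] != counts.shape[0] or len(barcodes) != counts.shape[1]:
        raise ValueError(f"{directory}: matrix shape does not match features/barcodes")
    return counts.astype(np.int64), features, barcodes


def _load_any(path) -> tuple[np.ndarray, list[str], list[str], pd.DataFrame | None]:
    p = Path(path)
    if p.is_dir():
        counts, features, barcodes = read_10x_dir(p)
        ids = features.iloc[:, min(1, features.shape[1] - 1)].tolist()
        return counts, ids, barcodes, features
    counts, feats, cells = read_counts_csv(p)
    return counts, feats, cells, None


def read_paired_counts(rna_path, adt_path=None) -> PairedCounts:
    """Load paired RNA/ADT counts from disk.

    With ``adt_path`` given, each path may be a dense CSV or a 10x triplet
    directory. With ``adt_path`` omitted, ``rna_path`` must be a 10x
    directory whose features file carries a feature-type column; rows are
    split into "Gene Expression" (RNA) and "Antibody Capture" (ADT).
    Cells are intersected and ordered identically (RNA order wins).
    """
    if adt_path is None:
        counts, features, barcodes = read_10x_dir(rna_path)
        if features.shape[1] < 3:
            raise ValueError(
                f"{rna_path}: features.tsv has no feature-type column; "
                "pass an explicit adt_path instead"
            )
        ftype = features.iloc[:, 2]
        rna_mask = (ftype == GENE_EXPRESSION).to_numpy()
        adt_mask = (ftype == ANTIBODY_CAPTURE).to_numpy()
        if not rna_mask.any() or not adt_mask.any():
            raise ValueError(
                f"{rna_path}: need both '{GENE_EXPRESSION}' and "
                f"'{ANTIBODY_CAPTURE}' feature types"
            )
        names = features.iloc[:, 1].tolist()
        return PairedCounts(
            rna_counts=counts[rna_mask],
            adt_counts=counts[adt_mask],
            gene_ids=[names[i] for i in np.flatnonzero(rna_mask)],
            marker_ids=[names[i] for i in np.flatnonzero(adt_mask)],
            cell_ids=barcodes,
        )

    rna, gene_ids, rna_cells, _ = _load_any(rna_path)
    adt, marker_ids, adt_cells, _ = _load_any(adt_path)
    common = [c for c in rna_cells if c in set(adt_cells)]
    if not common:
        raise ValueError(
            f"RNA and ADT barcodes are disjoint (overlap size 0; "
            f"{len(rna_cells)} vs {len(adt_cells)} cells)"
        )
    rna_idx = [rna_cells.index(c) for c in common]
    adt_pos = {c: i for i, c in enumerate(adt_cells)}
    adt_idx = [adt_pos[c] for c in common]
    return PairedCounts(
        rna_counts=rna[:, rna_idx],
        adt_counts=adt[:, adt_idx],
        gene_ids=gene_ids,
        marker_ids=marker_ids,
        cell_ids=common,
    )


def write_counts_csv(path, counts, feature_ids, cell_ids) -> None:
    pd.DataFrame(np.asarray(counts), index=feature_ids, columns=cell_ids).to_csv(path)


def write_10x_dir(path, counts, feature_ids, cell_ids, feature_types=None) -> None:
    """Write one matrix as a 10x-style Matrix Market triplet directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(np.asarray(counts)), field="integer")
    if feature_types is None:
        feature_types = [GENE_EXPRESSION] * len(feature_ids)
    pd.DataFrame(
        {"id": feature_ids, "name": feature_ids, "type": feature_types}
    ).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)


def write_paired_counts(data: PairedCounts, out_dir, fmt: str = "csv") -> None:
    """Write the pair either as two CSVs or one combined 10x directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        write_counts_csv(out / "rna_counts.csv", data.rna_counts, data.gene_ids, data.cell_ids)
        write_counts_csv(out / "adt_counts.csv", data.adt_counts, data.marker_ids, data.cell_ids)
    elif fmt == "10x":
        counts = np.vstack([data.rna_counts, data.adt_counts])
        types = [GENE_EXPRESSION] * data.n_genes + [ANTIBODY_CAPTURE] * data.n_markers
        write_10x_dir(out / "matrix_10x", counts, data.gene_ids + data.marker_ids, data.cell_ids, types)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or '10x')")


def write_sim_truth(truth: SimTruth, data: PairedCounts, out_dir) -> None:
    """Ground-truth labels/effects as CSV, generating alphas alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_id": data.cell_ids, "z_true": truth.z_true, "b_true": truth.b_true}
    ).to_csv(out / "truth.csv", index=False)
    if truth.params_true is not None:
        pd.DataFrame(truth.params_true.alpha_rna, columns=data.gene_ids).to_csv(
            out / "alpha_rna_true.csv", index=False
        )
        pd.DataFrame(truth.params_true.alpha_adt, columns=data.marker_ids).to_csv(
            out / "alpha_adt_true.csv", index=False
        )


def read_labels_csv(path) -> pd.Series:
    """Label CSV with columns (cell_id, label); returns labels indexed by cell."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns cell_id,label")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_labels_csv(path, cell_ids, labels) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": np.asarray(labels)}).to_csv(path, index=False)


def filter_hvg(rna_counts: np.ndarray, n_top: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the n_top genes with highest variance of log-normalised counts.

    Variance is taken over cells of log1p(counts-per-10k); ties are broken
    deterministically by gene index, and the retained genes keep their
    original order. Returns (reduced matrix, kept indices).
    """
    rna_counts = np.asarray(rna_counts)
    n_genes = rna_counts.shape[0]
    if not 1 <= n_top <= n_genes:
        raise ValueError(f"n_top={n_top} must lie in 1..{n_genes}")
    totals = rna_counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    logn = np.log1p(rna_counts / totals * 1e4)
    var = logn.var(axis=1)
    order = np.lexsort((np.arange(n_genes), -var))
    kept = np.sort(order[:n_top])
    return rna_counts[kept], kept


def dump_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
        fh.write("\n")
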