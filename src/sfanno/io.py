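"""Reading count matrices, gene alignment, and network-input preprocessing.

Cells are rows everywhere.  Raw counts are carried through preprocessing
untouched because the count likelihood is always evaluated on raw counts,
never on the normalized network input.

The RNA normalization recipe (declared convention, recorded in the model
artifact so that target data are preprocessed identically at annotation
time): per-cell size factor = library size / median library size; network
input = per-gene z-scored log1p of size-factor-normalized counts, clipped to
|10|.  Binarized ATAC gene-activity matrices skip normalization entirely
(unit size factors, identity input).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ZCLIP = 10.0


@dataclass
class ExpressionMatrix:
    counts: np.ndarray  # cells x genes
    gene_names: List[str]
    cell_ids: List[str]
    modality: str = "rna"  # "rna" | "atac_binary" | "generic"
    labels: Optional[List[str]] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("expression matrix contains negative entries")
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length must match column count")
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length must match row count")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if self.modality == "atac_binary" and not np.isin(self.counts, (0, 1)).all():
            raise ValueError("atac_binary matrices must contain only 0/1 entries")


@dataclass
class ScalingStats:
    """Per-gene location/scale recorded at source-model time."""

    gene_mean: np.ndarray
    gene_std: np.ndarray
    median_library: float

    def to_dict(self) -> dict:
        return {
            "gene_mean": self.gene_mean.tolist(),
            "gene_std": self.gene_std.tolist(),
            "median_library": float(self.median_library),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingStats":
        return cls(
            gene_mean=np.asarray(d["gene_mean"], dtype=float),
            gene_std=np.asarray(d["gene_std"], dtype=float),
            median_library=float(d["median_library"]),
        )


@dataclass
class PreprocessedData:
    x_input: np.ndarray  # cells x genes, network input
    raw_counts: np.ndarray  # untouched counts, likelihood target
    size_factors: np.ndarray  # per-cell positive reals
    scaling_stats: Optional[ScalingStats]
    gene_names: List[str] = field(default_factory=list)
    cell_ids: List[str] = field(default_factory=list)
    modality: str = "rna"


def read_counts(path, format: Optional[str] = None) -> ExpressionMatrix:
    """Read a counts matrix from MTX (+ sidecars), dense CSV, or H5AD."""
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix == ".h5ad":
            format = "h5ad"
        else:
            format = "csv"
    if format == "mtx":
        return _read_mtx(path)
    if format == "csv":
        return _read_csv(path)
    if format == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path) -> ExpressionMatrix:
    from scipy.io import mmread

    d = path if path.is_dir() else path.parent
    mtx_path = d / "matrix.mtx" if path.is_dir() else path
    for side in ("barcodes.tsv", "genes.tsv"):
        if not (d / side).exists():
            raise FileNotFoundError(f"MTX sidecar missing: {d / side}")
    counts = np.asarray(mmread(str(mtx_path)).todense())
    barcodes = (d / "barcodes.tsv").read_text().split()
    genes = (d / "genes.tsv").read_text().split()
    orientation = "cells_x_genes"
    manifest = d / "manifest.json"
    if manifest.exists():
        orientation = json.loads(manifest.read_text()).get("orientation", orientation)
    if orientation == "genes_x_cells":
        counts = counts.T
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match sidecars "
            f"({len(barcodes)} barcodes x {len(genes)} genes)"
        )
    labels = None
    if (d / "labels.tsv").exists():
        labels = (d / "labels.tsv").read_text().split("\n")
        labels = [l for l in labels if l]
    return ExpressionMatrix(counts, genes, barcodes, labels=labels)


def _read_csv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(), list(df.columns), [str(i) for i in df.index]
    )


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata as ad

    a = ad.read_h5ad(str(path))
    X = a.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    labels = None
    for key in ("cell_type", "labels", "label"):
        if key in a.obs:
            labels = [str(v) for v in a.obs[key]]
            break
    return ExpressionMatrix(
        np.asarray(X), [str(g) for g in a.var_names], [str(c) for c in a.obs_names],
        labels=labels,
    )


def align_genes(
    model_genes: Sequence[str], target: ExpressionMatrix, policy: str = "strict"
) -> ExpressionMatrix:
    """Reorder target columns to the model's gene list.

    ``strict`` errors on any missing gene; ``pad_zero`` fills missing genes
    with zero counts and logs which ones.
    """
    if not model_genes:
        raise ValueError("model gene list is empty")
    if policy not in ("strict", "pad_zero"):
        raise ValueError(f"unknown policy {policy!r}")
    idx = {g: j for j, g in enumerate(target.gene_names)}
    missing = [g for g in model_genes if g not in idx]
    if missing and policy == "strict":
        raise ValueError(f"target is missing model genes: {missing}")
    if missing:
        logger.warning("padding %d missing genes with zeros: %s", len(missing), missing)
        warnings.warn(f"padding missing genes with zeros: {missing}", stacklevel=2)
    n, p = target.counts.shape[0], len(model_genes)
    out = np.zeros((n, p), dtype=target.counts.dtype)
    for j, g in enumerate(model_genes):
        if g in idx:
            out[:, j] = target.counts[:, idx[g]]
    return ExpressionMatrix(
        out, list(model_genes), list(target.cell_ids), target.modality, target.labels
    )


def preprocess(
    em: ExpressionMatrix, stats: Optional[ScalingStats] = None
) -> PreprocessedData:
    """Produce the network input while retaining raw counts.

    When ``stats`` is given (annotation time) the source-time per-gene
    location/scale and median library are reused, so the same recipe is applied
    to target data as was applied to the source.
    """
    counts = np.asarray(em.counts, dtype=np.float64)
    if em.modality == "atac_binary":
        return PreprocessedData(
            x_input=counts.copy(),
            raw_counts=em.counts.copy(),
            size_factors=np.ones(counts.shape[0]),
            scaling_stats=None,
            gene_names=list(em.gene_names),
            cell_ids=list(em.cell_ids),
            modality=em.modality,
        )
    libs = counts.sum(axis=1)
    zero_cells = libs == 0
    if zero_cells.any():
        warnings.warn(
            f"{int(zero_cells.sum())} all-zero cells kept with size factor 1",
            stacklevel=2,
        )
    median_lib = stats.median_library if stats is not None else float(np.median(libs))
    if median_lib <= 0:
        median_lib = 1.0
    sf = np.where(zero_cells, 1.0, libs / median_lib)
    norm = np.log1p(counts / sf[:, None])
    if stats is None:
        mean = norm.mean(axis=0)
        std = norm.std(axis=0)
        std = np.where(std < 1e-8, 1.0, std)
        stats = ScalingStats(gene_mean=mean, gene_std=std, median_library=median_lib)
    x = np.clip((norm - stats.gene_mean) / stats.gene_std, -_ZCLIP, _ZCLIP)
    return PreprocessedData(
        x_input=x,
        raw_counts=em.counts.copy(),
        size_factors=sf,
        scaling_stats=stats,
        gene_names=list(em.gene_names),
        cell_ids=list(em.cell_ids),
        modality=em.modality,
    )
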