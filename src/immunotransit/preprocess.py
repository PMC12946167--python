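"""Normalization, PC embedding, down-sampling and high-expressor selection.

Two per-cell normalizations are used downstream: log-normalization
(counts scaled to a fixed total of 10,000 then ln(1+x), the convention of
standard single-cell workflows) and relative counts (RC: scaling to 1e6
without a log), used for pathway activity ratios.  Both preserve zeros
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import CohortDataset
from .errors import AnalysisError, ValidationError

__all__ = [
    "Embedding",
    "log_normalize",
    "rc_normalize",
    "compute_pc_embedding",
    "downsample_equal",
    "select_high_expressors",
]

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cell embedding: coords are cells x d, in the source dataset's cell order."""

    coords: np.ndarray
    basis: str  # "PC" or "UMAP2D"
    n_components: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding contains non-finite values")


def _counts_and_totals(dataset: CohortDataset | sp.spmatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    counts = dataset.counts if isinstance(dataset, CohortDataset) else sp.csr_matrix(dataset)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise ValidationError(f"{bad} cell(s) with zero total counts")
    return sp.csr_matrix(counts), totals


def _scale_cells(counts: sp.csr_matrix, totals: np.ndarray, scale: float) -> sp.csr_matrix:
    out = sp.csc_matrix(counts, dtype=float, copy=True)
    # scale each column (cell) by scale/total; zeros stay exactly zero
    out.data *= np.repeat(scale / totals, np.diff(out.indptr))
    return sp.csr_matrix(out)


def log_normalize(dataset: CohortDataset | sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Per-cell global scaling: ln(1 + count / total * scale), genes x cells."""
    counts, totals = _counts_and_totals(dataset)
    out = _scale_cells(counts, totals, scale)
    out.data = np.log1p(out.data)
    return out


def rc_normalize(dataset: CohortDataset | sp.spmatrix, scale: float = 1e6) -> sp.csr_matrix:
    """Relative counts: count / total * scale, no log transform."""
    counts, totals = _counts_and_totals(dataset)
    return _scale_cells(counts, totals, scale)


def compute_pc_embedding(
    normalized: sp.spmatrix | np.ndarray,
    n_components: int = 75,
    center: bool = True,
    scale_genes: bool = True,
) -> Embedding:
    """Principal-component scores of a genes x cells normalized matrix.

    Genes are standardized (centered, optionally unit-variance; zero-variance
    genes are dropped with a warning), and scores computed by SVD.  The sign
    of each component is fixed so that its largest-magnitude gene loading is
    positive, making results deterministic.
    """
    x = np.asarray(normalized.todense() if sp.issparse(normalized) else normalized, dtype=float)
    n_genes, n_cells = x.shape
    if n_components >= min(n_genes, n_cells):
        raise AnalysisError(
            f"n_components={n_components} must be < min(n_genes, n_cells)={min(n_genes, n_cells)}"
        )
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    if scale_genes:
        sd = x.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance gene(s) before PCA", int((~keep).sum()))
        x = x[keep] / sd[keep, None]
    # SVD of cells x genes; scores are U * S
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]  # components x genes
    flip = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return Embedding(coords=scores * flip[None, :], basis="PC", n_components=n_components)


def downsample_equal(
    dataset: CohortDataset,
    group_keys: list[str],
    seed: int,
) -> np.ndarray:
    """Boolean cell mask equalizing stratum sizes over the given metadata keys.

    Every stratum defined by ``group_keys`` (typically survival group and
    timepoint) is reduced to the smallest stratum's size by seeded sampling
    without replacement.
    """
    meta = dataset.cell_meta
    groups = meta.groupby(list(group_keys), observed=True, sort=True).indices
    if not groups:
        raise AnalysisError("no strata found")
    sizes = {k: len(v) for k, v in groups.items()}
    empty = [k for k, n in sizes.items() if n == 0]
    if empty:
        raise AnalysisError(f"empty stratum/strata: {empty}")
    target = min(sizes.values())
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(meta), dtype=bool)
    for key in sorted(groups, key=str):
        idx = np.sort(np.asarray(groups[key]))
        chosen = rng.choice(idx, size=target, replace=False)
        mask[chosen] = True
    return mask


def select_high_expressors(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    gene: str,
    quantile: float,
    population: str = "nonzero",
) -> np.ndarray:
    """Boolean mask of cells in the top ``quantile`` of a gene's expression.

    The threshold is the (1-quantile) empirical quantile among expressing
    cells by default (``population="nonzero"``; checkpoint genes are sparse
    and a global quantile of mostly zeros is degenerate) or among all cells
    (``population="all"``).  Ties at the threshold are all included.
    """
    if not 0 < quantile < 1:
        raise AnalysisError("quantile must lie in (0, 1)")
    if population not in ("nonzero", "all"):
        raise AnalysisError("population must be 'nonzero' or 'all'")
    if gene not in gene_ids:
        raise AnalysisError(f"gene {gene!r} not in dataset")
    row = np.asarray(sp.csr_matrix(normalized)[gene_ids.index(gene)].todense()).ravel()
    values = row[row > 0] if population == "nonzero" else row
    if values.size == 0:
        return np.zeros(row.size, dtype=bool)
    threshold = np.quantile(values, 1.0 - quantile)
    mask = row >= threshold
    if population == "nonzero":
        mask &= row > 0
    return mask
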