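"""Expression-side preparation: cell QC, normalization, variable-gene
selection, and principal-component covariates.

Cells are removed on strict inequalities exactly as the QC rules are phrased
(mitochondrial fraction over the cutoff, fewer genes than the minimum, more
genes or more total counts than the doublet cutoffs); the boundaries
themselves are kept. Normalization is median-depth scaling + log1p + per-gene
z-scaling; the pre-scaling log values are retained because the variable-gene
rule and slope interpretation operate on that scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellQcMetrics:
    barcode: str
    total_counts: int
    n_genes: int
    mito_fraction: float


@dataclass(frozen=True)
class QcThresholds:
    """Cell QC cutoffs.

    Defaults: mitochondrial fraction over 6% removed, cells with fewer than
    3000 detected genes removed, and doublet candidates (more than 8000 genes
    or more than 12,500 total counts) removed.
    """

    max_mito_fraction: float = 0.06
    min_genes: int = 3000
    max_genes: int = 8000
    max_total_counts: int = 12500

    def __post_init__(self) -> None:
        if not (self.min_genes < self.max_genes):
            raise ParameterError("min_genes must be < max_genes")
        if min(self.max_mito_fraction, self.min_genes,
               self.max_genes, self.max_total_counts) <= 0:
            raise ParameterError("QC thresholds must be positive")


@dataclass
class NormalizedExpression:
    """Normalized expression on two scales.

    ``lognorm`` is the depth-normalized log1p matrix (genes x cells) on which
    the variable-gene rule operates and on which slopes are interpretable;
    ``scaled`` is the per-gene centered/unit-variance version used for
    correlation and PC covariates.
    """

    genes: list[str]
    barcodes: list[str]
    lognorm: np.ndarray
    scaled: np.ndarray
    variable_genes: list[str] | None = None

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def restrict_to_variable(self) -> "NormalizedExpression":
        if self.variable_genes is None:
            raise ValidationError("variable genes not selected yet")
        keep = [i for i, g in enumerate(self.genes) if g in set(self.variable_genes)]
        return NormalizedExpression(
            [self.genes[i] for i in keep],
            list(self.barcodes),
            self.lognorm[keep, :],
            self.scaled[keep, :],
            list(self.variable_genes),
        )


@dataclass
class CovariateMatrix:
    """Cells x k principal-component scores used as regression covariates."""

    barcodes: list[str]
    components: np.ndarray  # cells x k

    @property
    def k(self) -> int:
        return self.components.shape[1]


def compute_cell_qc(
    counts: ExpressionMatrix, mito_genes: Iterable[str]
) -> list[CellQcMetrics]:
    """Per-cell totals, detected-gene counts, and mitochondrial fraction.

    ``mito_fraction`` is the share of a cell's counts attributed to the
    designated mitochondrial gene set; 0 for an all-zero cell.
    """
    mito = set(mito_genes)
    unknown = mito - set(counts.genes)
    if unknown:
        logger.warning("ignoring %d mito gene ids absent from matrix", len(unknown))
    mito_rows = [i for i, g in enumerate(counts.genes) if g in mito]
    mat = counts.counts
    totals = mat.sum(axis=0)
    n_genes = (mat > 0).sum(axis=0)
    mito_counts = mat[mito_rows, :].sum(axis=0) if mito_rows else np.zeros(mat.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return [
        CellQcMetrics(b, int(totals[j]), int(n_genes[j]), float(frac[j]))
        for j, b in enumerate(counts.barcodes)
    ]


def filter_cells(
    metrics: Sequence[CellQcMetrics], thresholds: QcThresholds
) -> set[str]:
    """Apply the QC rules; returns the kept barcode set.

    A cell is kept iff mito_fraction <= max_mito_fraction, min_genes <=
    n_genes <= max_genes, and total_counts <= max_total_counts. Raises if no
    cell survives.
    """
    removed = {"mito": 0, "min_genes": 0, "max_genes": 0, "max_counts": 0}
    kept: set[str] = set()
    for m in metrics:
        ok = True
        if m.mito_fraction > thresholds.max_mito_fraction:
            removed["mito"] += 1
            ok = False
        if m.n_genes < thresholds.min_genes:
            removed["min_genes"] += 1
            ok = False
        if m.n_genes > thresholds.max_genes:
            removed["max_genes"] += 1
            ok = False
        if m.total_counts > thresholds.max_total_counts:
            removed["max_counts"] += 1
            ok = False
        if ok:
            kept.add(m.barcode)
    logger.info("cell QC: kept %d of %d cells (removed per rule: %s)",
                len(kept), len(metrics), removed)
    if not kept:
        raise ValidationError(
            "cell QC removed every cell; review the thresholds "
            f"(removed per rule: {removed})"
        )
    return kept


def normalize_expression(counts: ExpressionMatrix) -> NormalizedExpression:
    """Median-depth normalization, log1p, then per-gene z-scaling.

    Each cell's counts are rescaled so its total equals the median per-cell
    total, log1p-transformed, and each gene is centered and scaled to unit
    variance (zero-variance genes scale to all-zero rows). Deterministic.
    """
    if len(counts.barcodes) < 2:
        raise ValidationError("normalization requires at least 2 cells")
    mat = counts.counts.astype(float)
    totals = mat.sum(axis=0)
    median_total = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    scale = np.where(totals > 0, median_total / np.maximum(totals, 1e-300), 0.0)
    lognorm = np.log1p(mat * scale[np.newaxis, :])
    means = lognorm.mean(axis=1, keepdims=True)
    sds = lognorm.std(axis=1, ddof=0, keepdims=True)
    scaled = np.where(sds > 0, (lognorm - means) / np.where(sds > 0, sds, 1.0), 0.0)
    return NormalizedExpression(
        list(counts.genes), list(counts.barcodes), lognorm, scaled
    )


def select_variable_genes(
    norm: NormalizedExpression,
    frac_cells: float = 0.80,
    frac_range: float = 0.20,
) -> set[str]:
    """Remove floor/ceiling-saturated genes; keep the variable ones.

    A gene is removed iff at least ``frac_cells`` of cells sit within
    ``frac_range`` of either end of its (pre-scaling) expression range.
    Constant genes are removed. The rule is range-relative, hence invariant
    to per-gene affine transforms.
    """
    mat = norm.lognorm
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    rng = hi - lo
    tail = frac_range * rng
    in_tails = (mat <= lo + tail) | (mat >= hi - tail)
    frac = in_tails.mean(axis=1)
    keep_mask = (rng.ravel() > 0) & (frac < frac_cells)
    kept = {g for g, k in zip(norm.genes, keep_mask) if k}
    norm.variable_genes = sorted(kept)
    logger.info("variable-gene filter: kept %d of %d genes", len(kept), len(norm.genes))
    return kept


def compute_pc_covariates(
    norm: NormalizedExpression, k: int = 15, use_variable_only: bool = True
) -> CovariateMatrix:
    """Top-k principal-component scores of the expression matrix.

    Computed by SVD of the gene-centered cells x genes matrix; component sign
    is fixed by making the largest-magnitude gene loading positive. If k
    meets or exceeds the matrix rank it is reduced with a warning.
    """
    if k < 1:
        raise ParameterError("number of PCs must be >= 1")
    mat = norm.scaled
    if use_variable_only and norm.variable_genes is not None:
        keep = [i for i, g in enumerate(norm.genes) if g in set(norm.variable_genes)]
        mat = mat[keep, :]
    x = mat.T.copy()  # cells x genes
    x -= x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        logger.warning("requested %d PCs but rank is %d; reducing", k, rank)
        k = max(rank, 1)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k, :]
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]
    return CovariateMatrix(list(norm.barcodes), scores)
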