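"""The correlation engine.

Each (SNV locus, gene) pair within one (sample, cell type) group is tested by
ordinary least squares of normalized expression on VAF_RNA with the top
expression principal components as covariates (Matrix-eQTL-style model):

    expr_c = a + beta * VAF_c + sum_j g_j * PC_cj + e_c

over exactly the cells informative for that locus (complete-case; VAF
dropouts are structural). ``beta`` and its t-statistic refer to the VAF
coefficient; the two-sided p comes from the t distribution with
n - (k + 2) residual degrees of freedom. Benjamini-Hochberg q-values are
assigned within the group, and pairs are annotated cis when the SNV lies
inside the correlated gene's transcribed interval.

``ScReqtlModel`` / ``ScReqtlResults`` wrap these operations in a
fit-and-summarize interface; the underlying operations are plain functions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ScreqtlError, ValidationError
from .ge_prep import CovariateMatrix, NormalizedExpression
from .types import GeneModel, SnvLocus
from .vaf import VafMatrix

logger = logging.getLogger(__name__)


class PairSkipped(ScreqtlError):
    """A pair cannot be fitted; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ReqtlRecord:
    """One SNV-gene test result."""

    locus: SnvLocus
    gene_id: str
    beta: float
    t_stat: float
    p_value: float
    q_value: float = float("nan")
    cls: str = "unannotated"
    n_cells: int = 0
    group: tuple[str, str] = ("", "")


def _design_matrix(vaf_values: np.ndarray, covars: np.ndarray | None) -> np.ndarray:
    n = vaf_values.size
    columns = [np.ones(n), vaf_values]
    if covars is not None and covars.size:
        columns.extend(covars.T)
    return np.column_stack(columns)


def _ols_vaf_coefficient(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of each column of y on x; returns (beta, t, p, df) for column 1.

    y is n x G; the VAF regressor is column index 1 of x. Singular designs
    (beyond a constant VAF, which callers reject first) are resolved by QR
    with column pivoting via lstsq.
    """
    n, p = x.shape
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = n * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if diag.size and diag.min() > tol:
        df = n - p
        beta_all = np.linalg.solve(r, q.T @ y)
        r_inv = np.linalg.inv(r)
        xtx_inv = r_inv @ r_inv.T
    else:
        # rank-deficient design (e.g. a constant or all-zero covariate):
        # minimum-norm solution; df counts only the effective rank
        x_pinv = np.linalg.pinv(x)
        beta_all = x_pinv @ y
        xtx_inv = x_pinv @ x_pinv.T
        df = n - int(np.linalg.matrix_rank(x))
    resid = y - x @ beta_all
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t = beta_all[1] / se
    beta = beta_all[1]
    # A numerically perfect fit gives se ~ 0: t is +-inf and p underflows to 0.
    # An all-constant response gives 0/0: report no effect.
    t = np.where(np.isnan(t) & (np.abs(beta) < 1e-12), 0.0, t)
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    p_val = np.where(np.isinf(t), 0.0, p_val)
    return np.atleast_1d(beta), np.atleast_1d(t), np.atleast_1d(p_val), df


def fit_snv_gene(
    vaf: np.ndarray,
    expr: np.ndarray,
    covars: CovariateMatrix | np.ndarray | None = None,
    min_cells: int = 2,
) -> tuple[float, float, float, int]:
    """Fit one SNV-gene pair; returns (beta, t_stat, p_value, n_cells).

    ``vaf`` is a per-cell vector with NaN at non-informative entries; the fit
    uses exactly the informative cells. Raises :class:`PairSkipped` with the
    reason when the VAF is constant or the residual degrees of freedom are
    exhausted.
    """
    vaf = np.asarray(vaf, dtype=float)
    expr = np.asarray(expr, dtype=float)
    cov = covars.components if isinstance(covars, CovariateMatrix) else covars
    informative = np.isfinite(vaf)
    n = int(informative.sum())
    if n < max(min_cells, 2):
        raise PairSkipped(f"insufficient cells ({n} informative)")
    v = vaf[informative]
    if np.ptp(v) == 0:
        raise PairSkipped("degenerate regressor")
    x = _design_matrix(v, cov[informative] if cov is not None else None)
    if x.shape[0] - x.shape[1] <= 0:
        raise PairSkipped("insufficient cells for covariates")
    y = expr[informative][:, np.newaxis]
    beta, t, p, _ = _ols_vaf_coefficient(x, y)
    return float(beta[0]), float(t[0]), float(p[0]), n


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def annotate_cis_trans(
    records: Sequence[ReqtlRecord], genes: Sequence[GeneModel]
) -> list[ReqtlRecord]:
    """Set cls to cis when the SNV lies within the correlated gene, else trans.

    Containment is chromosome match and start <= pos <= end (closed interval,
    strand ignored). Records whose gene has no model are flagged
    ``unannotated`` rather than dropped.
    """
    by_id = {g.gene_id: g for g in genes}
    by_name = {g.gene_name: g for g in genes}
    out = []
    for r in records:
        model = by_id.get(r.gene_id) or by_name.get(r.gene_id)
        if model is None:
            out.append(replace(r, cls="unannotated"))
            continue
        cls = "cis" if model.contains(r.locus.chrom, r.locus.pos) else "trans"
        out.append(replace(r, cls=cls))
    return out


@dataclass
class SkippedPair:
    locus: SnvLocus
    gene_id: str
    reason: str


def run_reqtl(
    m: VafMatrix,
    norm: NormalizedExpression,
    covars: CovariateMatrix | None,
    group: tuple[str, str] = ("", ""),
    min_cells: int = 20,
) -> tuple[list[ReqtlRecord], list[SkippedPair]]:
    """Test every (locus, variable gene) pair in one analysis group.

    Expression enters on its per-gene z-scaled form. q-values are assigned by
    BH across all valid tests in the group; no significance threshold is
    applied here. Returns (records, skipped pairs with reasons).
    """
    if norm.barcodes != m.cells:
        raise ValidationError("VAF matrix and expression cover different cells")
    genes = norm.variable_genes if norm.variable_genes is not None else norm.genes
    gene_rows = [norm.genes.index(g) for g in genes]
    cov = covars.components if covars is not None else None
    if cov is not None and cov.shape[0] != len(m.cells):
        raise ValidationError("covariate matrix covers different cells")
    records: list[ReqtlRecord] = []
    skipped: list[SkippedPair] = []
    if not m.loci or not genes:
        logger.warning("empty locus or gene set for group %s", group)
        return records, skipped
    y_all = norm.scaled[gene_rows, :]
    for i, locus in enumerate(m.loci):
        informative = m.mask[i]
        n = int(informative.sum())
        reason = None
        if n < max(min_cells, 2):
            reason = f"insufficient cells ({n} informative)"
        else:
            v = m.vaf[i, informative]
            if np.ptp(v) == 0:
                reason = "degenerate regressor"
        if reason is None:
            x = _design_matrix(v, cov[informative] if cov is not None else None)
            if x.shape[0] - x.shape[1] <= 0:
                reason = "insufficient cells for covariates"
        if reason is not None:
            skipped.extend(SkippedPair(locus, g, reason) for g in genes)
            continue
        y = y_all[:, informative].T  # n x G
        beta, t, p, _ = _ols_vaf_coefficient(x, y)
        for g, b_, t_, p_ in zip(genes, beta, t, p):
            records.append(ReqtlRecord(
                locus=locus, gene_id=g, beta=float(b_), t_stat=float(t_),
                p_value=float(p_), n_cells=n, group=group,
            ))
    if records:
        q = bh_fdr([r.p_value for r in records])
        for r, qv in zip(records, q):
            r.q_value = qv
    logger.info("group %s: %d tests, %d skipped pairs", group, len(records),
                len(skipped))
    return records, skipped


class ScReqtlModel:
    """SNV-gene correlation model for one (sample, cell type) group.

    Parameters
    ----------
    vaf : VafMatrix
        Filtered loci x cells VAF matrix (informative mask included).
    expression : NormalizedExpression
        Normalized expression over the same cells; ``variable_genes``
        restricts the tested gene set when present.
    covariates : CovariateMatrix, optional
        Expression principal-component scores (cells x k).
    gene_models : sequence of GeneModel, optional
        Needed for cis/trans annotation of the results.
    """

    def __init__(
        self,
        vaf: VafMatrix,
        expression: NormalizedExpression,
        covariates: CovariateMatrix | None = None,
        gene_models: Sequence[GeneModel] | None = None,
        group: tuple[str, str] = ("", ""),
        min_cells: int = 20,
    ):
        self.vaf = vaf
        self.expression = expression
        self.covariates = covariates
        self.gene_models = list(gene_models) if gene_models is not None else None
        self.group = group
        self.min_cells = min_cells

    def fit(self) -> "ScReqtlResults":
        records, skipped = run_reqtl(
            self.vaf, self.expression, self.covariates,
            group=self.group, min_cells=self.min_cells,
        )
        if self.gene_models is not None:
            records = annotate_cis_trans(records, self.gene_models)
        return ScReqtlResults(self, records, skipped)


class ScReqtlResults:
    """Fitted SNV-gene association results for one analysis group."""

    def __init__(self, model: ScReqtlModel, records: list[ReqtlRecord],
                 skipped: list[SkippedPair]):
        self.model = model
        self.records = records
        self.skipped = skipped

    @property
    def frame(self) -> pd.DataFrame:
        rows = [{
            "snv": r.locus.label, "gene": r.gene_id, "beta": r.beta,
            "t": r.t_stat, "p": r.p_value, "q": r.q_value, "class": r.cls,
            "n_cells": r.n_cells,
        } for r in self.records]
        df = pd.DataFrame(
            rows, columns=["snv", "gene", "beta", "t", "p", "q", "class", "n_cells"]
        )
        if len(df):
            df = df.sort_values(["q", "snv", "gene"], kind="mergesort")
        return df.reset_index(drop=True)

    def significant(self, fdr: float = 0.05) -> list[ReqtlRecord]:
        return [r for r in self.records if r.q_value <= fdr]

    def summary(self, fdr: float = 0.05) -> str:
        sig = self.significant(fdr)
        n_cis = sum(1 for r in sig if r.cls == "cis")
        n_trans = sum(1 for r in sig if r.cls == "trans")
        lines = [
            "scReQTL results",
            "=" * 54,
            f"group (sample, cell type):  {self.model.group}",
            f"loci tested:                {len(self.model.vaf.loci)}",
            f"genes tested:               "
            f"{len(self.model.expression.variable_genes or self.model.expression.genes)}",
            f"pairs fitted:               {len(self.records)}",
            f"pairs skipped:              {len(self.skipped)}",
            f"significant at q <= {fdr:g}:   {len(sig)} "
            f"({n_cis} cis, {n_trans} trans)",
            "=" * 54,
        ]
        top = self.frame.head(10)
        if len(top):
            lines.append(top.to_string(index=False,
                                       float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)
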