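"""Variant allele fraction (VAF_RNA) matrix construction and SNV-side filters.

VAF_RNA = n_var / (n_var + n_ref) at a biallelic locus in one cell. An entry
is *informative* when its UMI-deduplicated coverage meets minR. Loci pass
through four ordered filters: pooled biallelic selection (>= 50 reads per
allele across all cells), the minR informativeness mask, the non-variability
bands (loci dominated by stable-biallelic [0.4, 0.6] or monoallelic/skewed
[0, 0.25] u [0.75, 1] VAFs are dropped), and a minimum informative-cell
count (>= 20).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import ceil, comb
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .io import AlleleCountTable
from .types import SnvLocus

logger = logging.getLogger(__name__)


@dataclass
class VafMatrix:
    """Loci x cells VAF_RNA values with coverage and informativeness mask."""

    loci: list[SnvLocus]
    cells: list[str]
    vaf: np.ndarray       # loci x cells; NaN where not informative
    coverage: np.ndarray  # loci x cells total deduplicated reads
    mask: np.ndarray      # loci x cells bool, True where coverage >= minR
    minR: int = 10

    def informative_counts(self) -> np.ndarray:
        """Number of informative cells per locus."""
        return self.mask.sum(axis=1)

    def subset_loci(self, loci: Sequence[SnvLocus]) -> "VafMatrix":
        index = {l: i for i, l in enumerate(self.loci)}
        rows = [index[l] for l in loci]
        return VafMatrix(
            list(loci), list(self.cells),
            self.vaf[rows, :], self.coverage[rows, :], self.mask[rows, :],
            self.minR,
        )


@dataclass(frozen=True)
class VariabilityBands:
    """Band definitions for the non-variability filters.

    A locus is non-variable when more than ``frac`` of its informative VAFs
    fall in the stable-biallelic band or in the union of the monoallelic
    bands. All intervals are closed.
    """

    stable_band: tuple[float, float] = (0.4, 0.6)
    mono_low: tuple[float, float] = (0.0, 0.25)
    mono_high: tuple[float, float] = (0.75, 1.0)
    frac: float = 0.75

    def __post_init__(self) -> None:
        for lo, hi in (self.stable_band, self.mono_low, self.mono_high):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ParameterError(f"band ({lo}, {hi}) outside [0, 1]")
        if not (0.0 < self.frac < 1.0):
            raise ParameterError("dominance fraction must be in (0, 1)")


def pool_allele_counts(table: AlleleCountTable) -> dict[SnvLocus, tuple[int, int]]:
    """Sum n_ref and n_var per locus across all cells."""
    grouped = table.frame.groupby(
        ["chrom", "pos", "ref", "alt"], sort=False
    )[["n_ref", "n_var"]].sum()
    return {
        SnvLocus(chrom, int(pos), ref, alt): (int(row["n_ref"]), int(row["n_var"]))
        for (chrom, pos, ref, alt), row in grouped.iterrows()
    }


def select_biallelic_loci(
    pooled: Mapping[SnvLocus, tuple[int, int]],
    min_reads_per_allele: int = 50,
) -> set[SnvLocus]:
    """Keep loci with >= min_reads_per_allele pooled reads for *both* alleles."""
    kept = {
        locus for locus, (n_ref, n_var) in pooled.items()
        if n_ref >= min_reads_per_allele and n_var >= min_reads_per_allele
    }
    logger.info("biallelic selection: kept %d of %d loci", len(kept), len(pooled))
    return kept


def build_vaf_matrix(
    table: AlleleCountTable,
    cells: Sequence[str],
    loci: Sequence[SnvLocus],
    minR: int = 10,
) -> VafMatrix:
    """Assemble the loci x cells VAF matrix for one analysis group.

    Absent (locus, cell) records mean zero coverage. An entry is informative
    iff n_ref + n_var >= minR; VAF is defined only there (NaN elsewhere).
    """
    if minR < 1:
        raise ParameterError(f"minR must be >= 1, got {minR}")
    loci = sorted(set(loci))
    cells = list(cells)
    locus_index = {l: i for i, l in enumerate(loci)}
    cell_index = {c: j for j, c in enumerate(cells)}
    coverage = np.zeros((len(loci), len(cells)), dtype=int)
    n_var = np.zeros_like(coverage)
    df = table.frame
    for row in df.itertuples(index=False):
        locus = SnvLocus(row.chrom, int(row.pos), row.ref, row.alt)
        i = locus_index.get(locus)
        j = cell_index.get(row.barcode)
        if i is None or j is None:
            continue
        coverage[i, j] = row.n_ref + row.n_var
        n_var[i, j] = row.n_var
    mask = coverage >= minR
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(mask, n_var / np.maximum(coverage, 1), np.nan)
    return VafMatrix(loci, cells, vaf, coverage, mask, minR)


def filter_nonvariable_loci(
    m: VafMatrix,
    bands: VariabilityBands | None = None,
    strict_variable_band: bool = False,
) -> set[SnvLocus]:
    """Drop loci whose informative VAFs are dominated by a non-variable band.

    Default rule: a locus is removed iff more than ``bands.frac`` of its
    informative VAFs lie in the stable band, or more than ``bands.frac`` lie
    in the monoallelic band union (dominance strictly greater than the
    fraction). Loci with zero informative entries are removed.

    ``strict_variable_band=True`` switches to the stricter formulation that a
    locus is *kept* only when at least ``bands.frac`` of informative VAFs lie
    inside the variable bands [0.25, 0.4] u [0.6, 0.75].
    """
    bands = bands or VariabilityBands()
    kept: set[SnvLocus] = set()
    reasons: dict[str, int] = {"no_informative": 0, "stable": 0, "mono": 0,
                               "not_variable": 0}
    for i, locus in enumerate(m.loci):
        values = m.vaf[i, m.mask[i]]
        n = values.size
        if n == 0:
            reasons["no_informative"] += 1
            continue
        if strict_variable_band:
            in_var = (((values >= bands.mono_low[1]) & (values <= bands.stable_band[0]))
                      | ((values >= bands.stable_band[1]) & (values <= bands.mono_high[0])))
            if in_var.sum() / n >= bands.frac:
                kept.add(locus)
            else:
                reasons["not_variable"] += 1
            continue
        in_stable = ((values >= bands.stable_band[0])
                     & (values <= bands.stable_band[1])).sum()
        in_mono = (((values >= bands.mono_low[0]) & (values <= bands.mono_low[1]))
                   | ((values >= bands.mono_high[0]) & (values <= bands.mono_high[1]))).sum()
        if in_stable / n > bands.frac:
            reasons["stable"] += 1
        elif in_mono / n > bands.frac:
            reasons["mono"] += 1
        else:
            kept.add(locus)
    logger.info("variability filter: kept %d of %d loci (removed: %s)",
                len(kept), len(m.loci), reasons)
    return kept


def filter_min_cells(m: VafMatrix, min_cells: int = 20) -> set[SnvLocus]:
    """Keep loci informative in at least ``min_cells`` cells (inclusive)."""
    counts = m.informative_counts()
    kept = {locus for locus, n in zip(m.loci, counts) if n >= min_cells}
    logger.info("min-cells filter: kept %d of %d loci", len(kept), len(m.loci))
    return kept


def chance_variability_probability(
    n_cells: int, frac: float = 0.75, p: float = 0.5
) -> float:
    """Probability of a locus looking variable purely by chance.

    Exact binomial tail P(X >= ceil(frac * n_cells)) for X ~ Bin(n_cells, p):
    the chance that, with per-cell probability ``p`` of landing in the
    variable range, at least the dominance fraction of cells do so. At the
    defaults (20 cells, 75%, p = 0.5) this is 21700/2^20 ~ 0.0206.
    """
    if not isinstance(n_cells, (int, np.integer)) or isinstance(n_cells, bool):
        raise ParameterError("n_cells must be an integer")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if not (0.0 < p < 1.0):
        raise ParameterError("p must be in (0, 1)")
    threshold = ceil(frac * n_cells)
    exact = chance_variability_fraction(n_cells, frac, p)
    if exact is not None:
        return float(exact)
    tail = sum(
        comb(n_cells, k) * p**k * (1 - p) ** (n_cells - k)
        for k in range(threshold, n_cells + 1)
    )
    return float(min(tail, 1.0))


def chance_variability_fraction(
    n_cells: int, frac: float = 0.75, p: float = 0.5
) -> Fraction | None:
    """Exact rational binomial tail, when ``p`` is exactly representable.

    Returns None for irrational-float ``p`` values that cannot be expressed
    as a small fraction; the float wrapper then falls back to summation.
    """
    p_frac = Fraction(p).limit_denominator(10**6)
    if float(p_frac) != p:
        return None
    threshold = ceil(frac * n_cells)
    q_frac = 1 - p_frac
    return sum(
        comb(n_cells, k) * p_frac**k * q_frac ** (n_cells - k)
        for k in range(threshold, n_cells + 1)
    )
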