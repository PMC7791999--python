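"""Post-hoc statistics: permutation enrichment of trans SNV-gene pairs in a
known gene-gene interaction set, and chi-square overlap comparisons.

The permutation test draws, for each permutation, a random set of distinct
unordered gene pairs of the same size as the observed set from the analysis
gene universe, and the p-value is the fraction of permutations whose overlap
with the interaction set meets or exceeds the observed overlap.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """An unordered pair of distinct genes (canonical form sorts the ids)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a!r} is not allowed")
        if self.gene_a > self.gene_b:
            lo, hi = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", lo)
            object.__setattr__(self, "gene_b", hi)

    @staticmethod
    def of(a: str, b: str) -> "GenePair":
        lo, hi = sorted((a, b))
        return GenePair(lo, hi)


@dataclass
class EnrichmentResult:
    observed_overlap: int
    n_pairs: int
    n_permutations: int
    permutation_overlaps: list[int]
    p_value: float
    seed: int

    def formatted_p(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def pair_overlap(pairs: Iterable[GenePair], interactions: Iterable[GenePair]) -> int:
    """Size of the intersection under unordered-pair equality."""
    return len(set(pairs) & set(interactions))


def _unrank_pair(index: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map lexicographic pair index in [0, C(n,2)) to (i, j), i < j."""
    # pairs with first element < i occupy the first i*(2n-1-i)/2 indices
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * index)) / 2).astype(np.int64)
    offset = i * n - (i * (i + 1)) // 2
    j = index - offset + i + 1
    return i, j


def permutation_enrichment(
    pairs: Iterable[GenePair],
    universe: Sequence[str],
    interactions: Iterable[GenePair],
    n_perm: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for enrichment of observed pairs in an interaction set.

    Each permutation draws ``len(pairs)`` distinct unordered pairs uniformly
    from all pairs over ``universe`` (no self-pairs, no duplicates within a
    permutation) and counts the overlap with ``interactions``; p is the
    fraction of permutations whose overlap is at least the observed overlap.
    Bit-reproducible given (seed, n_perm).
    """
    pairs = set(pairs)
    interactions = set(interactions)
    universe = sorted(set(universe))
    n = len(universe)
    n_pairs = len(pairs)
    if n_pairs < 1:
        raise ParameterError("at least one observed pair is required")
    total_pairs = n * (n - 1) // 2
    if total_pairs < n_pairs:
        raise ParameterError(
            f"universe of {n} genes cannot form {n_pairs} distinct pairs"
        )
    observed = pair_overlap(pairs, interactions)
    index_of = {g: i for i, g in enumerate(universe)}
    interaction_codes = set()
    for p in interactions:
        ia, ib = index_of.get(p.gene_a), index_of.get(p.gene_b)
        if ia is None or ib is None:
            continue
        lo, hi = (ia, ib) if ia < ib else (ib, ia)
        interaction_codes.add(lo * n + hi)
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_perm, dtype=int)
    for it in range(n_perm):
        drawn = rng.choice(total_pairs, size=n_pairs, replace=False)
        i, j = _unrank_pair(drawn.astype(np.int64), n)
        codes = i * n + j
        overlaps[it] = sum(1 for c in codes if int(c) in interaction_codes)
    p_value = float((overlaps >= observed).sum() / n_perm)
    logger.info("permutation enrichment: observed %d/%d, p = %s",
                observed, n_pairs, p_value)
    return EnrichmentResult(
        observed_overlap=observed,
        n_pairs=n_pairs,
        n_permutations=n_perm,
        permutation_overlaps=overlaps.tolist(),
        p_value=p_value,
        seed=seed,
    )


def overlap_chi_square(
    hits_a: int, total_a: int, hits_b: int, total_b: int,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square comparing two overlap proportions (1 df).

    The 2x2 table is [[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]].
    Raises when any expected cell is zero (an exact test is then advisable).
    """
    if total_a <= 0 or total_b <= 0:
        raise ParameterError("totals must be positive")
    if hits_a > total_a or hits_b > total_b:
        raise ParameterError("hits cannot exceed totals")
    table = np.array([[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]])
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValidationError(
            "zero expected cell in the 2x2 table; use an exact test instead"
        )
    if np.array_equal(table[0], table[1]):
        return 0.0, 1.0
    result = stats.chi2_contingency(table, correction=continuity_correction)
    return float(result.statistic), float(result.pvalue)


def read_interaction_pairs(
    path: str | Path, min_score: float | None = None
) -> set[GenePair]:
    """Read a 2-column TSV of interacting gene symbols.

    An optional third numeric column is treated as a confidence score and
    thresholded by ``min_score``; by default any listed pair counts.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: interaction list needs at least 2 columns")
    pairs: set[GenePair] = set()
    for row in df.itertuples(index=False):
        if min_score is not None and df.shape[1] >= 3:
            try:
                score = float(row[2])
            except (TypeError, ValueError):
                raise ValidationError(f"{path}: non-numeric interaction score {row[2]!r}")
            if score < min_score:
                continue
        pairs.add(GenePair.of(str(row[0]), str(row[1])))
    return pairs


def write_interaction_pairs(pairs: Iterable[GenePair], path: str | Path) -> None:
    with open(path, "w") as out:
        for p in sorted(pairs, key=lambda x: (x.gene_a, x.gene_b)):
            out.write(f"{p.gene_a}\t{p.gene_b}\n")
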