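"""Domain objects shared across the pipeline.

Coordinates are 1-based inclusive throughout (VCF/GTF convention); BED input
is converted at the I/O boundary. A locus is identified by the 4-tuple
(chrom, pos, ref, alt), written in text output as ``chrom:pos_ref>alt``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ValidationError

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SnvLocus:
    """A biallelic single-nucleotide variant locus."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"locus position must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValidationError(
                f"ref/alt must be single nucleotides A/C/G/T, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}_{self.ref}>{self.alt}"

    @classmethod
    def from_label(cls, label: str) -> "SnvLocus":
        m = re.fullmatch(r"(.+):(\d+)_([ACGT])>([ACGT])", label.strip())
        if m is None:
            raise ValidationError(f"cannot parse SNV label {label!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3), m.group(4))


@dataclass(frozen=True)
class AlleleCountRecord:
    """Deduplicated reference/variant read counts at one locus in one cell."""

    locus: SnvLocus
    barcode: str
    n_ref: int
    n_var: int

    def __post_init__(self) -> None:
        if self.n_ref < 0 or self.n_var < 0:
            raise ValidationError(
                f"negative allele count at {self.locus.label} / {self.barcode}"
            )


@dataclass(frozen=True)
class GeneModel:
    """One gene's transcribed interval (introns and UTRs included)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        """Positional containment; strand is deliberately ignored."""
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class CellAnnotation:
    """Assignment of one cell barcode to a donor/sample and a cell type."""

    barcode: str
    sample_id: str
    cell_type: str
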