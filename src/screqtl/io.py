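"""Readers and writers for every external file the pipeline touches.

All formats are plain text (optionally gzipped): allele counts as a headered
TSV, expression as MatrixMarket triplets with features/barcodes sidecars or as
a dense TSV with genes in rows, gene models as GTF or BED6, cell annotations
and result tables as TSV. Every reader validates strictly and every
write/read pair round-trips at full text precision.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError
from .types import AlleleCountRecord, CellAnnotation, GeneModel, SnvLocus

logger = logging.getLogger(__name__)

#: SCReadCounts-style default header for allele-count tables.
DEFAULT_ALLELE_DIALECT: Mapping[str, str] = {
    "chrom": "CHROM",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "barcode": "ReadGroup",
    "n_ref": "SNVCountRef",
    "n_var": "SNVCount",
}

_ALLELE_COLUMNS = ("chrom", "pos", "ref", "alt", "barcode", "n_ref", "n_var")


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class AlleleCountTable:
    """Long-format (locus, cell) -> (n_ref, n_var) observations.

    Backed by a DataFrame with columns chrom, pos, ref, alt, barcode,
    n_ref, n_var; at most one row per (locus, barcode). An absent row means
    zero coverage for that pair.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ALLELE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"allele count table missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)
        if (self.frame[["n_ref", "n_var"]] < 0).any().any():
            raise ValidationError("negative allele counts")
        key = ["chrom", "pos", "ref", "alt", "barcode"]
        dup = self.frame.duplicated(subset=key)
        if dup.any():
            first = self.frame.loc[dup.idxmax(), key].tolist()
            raise ValidationError(
                f"duplicate (locus, barcode) record: {first}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        a = self.frame.sort_values(list(_ALLELE_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(_ALLELE_COLUMNS)).reset_index(drop=True)
        return a[list(_ALLELE_COLUMNS)].equals(b[list(_ALLELE_COLUMNS)])

    @classmethod
    def from_records(cls, records: Iterable[AlleleCountRecord]) -> "AlleleCountTable":
        rows = [
            (r.locus.chrom, r.locus.pos, r.locus.ref, r.locus.alt,
             r.barcode, r.n_ref, r.n_var)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(_ALLELE_COLUMNS))
        if frame.empty:
            frame = frame.astype({"pos": int, "n_ref": int, "n_var": int})
        return cls(frame)

    def to_records(self) -> list[AlleleCountRecord]:
        return [
            AlleleCountRecord(
                SnvLocus(row.chrom, int(row.pos), row.ref, row.alt),
                row.barcode, int(row.n_ref), int(row.n_var),
            )
            for row in self.frame.itertuples(index=False)
        ]

    def loci(self) -> list[SnvLocus]:
        uniq = self.frame[["chrom", "pos", "ref", "alt"]].drop_duplicates()
        return sorted(
            SnvLocus(r.chrom, int(r.pos), r.ref, r.alt)
            for r in uniq.itertuples(index=False)
        )

    def barcodes(self) -> list[str]:
        return sorted(self.frame["barcode"].unique())


def read_allele_counts(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> AlleleCountTable:
    """Read a long-format allele-count TSV (SCReadCounts-style by default).

    ``dialect`` maps the internal field names (chrom, pos, ref, alt, barcode,
    n_ref, n_var) to the column names actually present in the file header.
    """
    path = Path(path)
    dialect = dict(DEFAULT_ALLELE_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for internal, column in dialect.items():
        if column not in df.columns:
            raise FormatError(
                f"{path}: required column {column!r} (for field {internal!r}) "
                f"not found in header {list(df.columns)}"
            )
    df = df.rename(columns={v: k for k, v in dialect.items()})[list(_ALLELE_COLUMNS)]
    for col in ("pos", "n_ref", "n_var"):
        try:
            values = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-integer value in column {col}: {exc}")
        bad = values < 0 if col != "pos" else values < 1
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValidationError(
                f"{path}, line {line}: invalid value {values[bad.idxmax()]} in column {col}"
            )
        df[col] = values
    table = AlleleCountTable(df)
    logger.info("read %d allele-count records from %s", len(table), path)
    return table


def write_allele_counts(
    table: AlleleCountTable,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    dialect = dict(DEFAULT_ALLELE_DIALECT if dialect is None else dialect)
    out = table.frame[list(_ALLELE_COLUMNS)].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with gene and barcode labels."""

    genes: list[str]
    barcodes: list[str]
    counts: np.ndarray  # dense genes x cells

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"expression matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative expression counts")

    def subset_cells(self, barcodes: Sequence[str]) -> "ExpressionMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        cols = [index[b] for b in barcodes]
        return ExpressionMatrix(list(self.genes), list(barcodes), self.counts[:, cols])


def read_expression_matrix(
    path: str | Path,
    layout: str = "mtx-triplet",
) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    ``mtx-triplet``: a directory holding matrix.mtx, features.tsv (gene ids in
    the first column) and barcodes.tsv; the on-disk matrix is genes x cells.
    ``dense-tsv``: a TSV with gene ids in the first column and barcodes in the
    header.
    """
    path = Path(path)
    if layout == "mtx-triplet":
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for p in (mtx, feat, bars):
            if not p.exists():
                raise FormatError(f"mtx-triplet layout: missing {p}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:
            raise FormatError(f"{mtx}: unreadable MatrixMarket file: {exc}")
        genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(bars, sep="\t", header=None)[0].astype(str).tolist()
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        if dense.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"{mtx}: matrix is {dense.shape} but sidecars declare "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        if not np.allclose(dense, np.round(dense)):
            raise ValidationError(f"{mtx}: non-integer entries in count matrix")
        counts = dense
    elif layout == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = df.index.astype(str).tolist()
        barcodes = df.columns.astype(str).tolist()
        counts = df.to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError(f"{path}: non-integer entries in count matrix")
    else:
        raise FormatError(f"unknown expression layout {layout!r}")
    matrix = ExpressionMatrix(genes, barcodes, counts)
    logger.info(
        "read %d genes x %d cells from %s", len(genes), len(barcodes), path
    )
    return matrix


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    layout: str = "mtx-triplet",
) -> None:
    path = Path(path)
    if layout == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
        pd.Series(matrix.genes).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        pd.Series(matrix.barcodes).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
    elif layout == "dense-tsv":
        df = pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.barcodes)
        df.to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown expression layout {layout!r}")


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive) or BED6 (0-based half-open).

    GTF: only records with feature type ``gene`` are used and must carry a
    ``gene_id`` attribute. BED intervals are converted to 1-based inclusive.
    """
    path = Path(path)
    models: dict[str, GeneModel] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gtf":
                if len(fields) < 9:
                    raise FormatError(f"{path}, line {lineno}: expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                if "gene_id" not in attrs:
                    raise FormatError(
                        f"{path}, line {lineno}: gene record without gene_id attribute"
                    )
                model = GeneModel(
                    gene_id=attrs["gene_id"],
                    gene_name=attrs.get("gene_name", attrs["gene_id"]),
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                )
            elif format == "bed":
                if len(fields) < 6:
                    raise FormatError(f"{path}, line {lineno}: expected 6 BED columns")
                model = GeneModel(
                    gene_id=fields[3],
                    gene_name=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]) + 1,  # 0-based half-open -> 1-based inclusive
                    end=int(fields[2]),
                    strand=fields[5] if fields[5] in "+-" else "+",
                )
            else:
                raise FormatError(f"unknown gene model format {format!r}")
            previous = models.get(model.gene_id)
            if previous is not None and previous != model:
                raise ValidationError(
                    f"{path}: duplicate gene_id {model.gene_id} with conflicting coordinates"
                )
            models[model.gene_id] = model
    logger.info("read %d gene models from %s", len(models), path)
    return list(models.values())


def write_gene_models(models: Sequence[GeneModel], path: str | Path,
                      format: str = "gtf") -> None:
    path = Path(path)
    with open(path, "w") as out:
        for m in models:
            if format == "gtf":
                attrs = f'gene_id "{m.gene_id}"; gene_name "{m.gene_name}";'
                out.write(
                    f"{m.chrom}\tscreqtl\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            elif format == "bed":
                out.write(
                    f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n"
                )
            else:
                raise FormatError(f"unknown gene model format {format!r}")


def read_cell_annotations(path: str | Path) -> list[CellAnnotation]:
    """Read a barcode / sample_id / cell_type TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("barcode", "sample_id", "cell_type")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {missing}")
    if df["barcode"].duplicated().any():
        raise ValidationError(f"{path}: duplicate barcode annotation")
    return [
        CellAnnotation(r.barcode, r.sample_id, r.cell_type)
        for r in df.itertuples(index=False)
    ]


def write_cell_annotations(annotations: Sequence[CellAnnotation],
                           path: str | Path) -> None:
    pd.DataFrame(
        [(a.barcode, a.sample_id, a.cell_type) for a in annotations],
        columns=["barcode", "sample_id", "cell_type"],
    ).to_csv(path, sep="\t", index=False)


REQTL_COLUMNS = ["snv", "gene", "beta", "t", "p", "q", "class", "n_cells"]


def write_reqtl_table(records: Sequence, path: str | Path) -> None:
    """Write SNV-gene association records as TSV.

    Rows are ordered deterministically by (q ascending, snv, gene); numeric
    fields are written with 12 significant digits.
    """
    rows = []
    for r in records:
        for value in (r.beta, r.t_stat, r.p_value, r.q_value):
            if not np.isfinite(value):
                raise ValidationError(
                    f"non-finite statistic for {r.locus.label} / {r.gene_id}"
                )
        rows.append({
            "snv": r.locus.label,
            "gene": r.gene_id,
            "beta": r.beta,
            "t": r.t_stat,
            "p": r.p_value,
            "q": r.q_value,
            "class": r.cls,
            "n_cells": r.n_cells,
        })
    df = pd.DataFrame(rows, columns=REQTL_COLUMNS)
    if len(df):
        df = df.sort_values(["q", "snv", "gene"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_reqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: result table missing columns {missing}")
    return df
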