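"""Synthetic-data generator with known ground truth.

Emulates the statistical structure the method assumes, without modelling a
full transcriptome: per-(locus, cell) coverage is negative-binomial with
dropout; each locus follows one of three allelic archetypes — stable
biallelic (latent per-cell VAF tight around 0.5), monoallelic/skewed (tight
around 0.05 or 0.95), or variable (broadly spread across the central VAF
range); variant-supporting reads are binomial in the latent VAF; expression
counts are log-normal per gene, with planted SNV-gene effects acting as
``beta * latent VAF`` on the log scale. Everything is reproducible from the
config seed, and the planted truth is returned alongside the data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import (
    AlleleCountTable, ExpressionMatrix,
    write_allele_counts, write_cell_annotations, write_expression_matrix,
    write_gene_models,
)
from .types import AlleleCountRecord, CellAnnotation, GeneModel, SnvLocus

logger = logging.getLogger(__name__)

ARCHETYPES = ("variable", "stable", "mono")


@dataclass(frozen=True)
class PlantedEffect:
    """A true linear effect of one locus's allelic ratio on one gene."""

    locus_index: int
    gene_index: int
    beta: float
    noise_sd: float = 0.5


@dataclass
class SimConfig:
    """Generator settings; the defaults define the simulated study conditions.

    ``locus_archetypes`` gives the proportion of variable, stable-biallelic,
    and monoallelic/skewed loci. ``vaf_concentration`` is the Beta
    concentration of per-cell latent VAFs around the stable/mono archetype
    means; variable loci instead draw latent VAFs from a broad symmetric Beta
    (``variable_spread_concentration``) so most cells fall between 0.25 and
    0.75. Coverage is NB(mean, dispersion) per (locus, cell), zeroed with
    probability ``dropout_rate``.
    """

    n_cells: int = 200
    n_genes: int = 100
    n_loci: int = 20
    locus_archetypes: dict = field(
        default_factory=lambda: {"variable": 0.25, "stable": 0.5, "mono": 0.25}
    )
    coverage_mean: float = 25.0
    coverage_dispersion: float = 5.0
    dropout_rate: float = 0.2
    vaf_concentration: float = 60.0
    variable_spread_concentration: float = 6.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    expression_baseline: tuple[float, float] = (3.4, 1.0)  # log-mean, log-sd
    expression_noise_sd: float = 0.5
    n_cell_types: int = 1
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.locus_archetypes.get(a, 0.0) for a in ARCHETYPES)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("archetype proportions must sum to 1")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ParameterError("dropout_rate must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ParameterError("coverage parameters must be positive")
        if min(self.n_cells, self.n_genes, self.n_loci) < 1:
            raise ParameterError("n_cells, n_genes, n_loci must be >= 1")
        for e in self.planted_effects:
            if not (0 <= e.locus_index < self.n_loci):
                raise ParameterError(f"planted locus index {e.locus_index} out of range")
            if not (0 <= e.gene_index < self.n_genes):
                raise ParameterError(f"planted gene index {e.gene_index} out of range")
        labels = archetype_labels(self)
        for e in self.planted_effects:
            if labels[e.locus_index] == "mono":
                raise ParameterError(
                    f"planted effect on monoallelic locus {e.locus_index}: "
                    "undetectable by design (no VAF variation survives filtering)"
                )


def archetype_labels(config: SimConfig) -> list[str]:
    """Deterministic archetype per locus (variable loci come first)."""
    counts = {}
    remaining = config.n_loci
    for name in ("variable", "stable"):
        counts[name] = round(config.locus_archetypes.get(name, 0.0) * config.n_loci)
        remaining -= counts[name]
    counts["mono"] = remaining
    if counts["mono"] < 0:
        overflow = -counts["mono"]
        counts["stable"] -= overflow
        counts["mono"] = 0
    labels: list[str] = []
    for name in ("variable", "stable", "mono"):
        labels.extend([name] * counts[name])
    return labels[: config.n_loci]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated dataset."""

    loci: list[SnvLocus]
    genes: list[str]
    barcodes: list[str]
    archetypes: list[str]
    latent_vaf: np.ndarray                       # loci x cells
    true_slopes: dict[tuple[int, int], float]    # (locus idx, gene idx) -> beta

    def slope(self, locus_index: int, gene_index: int) -> float:
        return self.true_slopes.get((locus_index, gene_index), 0.0)


@dataclass
class SyntheticDataset:
    allele_counts: AlleleCountTable
    expression: ExpressionMatrix
    gene_models: list[GeneModel]
    annotations: list[CellAnnotation]
    truth: SyntheticTruth


_GENE_SPAN = 1500
_GENE_PITCH = 2000


def _gene_model(g: int) -> GeneModel:
    start = g * _GENE_PITCH + 1
    return GeneModel(
        gene_id=f"G{g:04d}", gene_name=f"G{g:04d}", chrom="chr1",
        start=start, end=start + _GENE_SPAN - 1,
        strand="+" if g % 2 == 0 else "-",
    )


def _locus_position(i: int, n_genes: int) -> tuple[str, int]:
    """Place locus i inside gene (i mod n_genes) so cis pairs exist."""
    g = i % n_genes
    pos = g * _GENE_PITCH + 1 + 500 + (i // n_genes)
    return "chr1", pos


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate allele counts, expression, gene models, annotations, truth."""
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes, n_loci = config.n_cells, config.n_genes, config.n_loci
    barcodes = [f"CELL{c:05d}" for c in range(n_cells)]
    genes = [f"G{g:04d}" for g in range(n_genes)]
    gene_models = [_gene_model(g) for g in range(n_genes)]
    loci = []
    for i in range(n_loci):
        chrom, pos = _locus_position(i, n_genes)
        loci.append(SnvLocus(chrom, pos, "G", "A"))
    labels = archetype_labels(config)

    # Latent per-cell allelic ratio for every locus.
    latent = np.empty((n_loci, n_cells))
    c = config.vaf_concentration
    for i, label in enumerate(labels):
        if label == "stable":
            latent[i] = rng.beta(0.5 * c, 0.5 * c, size=n_cells)
        elif label == "mono":
            mean = 0.05 if i % 2 == 0 else 0.95
            latent[i] = rng.beta(mean * c, (1 - mean) * c, size=n_cells)
        else:  # variable
            a = config.variable_spread_concentration / 2.0
            latent[i] = rng.beta(a, a, size=n_cells)

    # Sequencing coverage and variant-supporting reads.
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    coverage = rng.negative_binomial(r, p_nb, size=(n_loci, n_cells))
    observed = rng.random((n_loci, n_cells)) >= config.dropout_rate
    coverage = np.where(observed, coverage, 0)
    n_var = rng.binomial(coverage, latent)
    records = []
    for i in range(n_loci):
        for j in range(n_cells):
            cov = int(coverage[i, j])
            if cov > 0:
                records.append(AlleleCountRecord(
                    loci[i], barcodes[j], cov - int(n_var[i, j]), int(n_var[i, j])
                ))
    allele_counts = AlleleCountTable.from_records(records)

    # Expression: per-gene log-normal baseline plus planted VAF effects.
    mu, sd = config.expression_baseline
    baseline = rng.normal(mu, sd, size=n_genes)
    noise_sd = np.full(n_genes, config.expression_noise_sd)
    true_slopes: dict[tuple[int, int], float] = {}
    signal = np.zeros((n_genes, n_cells))
    for e in config.planted_effects:
        true_slopes[(e.locus_index, e.gene_index)] = e.beta
        signal[e.gene_index] += e.beta * latent[e.locus_index]
        noise_sd[e.gene_index] = e.noise_sd
    log_expr = (baseline[:, np.newaxis] + signal
                + rng.normal(0.0, 1.0, size=(n_genes, n_cells)) * noise_sd[:, np.newaxis])
    counts = np.round(np.exp(log_expr)).astype(int)
    expression = ExpressionMatrix(genes, barcodes, counts)

    # One cell type by default; multi-type mode blocks the cells per type.
    annotations = []
    per_type = max(1, n_cells // config.n_cell_types)
    for j, b in enumerate(barcodes):
        t = min(j // per_type, config.n_cell_types - 1)
        annotations.append(CellAnnotation(b, config.sample_id, f"type{t + 1}"))

    truth = SyntheticTruth(loci, genes, barcodes, labels, latent, true_slopes)
    logger.info("generated %d loci x %d cells (%d allele records), %d genes",
                n_loci, n_cells, len(allele_counts), n_genes)
    return SyntheticDataset(allele_counts, expression, gene_models, annotations, truth)


def archetype_recall(
    truth: SyntheticTruth, surviving_loci: Sequence[SnvLocus] | set
) -> dict[str, dict[str, int]]:
    """How the locus filters treated each archetype: retained/removed counts."""
    surviving = set(surviving_loci)
    summary = {a: {"retained": 0, "removed": 0} for a in ARCHETYPES}
    for locus, label in zip(truth.loci, truth.archetypes):
        key = "retained" if locus in surviving else "removed"
        summary[label][key] += 1
    return summary


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all five inputs in the formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "allele_counts": out / "allele_counts.tsv",
        "expression": out / "expression",
        "gene_models": out / "genes.gtf",
        "annotations": out / "cells.tsv",
    }
    write_allele_counts(dataset.allele_counts, paths["allele_counts"])
    write_expression_matrix(dataset.expression, paths["expression"], "mtx-triplet")
    write_gene_models(dataset.gene_models, paths["gene_models"], "gtf")
    write_cell_annotations(dataset.annotations, paths["annotations"])
    return paths
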