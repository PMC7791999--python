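"""End-to-end orchestration: QC -> normalization -> variable genes -> PC
covariates -> VAF matrix -> locus filters -> regression -> FDR -> cis/trans
-> optional enrichment, per (sample, cell type) group, with an audit trail
of every removal decision and a machine-readable run summary.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .enrichment import GenePair, permutation_enrichment, read_interaction_pairs
from .errors import ParameterError, ValidationError
from .ge_prep import (
    QcThresholds, compute_cell_qc, compute_pc_covariates, filter_cells,
    normalize_expression, select_variable_genes,
)
from .io import (
    read_allele_counts, read_cell_annotations, read_expression_matrix,
    read_gene_models, write_reqtl_table, AlleleCountTable,
)
from .model import ReqtlRecord, ScReqtlModel
from .vaf import (
    VariabilityBands, build_vaf_matrix, filter_min_cells,
    filter_nonvariable_loci, pool_allele_counts, select_biallelic_loci,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline settings; mirrors the YAML config file."""

    counts_path: str
    expression_path: str
    genes_path: str
    annotations_path: str
    out_dir: str
    expression_layout: str = "mtx-triplet"
    genes_format: str = "gtf"
    interactions_path: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    bands: VariabilityBands = field(default_factory=VariabilityBands)
    min_reads_per_allele: int = 50
    minR: int = 10
    min_cells: int = 20
    n_pcs: int = 15
    fdr: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    mito_prefix: str = "MT-"
    mito_genes: list[str] | None = None
    strict_variable_band: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ParameterError("fdr must be in (0, 1)")
        if self.minR < 1 or self.min_cells < 1 or self.min_reads_per_allele < 0:
            raise ParameterError("thresholds must be positive")

    def validate_paths(self) -> None:
        for name in ("counts_path", "expression_path", "genes_path",
                     "annotations_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name}: {p} does not exist")
        if self.interactions_path and not Path(self.interactions_path).exists():
            raise ValidationError(
                f"interactions_path: {self.interactions_path} does not exist"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        if "qc" in raw:
            raw["qc"] = QcThresholds(**raw["qc"])
        if "bands" in raw:
            b = raw["bands"]
            raw["bands"] = VariabilityBands(
                stable_band=tuple(b.get("stable_band", (0.4, 0.6))),
                mono_low=tuple(b.get("mono_low", (0.0, 0.25))),
                mono_high=tuple(b.get("mono_high", (0.75, 1.0))),
                frac=b.get("frac", 0.75),
            )
        return cls(**raw)


@dataclass
class PipelineResult:
    records: list[ReqtlRecord]
    summary: dict[str, Any]
    reqtl_path: Path
    summary_path: Path
    audit_path: Path


def _mito_gene_set(config: PipelineConfig, genes: list[str]) -> set[str]:
    if config.mito_genes is not None:
        return set(config.mito_genes)
    return {g for g in genes if g.startswith(config.mito_prefix)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for every (sample, cell type) group.

    Writes ``reqtl.tsv`` (all groups, deterministic order), ``audit.log``
    (every removal decision: entity, rule, values) and ``summary.json``
    (per-group counts at each stage) under ``config.out_dir``.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit: list[str] = []

    counts_table = read_allele_counts(config.counts_path)
    expression = read_expression_matrix(config.expression_path,
                                        config.expression_layout)
    gene_models = read_gene_models(config.genes_path, config.genes_format)
    annotations = read_cell_annotations(config.annotations_path)

    known_barcodes = set(expression.barcodes)
    usable = [a for a in annotations if a.barcode in known_barcodes]
    dropped = len(annotations) - len(usable)
    if dropped:
        logger.warning("%d annotated barcodes absent from expression matrix; "
                       "dropped from analysis", dropped)
        audit.append(f"-\tannotation\t{dropped} barcodes\tabsent from expression matrix")

    # Pooled biallelic selection per sample, over all sample cells (pre-QC).
    samples = sorted({a.sample_id for a in usable})
    biallelic_by_sample: dict[str, set] = {}
    for sample in samples:
        sample_cells = {a.barcode for a in usable if a.sample_id == sample}
        sample_table = AlleleCountTable(
            counts_table.frame[counts_table.frame["barcode"].isin(sample_cells)]
        )
        pooled = pool_allele_counts(sample_table)
        kept = select_biallelic_loci(pooled, config.min_reads_per_allele)
        for locus in set(pooled) - kept:
            audit.append(f"{sample}\tbiallelic\t{locus.label}\t"
                         f"pooled counts {pooled[locus]} below "
                         f"{config.min_reads_per_allele} per allele")
        biallelic_by_sample[sample] = kept

    mito = _mito_gene_set(config, expression.genes)
    groups = sorted({(a.sample_id, a.cell_type) for a in usable})
    all_records: list[ReqtlRecord] = []
    group_summaries: dict[str, Any] = {}

    for sample, cell_type in groups:
        gname = f"{sample}:{cell_type}"
        group_barcodes = [a.barcode for a in usable
                          if a.sample_id == sample and a.cell_type == cell_type]
        sub = expression.subset_cells(group_barcodes)
        metrics = compute_cell_qc(sub, mito)
        kept_cells = filter_cells(metrics, config.qc)
        for m in metrics:
            if m.barcode not in kept_cells:
                audit.append(f"{gname}\tcell_qc\t{m.barcode}\t"
                             f"total={m.total_counts} genes={m.n_genes} "
                             f"mito={m.mito_fraction:.4f}")
        kept_ordered = [b for b in group_barcodes if b in kept_cells]
        if len(kept_ordered) < config.n_pcs + config.min_cells:
            logger.warning("group %s has %d QC-passing cells "
                           "(< n_pcs + min_cells = %d); skipped",
                           gname, len(kept_ordered),
                           config.n_pcs + config.min_cells)
            audit.append(f"{gname}\tgroup\t-\tonly {len(kept_ordered)} cells; skipped")
            group_summaries[gname] = {
                "n_cells_in": len(group_barcodes),
                "n_cells_qc": len(kept_ordered),
                "skipped": True,
            }
            continue

        qc_expr = sub.subset_cells(kept_ordered)
        norm = normalize_expression(qc_expr)
        variable = select_variable_genes(norm)
        for g in norm.genes:
            if g not in variable:
                audit.append(f"{gname}\tvariable_genes\t{g}\tsaturated or constant")
        covars = compute_pc_covariates(norm, k=config.n_pcs)

        loci = sorted(biallelic_by_sample[sample])
        vaf_all = build_vaf_matrix(counts_table, kept_ordered, loci, config.minR)
        variable_loci = filter_nonvariable_loci(
            vaf_all, config.bands, config.strict_variable_band
        )
        for locus in set(vaf_all.loci) - variable_loci:
            audit.append(f"{gname}\tvariability\t{locus.label}\tnon-variable VAF profile")
        vaf_var = vaf_all.subset_loci(sorted(variable_loci))
        final_loci = filter_min_cells(vaf_var, config.min_cells)
        for locus in set(vaf_var.loci) - final_loci:
            audit.append(f"{gname}\tmin_cells\t{locus.label}\t"
                         f"informative in fewer than {config.min_cells} cells")
        if not final_loci:
            raise ValidationError(
                f"group {gname}: no SNV locus survives filtering; "
                "nothing to regress"
            )
        if not variable:
            raise ValidationError(
                f"group {gname}: no variable gene survives filtering"
            )
        vaf_final = vaf_var.subset_loci(sorted(final_loci))

        model = ScReqtlModel(
            vaf_final, norm, covars, gene_models=gene_models,
            group=(sample, cell_type), min_cells=config.min_cells,
        )
        results = model.fit()
        for s in results.skipped:
            audit.append(f"{gname}\tregression\t{s.locus.label}/{s.gene_id}\t{s.reason}")
        sig = results.significant(config.fdr)
        all_records.extend(results.records)
        group_summaries[gname] = {
            "n_cells_in": len(group_barcodes),
            "n_cells_qc": len(kept_ordered),
            "n_genes": len(norm.genes),
            "n_variable_genes": len(variable),
            "n_loci_biallelic": len(loci),
            "n_loci_variable": len(variable_loci),
            "n_loci_final": len(final_loci),
            "n_tests": len(results.records),
            "n_skipped_pairs": len(results.skipped),
            "n_significant": len(sig),
            "n_cis": sum(1 for r in sig if r.cls == "cis"),
            "n_trans": sum(1 for r in sig if r.cls == "trans"),
            "skipped": False,
        }

    summary: dict[str, Any] = {
        "groups": group_summaries,
        "n_groups": len(groups),
        "n_records_total": len(all_records),
        "n_significant_total": sum(
            1 for r in all_records if r.q_value <= config.fdr
        ),
        "fdr": config.fdr,
        "seed": config.seed,
    }

    # Optional enrichment of significant trans pairs in known interactions.
    if config.interactions_path:
        interactions = read_interaction_pairs(config.interactions_path)
        by_id = {g.gene_id: g for g in gene_models}
        harboring = {}
        for r in all_records:
            for g in gene_models:
                if g.contains(r.locus.chrom, r.locus.pos):
                    harboring[r.locus] = g.gene_id
                    break
        sig_trans = [r for r in all_records
                     if r.q_value <= config.fdr and r.cls == "trans"
                     and r.locus in harboring]
        pairs = {GenePair.of(harboring[r.locus], r.gene_id) for r in sig_trans
                 if harboring[r.locus] != r.gene_id}
        universe = sorted({r.gene_id for r in all_records}
                          | set(harboring.values()))
        if pairs:
            enr = permutation_enrichment(
                pairs, universe, interactions,
                n_perm=config.n_perm, seed=config.seed,
            )
            summary["enrichment"] = {
                "observed_overlap": enr.observed_overlap,
                "n_pairs": enr.n_pairs,
                "n_permutations": enr.n_permutations,
                "p_value": enr.p_value,
                "p_formatted": enr.formatted_p(),
            }
        else:
            summary["enrichment"] = {"n_pairs": 0, "note": "no significant trans pairs"}

    reqtl_path = out_dir / "reqtl.tsv"
    write_reqtl_table(all_records, reqtl_path)
    audit_path = out_dir / "audit.log"
    audit_path.write_text("".join(line + "\n" for line in audit))
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished: %d records, %d significant",
                len(all_records), summary["n_significant_total"])
    return PipelineResult(all_records, summary, reqtl_path, summary_path, audit_path)
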