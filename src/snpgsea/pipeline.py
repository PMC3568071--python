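"""End-to-end orchestration: QC -> association -> mapping -> gene scores ->
pruning -> enrichment, with a manifest that makes reruns reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import yaml

from . import io as gio
from .config import RunConfig
from .errors import ConfigurationError
from .models import (
    CaseControlStudy,
    GeneSetEnrichment,
    MetaAnalysis,
    StudyResults,
    TrioStudy,
)

log = logging.getLogger("snpgsea")


def _config_hash(config: RunConfig) -> str:
    fields = asdict(config)
    fields.pop("output_dir", None)  # analysis-irrelevant
    payload = yaml.safe_dump(fields, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_scores(scores, path) -> None:
    gio.write_results(scores, path)


def run_sample(config: RunConfig) -> StudyResults:
    """Run the full per-sample pipeline and write every stage table.

    Outputs under ``config.output_dir``: qc_report.tsv, assoc.tsv,
    gene_models.tsv, exclusions.tsv, gene_scores.tsv, pruned_scores.tsv,
    enrichment.tsv and manifest.json (seed, config hash, stage counts).
    """
    for name in ("ped_path", "map_path", "annotation_path", "gene_set_path"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            raise ConfigurationError(f"{name}: path {path!r} does not exist")
    os.makedirs(config.output_dir, exist_ok=True)

    matrix = gio.read_ped_map(config.ped_path, config.map_path)
    annotation = gio.read_gene_table(config.annotation_path)
    gene_sets = gio.read_gmt(config.gene_set_path)

    is_trio_file = (matrix.subjects["father"] != "0").any()
    if config.design == "trios" and not is_trio_file:
        raise ConfigurationError(
            "design: 'trios' requested but the PED file contains no "
            "parent-child links")
    if config.design == "case-control" and is_trio_file:
        raise ConfigurationError(
            "design: 'case-control' requested but the PED file is a pedigree")

    kwargs = dict(qc=config.qc, upstream_bp=config.upstream_bp,
                  downstream_bp=config.downstream_bp,
                  strand_aware=config.strand_aware)
    if config.design == "trios":
        study = TrioStudy(gio.to_trios(matrix), annotation, **kwargs)
    else:
        study = CaseControlStudy(matrix, annotation, **kwargs)

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    log.info("fitting %s study: %d subjects, %d SNPs", config.design,
             matrix.n_subjects, matrix.n_snps)
    results = study.fit(schedule=config.permutation_schedule,
                        escalation=config.escalation_thresholds,
                        seed=seeds[0])

    enr = GeneSetEnrichment(results, gene_sets,
                            percentiles=config.percentiles,
                            n_samplings=config.n_samplings).fit(seed=seeds[1])

    out = config.output_dir
    results.qc_report.to_frame().pipe(_write_scores,
                                      os.path.join(out, "qc_report.tsv"))
    _write_scores(results.assoc, os.path.join(out, "assoc.tsv"))
    models = results.model_table.models.drop(columns=["snp_indices"])
    _write_scores(models, os.path.join(out, "gene_models.tsv"))
    _write_scores(results.model_table.exclusions,
                  os.path.join(out, "exclusions.tsv"))
    _write_scores(results.gene_scores.scores,
                  os.path.join(out, "gene_scores.tsv"))
    _write_scores(results.pruned_scores,
                  os.path.join(out, "pruned_scores.tsv"))
    enr.to_tsv(os.path.join(out, "enrichment.tsv"))

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "design": config.design,
        "stages": {
            "subjects_in": int(matrix.n_subjects),
            "snps_in": int(matrix.n_snps),
            "snps_after_qc": int(results.n_snps),
            "genes_scored": int(len(results.gene_scores.scores)),
            "genes_after_pruning": int(len(results.pruned_scores)),
            "gene_sets_tested": int(len(gene_sets)),
        },
        "flags": {
            "strand_aware": config.strand_aware,
            "percentiles": list(config.percentiles),
            "n_samplings": config.n_samplings,
            "schedule": list(config.permutation_schedule),
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results.extras["enrichment"] = enr
    return results


def run_meta(config: RunConfig, studies: list[StudyResults],
             annotation, gene_sets):
    """Combine fitted studies per SNP and run summary-based enrichment."""
    os.makedirs(config.output_dir, exist_ok=True)
    meta = MetaAnalysis(studies).fit()
    _write_scores(meta.table, os.path.join(config.output_dir, "meta_snp.tsv"))
    enr = meta.enrichment(
        annotation, gene_sets, percentiles=config.percentiles,
        n_samplings=config.n_samplings,
        seed=np.random.SeedSequence(config.seed ^ 0x5A5A).spawn(1)[0],
        upstream_bp=config.upstream_bp, downstream_bp=config.downstream_bp,
        strand_aware=config.strand_aware)
    enr.to_tsv(os.path.join(config.output_dir, "meta_enrichment.tsv"))
    return meta, enr
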