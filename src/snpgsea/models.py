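"""Model/results objects tying the pipeline stages together.

The surface follows the fit-then-results idiom: a study object is built from
data (`CaseControlStudy`, `TrioStudy`), its ``fit()`` runs QC, per-SNP
association, SNP-to-gene mapping and permutation gene scores, and returns a
results object carrying every intermediate table plus a ``summary()``.
`GeneSetEnrichment` and `MetaAnalysis` consume those results the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .assoc import catt_scan, chi2_sf_1df, count_transmissions, tdt_statistic
from .config import QcThresholds
from .datamodel import GeneAnnotation, GenotypeMatrix, TrioCollection
from .enrich import (
    DEFAULT_N_SAMPLINGS,
    DEFAULT_PERCENTILES,
    bonferroni,
    enrichment_analysis,
    prune_clustered,
    results_frame,
)
from .mapping import (
    DEFAULT_DOWNSTREAM_BP,
    DEFAULT_UPSTREAM_BP,
    GeneModelTable,
    map_genes,
)
from .meta import harmonize_alleles, meta_gsea, meta_scan
from .qc import (
    QcReport,
    mendelian_check,
    sample_qc_mask,
    snp_qc_mask,
    transmission_informative,
)
from .scores import (
    DEFAULT_ESCALATION,
    DEFAULT_SCHEDULE,
    GeneScoreTable,
    gene_scores_cc,
    gene_scores_tdt,
)


@dataclass
class StudyResults:
    """Fitted per-study results: QC, per-SNP association, gene scores.

    ``assoc`` has one row per QC-passing SNP (snp, chrom, pos, allele1,
    allele2, statistic, p, ln_or, se); ``gene_scores``/``pruned_scores``
    carry the permutation-corrected gene p-values before/after
    physical-clustering pruning.
    """

    design: str
    qc_report: QcReport
    assoc: pd.DataFrame
    model_table: GeneModelTable
    mapping_report: object
    gene_scores: GeneScoreTable
    pruned_scores: pd.DataFrame
    matrix: GenotypeMatrix | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.assoc)

    def summary(self) -> pd.DataFrame:
        """Stage-count overview of the fitted study."""
        rows = [
            ("design", self.design),
            ("snps_passing_qc", self.n_snps),
            ("genes_scored", len(self.gene_scores.scores)),
            ("genes_after_pruning", len(self.pruned_scores)),
            ("unique_snps_in_genes", self.mapping_report.n_unique_snps),
            ("pct_autosomal_snps",
             round(self.mapping_report.pct_of_autosomal_snps, 2)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


class CaseControlStudy:
    """Case-control GWAS + permutation gene scores, ready for enrichment.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Minor-allele dosages with a 0/1 phenotype column.
    annotation : GeneAnnotation
        Transcript table used for SNP-to-gene mapping.
    qc : QcThresholds, optional
        Filter thresholds; HWE is evaluated in controls.
    """

    design = "case-control"

    def __init__(self, matrix: GenotypeMatrix, annotation: GeneAnnotation,
                 qc: QcThresholds | None = None,
                 upstream_bp: int = DEFAULT_UPSTREAM_BP,
                 downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                 strand_aware: bool = True):
        self.matrix = matrix
        self.annotation = annotation
        self.qc = qc or QcThresholds()
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.strand_aware = strand_aware

    @classmethod
    def from_ped_map(cls, ped_path, map_path, annotation_path, **kwargs):
        matrix = gio.read_ped_map(ped_path, map_path)
        annotation = gio.read_gene_table(annotation_path)
        return cls(matrix, annotation, **kwargs)

    def fit(self, schedule=DEFAULT_SCHEDULE, escalation=DEFAULT_ESCALATION,
            seed=None) -> StudyResults:
        keep_subjects = sample_qc_mask(self.matrix, self.qc)
        m = self.matrix.subset(subject_mask=keep_subjects)
        qc_report = snp_qc_mask(m, self.qc, design="case-control")
        m = m.subset(snp_mask=qc_report.keep)

        stat, p = catt_scan(m)
        assoc = _assoc_frame(m.snps, self.design, stat, p)
        _add_allelic_or(assoc, m)

        model_table, map_report = map_genes(
            self.annotation, m.snps, self.upstream_bp, self.downstream_bp,
            self.strand_aware)
        scores = gene_scores_cc(m, model_table, schedule=schedule,
                                escalation=escalation, rng=seed)
        pruned = prune_clustered(scores.scores)
        return StudyResults(self.design, qc_report, assoc, model_table,
                            map_report, scores, pruned, matrix=m)


class TrioStudy:
    """Trio GWAS: Mendelian cleaning, TDT, transmission-flip gene scores."""

    design = "trios"

    def __init__(self, trios: TrioCollection, annotation: GeneAnnotation,
                 qc: QcThresholds | None = None,
                 upstream_bp: int = DEFAULT_UPSTREAM_BP,
                 downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                 strand_aware: bool = True):
        self.trios = trios
        self.annotation = annotation
        self.qc = qc or QcThresholds()
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.strand_aware = strand_aware

    @classmethod
    def from_ped_map(cls, ped_path, map_path, annotation_path, **kwargs):
        matrix = gio.read_ped_map(ped_path, map_path)
        trios = gio.to_trios(matrix)
        annotation = gio.read_gene_table(annotation_path)
        return cls(trios, annotation, **kwargs)

    def fit(self, schedule=DEFAULT_SCHEDULE, escalation=DEFAULT_ESCALATION,
            seed=None) -> StudyResults:
        cleaned, mendel_flags, fam_keep = mendelian_check(self.trios, self.qc)

        parents = cleaned.parent_matrix()
        qc_report = snp_qc_mask(parents, self.qc, design="parents-of-trios")
        keep = qc_report.keep.copy()

        b_fam, c_fam = count_transmissions(cleaned)
        informative = transmission_informative(b_fam.sum(axis=0),
                                               c_fam.sum(axis=0))
        qc_report.excluded_not_informative = int((keep & ~informative).sum())
        keep &= informative
        qc_report.keep = keep

        cleaned = cleaned.subset(snp_mask=keep)
        b_fam, c_fam = b_fam[:, keep], c_fam[:, keep]
        b, c = b_fam.sum(axis=0), c_fam.sum(axis=0)
        stat = tdt_statistic(b, c)
        assoc = _assoc_frame(cleaned.snps, self.design, stat,
                             chi2_sf_1df(stat))
        _add_tdt_or(assoc, b, c)

        model_table, map_report = map_genes(
            self.annotation, cleaned.snps, self.upstream_bp,
            self.downstream_bp, self.strand_aware)
        scores = gene_scores_tdt(b_fam, c_fam, cleaned.snps, model_table,
                                 schedule=schedule, escalation=escalation,
                                 rng=seed)
        pruned = prune_clustered(scores.scores)
        return StudyResults(
            self.design, qc_report, assoc, model_table, map_report, scores,
            pruned, matrix=cleaned.parent_matrix(),
            extras={"b": b, "c": c, "mendel_flags": mendel_flags,
                    "families_kept": fam_keep, "trios": cleaned})


def _assoc_frame(snps: pd.DataFrame, design: str, stat, p) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": snps["snp"].to_numpy(), "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(),
        "allele1": snps["allele1"].to_numpy(),
        "allele2": snps["allele2"].to_numpy(),
        "design": design, "statistic": stat, "p": p,
    })


def _add_allelic_or(assoc: pd.DataFrame, matrix: GenotypeMatrix) -> None:
    from .assoc import allelic_log_or

    y = matrix.phenotype
    case = matrix.genotype_counts(subject_mask=y == 1)
    ctrl = matrix.genotype_counts(subject_mask=y == 0)
    vals = [allelic_log_or(case[j], ctrl[j]) for j in range(matrix.n_snps)]
    assoc["ln_or"] = [v[0] for v in vals]
    assoc["se"] = [v[1] for v in vals]
    assoc["haldane"] = [v[2] for v in vals]


def _add_tdt_or(assoc: pd.DataFrame, b: np.ndarray, c: np.ndarray) -> None:
    corrected = (b == 0) | (c == 0)
    bb = np.where(corrected, b + 0.5, b)
    cc = np.where(corrected, c + 0.5, c)
    assoc["ln_or"] = np.log(bb / cc)
    assoc["se"] = np.sqrt(1 / bb + 1 / cc)
    assoc["haldane"] = corrected
    assoc["b"] = b
    assoc["c"] = c


@dataclass
class EnrichmentResults:
    """Fitted gene-set enrichment panel with Bonferroni flags."""

    results: list
    table: pd.DataFrame

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Result table plus Bonferroni-adjusted significance flags over the
        tested sets (the planted/decoy battery or the user's sets)."""
        out = self.table.copy()
        m = len(out)
        for col in [c for c in out.columns if c.startswith("p_gsea_")] + \
                ["p_wmw", "p_ks", "p_t"]:
            out[f"{col}_bonf"] = bonferroni(out[col].to_numpy(), m)
            out[f"{col}_sig"] = out[f"{col}_bonf"] <= alpha
        return out

    def to_tsv(self, path) -> None:
        gio.write_results(self.table, path)


class GeneSetEnrichment:
    """Leading-edge and rank enrichment tests over fitted gene scores.

    Built from a :class:`StudyResults` (permutation path) or any pruned
    gene-score frame with ``gene`` and ``p_gene`` columns.
    """

    def __init__(self, study: StudyResults | pd.DataFrame, gene_sets,
                 percentiles=DEFAULT_PERCENTILES,
                 n_samplings: int = DEFAULT_N_SAMPLINGS,
                 with_replacement: bool = False):
        if isinstance(study, StudyResults):
            self.pruned = study.pruned_scores
            self.model_table = study.model_table
            self.n_autosomal_snps = study.n_snps
        else:
            self.pruned = study
            self.model_table = None
            self.n_autosomal_snps = None
        self.gene_sets = gene_sets
        self.percentiles = percentiles
        self.n_samplings = n_samplings
        self.with_replacement = with_replacement

    def fit(self, seed=None) -> EnrichmentResults:
        res = enrichment_analysis(
            self.pruned, self.gene_sets, self.percentiles, self.n_samplings,
            rng=seed, model_table=self.model_table,
            n_autosomal_snps=self.n_autosomal_snps,
            with_replacement=self.with_replacement)
        return EnrichmentResults(res, results_frame(res))


@dataclass
class MetaResults:
    """Per-SNP fixed-effect combination across studies."""

    table: pd.DataFrame        # snp, ln_or, se, z, p, n_studies
    studies: list

    def summary(self) -> pd.DataFrame:
        return self.table

    def enrichment(self, annotation: GeneAnnotation, gene_sets,
                   reference: StudyResults | None = None,
                   percentiles=DEFAULT_PERCENTILES,
                   n_samplings: int = DEFAULT_N_SAMPLINGS,
                   seed=None, **map_kwargs) -> EnrichmentResults:
        """Summary-based (regression-corrected) enrichment on the meta p.

        ``reference`` supplies the genotype panel for LD estimation and the
        SNP map; it defaults to the first contributing study.
        """
        ref = reference or self.studies[0]
        snps = ref.matrix.snps
        table, _ = map_genes(annotation, snps, **map_kwargs)
        res = meta_gsea(self.table, snps, table, ref.matrix.dosages,
                        gene_sets, percentiles, n_samplings, rng=seed,
                        n_autosomal_snps=len(snps))
        return EnrichmentResults(res, results_frame(res))


class MetaAnalysis:
    """Inverse-variance fixed-effect meta-analysis of fitted studies."""

    def __init__(self, studies: list[StudyResults]):
        if not studies:
            raise ValueError("need at least one fitted study")
        self.studies = studies

    def fit(self) -> MetaResults:
        ref = self.studies[0].assoc
        frames = [ref]
        for s in self.studies[1:]:
            frames.append(harmonize_alleles(s.assoc, ref))
        return MetaResults(meta_scan(frames), self.studies)
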