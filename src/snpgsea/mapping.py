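"""SNP-to-gene mapping.

Transcripts of a gene are merged to the most extreme start/end; genes whose
transcripts sit on separate chromosomes, or more than 1 Mb apart on one
chromosome, are excluded.  Merged bounds are extended 110 kb upstream and
40 kb downstream of the transcription direction (the 99th percentile of
cis-eQTL distances motivates these margins), and every SNP inside a gene's
extended interval is assigned to it; a SNP inside several extended intervals
belongs to all of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneAnnotation

MAX_TRANSCRIPT_GAP_BP = 1_000_000
DEFAULT_UPSTREAM_BP = 110_000
DEFAULT_DOWNSTREAM_BP = 40_000


@dataclass
class GeneModelTable:
    """Merged, extended gene models plus the transcript-exclusion report.

    ``models`` columns: gene, chrom, strand, start, end, ext_start, ext_end
    (all 1-based inclusive); after :func:`assign_snps` also ``snp_indices``
    and ``n_snps``.  ``exclusions`` columns: gene, reason.
    """

    models: pd.DataFrame
    exclusions: pd.DataFrame


def merge_transcripts(annotation: GeneAnnotation,
                      max_gap_bp: int = MAX_TRANSCRIPT_GAP_BP,
                      gap_rule: str = "inter-transcript") -> GeneModelTable:
    """Merge per-gene transcripts to min(start)/max(end), applying exclusions.

    ``gap_rule`` selects how the 1 Mb same-chromosome rule is measured:
    ``"inter-transcript"`` (gap between transcript intervals, the default) or
    ``"span"`` (total merged span).
    """
    if gap_rule not in ("inter-transcript", "span"):
        raise ValueError(f"unknown gap_rule {gap_rule!r}")
    rows, excluded = [], []
    t = annotation.transcripts
    for gene, grp in t.groupby("gene", sort=False):
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            excluded.append((gene, "separate chromosomes"))
            continue
        starts = grp["tx_start"].to_numpy()
        ends = grp["tx_end"].to_numpy()
        if len(grp) > 1:
            if gap_rule == "span":
                too_far = ends.max() - starts.min() > max_gap_bp
            else:
                order = np.argsort(starts)
                run_end = np.maximum.accumulate(ends[order])
                gaps = starts[order][1:] - run_end[:-1]
                too_far = bool((gaps > max_gap_bp).any())
            if too_far:
                excluded.append((gene, "distance > 1 Mb"))
                continue
        strand = grp["strand"].iloc[0]
        # merged bounds reported 1-based inclusive
        rows.append((gene, chroms[0], strand,
                     int(starts.min()) + 1, int(ends.max())))
    models = pd.DataFrame(rows, columns=["gene", "chrom", "strand",
                                         "start", "end"])
    exclusions = pd.DataFrame(excluded, columns=["gene", "reason"])
    return GeneModelTable(models, exclusions)


def extend_bounds(start: int, end: int, strand: str,
                  upstream_bp: int = DEFAULT_UPSTREAM_BP,
                  downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                  strand_aware: bool = True) -> tuple[int, int]:
    """Extended interval of one merged gene model (1-based inclusive).

    Strand-aware by default: upstream is against the transcription direction.
    With ``strand_aware=False`` the upstream margin is applied on the left
    and the downstream margin on the right regardless of strand.  The start
    is clipped at position 1.
    """
    if strand_aware and strand == "-":
        left, right = downstream_bp, upstream_bp
    else:
        left, right = upstream_bp, downstream_bp
    return max(1, start - left), end + right


def extend_models(table: GeneModelTable,
                  upstream_bp: int = DEFAULT_UPSTREAM_BP,
                  downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
                  strand_aware: bool = True) -> GeneModelTable:
    """Add ext_start/ext_end columns to every model."""
    m = table.models.copy()
    bounds = [
        extend_bounds(s, e, st, upstream_bp, downstream_bp, strand_aware)
        for s, e, st in zip(m["start"], m["end"], m["strand"])
    ]
    m["ext_start"] = [b[0] for b in bounds]
    m["ext_end"] = [b[1] for b in bounds]
    return GeneModelTable(m, table.exclusions)


@dataclass
class AssignmentReport:
    """SNP-assignment summary in the Table-1 shape."""

    n_genes_with_snps: int
    n_genes_dropped: int
    n_unique_snps: int
    pct_of_autosomal_snps: float


def assign_snps(table: GeneModelTable, snps: pd.DataFrame):
    """Assign every SNP to each gene whose extended interval contains it.

    Containment is inclusive at both ends on 1-based positions.  Genes with
    zero assigned SNPs are dropped and counted.  Returns ``(table_with_snps,
    report)`` where the report's percentage is relative to the SNP map
    handed in (i.e. the QC-passing autosomal SNPs).
    """
    m = table.models.copy()
    snp_idx_lists: list[np.ndarray] = []
    all_assigned: set[int] = set()
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in snps.groupby("chrom", sort=False)
    }
    for rec in m.itertuples(index=False):
        grp = by_chrom.get(rec.chrom)
        if grp is None:
            snp_idx_lists.append(np.array([], dtype=int))
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, rec.ext_start, side="left")
        hi = np.searchsorted(pos, rec.ext_end, side="right")
        idx = grp.index.to_numpy()[lo:hi]
        snp_idx_lists.append(idx)
        all_assigned.update(idx.tolist())

    m["snp_indices"] = snp_idx_lists
    m["n_snps"] = [len(x) for x in snp_idx_lists]
    dropped = int((m["n_snps"] == 0).sum())
    m = m[m["n_snps"] > 0].reset_index(drop=True)

    n_total = len(snps)
    report = AssignmentReport(
        n_genes_with_snps=len(m),
        n_genes_dropped=dropped,
        n_unique_snps=len(all_assigned),
        pct_of_autosomal_snps=(100.0 * len(all_assigned) / n_total
                               if n_total else 0.0),
    )
    return GeneModelTable(m, table.exclusions), report


def map_genes(annotation: GeneAnnotation, snps: pd.DataFrame,
              upstream_bp: int = DEFAULT_UPSTREAM_BP,
              downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
              strand_aware: bool = True,
              gap_rule: str = "inter-transcript"):
    """Full mapping pass: merge, extend, assign.  Returns (table, report)."""
    table = merge_transcripts(annotation, gap_rule=gap_rule)
    table = extend_models(table, upstream_bp, downstream_bp, strand_aware)
    return assign_snps(table, snps)
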