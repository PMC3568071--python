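"""Synthetic genotype, trio, annotation and gene-set generator.

Emulates the study designs the pipeline targets: biallelic autosomal SNPs in
approximate Hardy-Weinberg equilibrium with configurable MAF range and
optional first-order adjacent-SNP LD (haplotype copying), genes tiled along
chromosomes with variable lengths and SNP densities, a binary phenotype from
an additive-log-odds model whose causal SNPs can be confined to designated
genes, trios ascertained on an affected child by rejection sampling, and
gene-set files with one planted set plus random decoy sets.

All randomness flows through child streams of ``SimulationConfig.seed``
(one per generator), so identical seed + config yields identical output
regardless of which generators are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datamodel import (
    SUBJECT_COLUMNS,
    GeneAnnotation,
    GenotypeMatrix,
    GeneSetCollection,
    TrioCollection,
)
from .errors import InfeasibleSimulationError

_STREAMS = {"annotation": 0, "map": 1, "case_control": 2, "trios": 3,
            "gene_sets": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Tile genes along chromosomes; optionally add second transcripts.

    A ``second_transcript_fraction`` of genes receives an extra transcript
    that obeys the merge rules (same chromosome, within 1 Mb); a
    ``split_transcript_fraction`` receives one that deliberately violates
    them, to exercise the exclusion logic downstream.
    """
    rng = _rng(config, "annotation")
    rows = []
    gene_no = 0
    for chrom_i in range(config.n_chromosomes):
        chrom = str(chrom_i + 1)
        cursor = int(rng.integers(*_hi(config.intergenic_gap_range)))
        for _ in range(config.genes_per_chromosome):
            length = int(rng.integers(*_hi(config.gene_length_range)))
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            rows.append((f"G{gene_no:05d}", chrom, strand, start, end))
            cursor = end + int(rng.integers(*_hi(config.intergenic_gap_range)))
    transcripts = pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "tx_start", "tx_end"])

    extra = []
    for rec in transcripts.itertuples(index=False):
        u = rng.random()
        if u < config.split_transcript_fraction:
            # violate the merge rules: other chromosome, or > 1 Mb away
            if rng.random() < 0.5 and config.n_chromosomes > 1:
                other = str(1 + (int(rec.chrom) % config.n_chromosomes))
                extra.append((rec.gene, other, rec.strand,
                              rec.tx_start, rec.tx_end))
            else:
                shift = 1_000_001 + int(rng.integers(0, 500_000))
                extra.append((rec.gene, rec.chrom, rec.strand,
                              rec.tx_end + shift, rec.tx_end + shift + 1_000))
        elif u < config.split_transcript_fraction + \
                config.second_transcript_fraction:
            # legal second transcript nested near the first
            mid = (rec.tx_start + rec.tx_end) // 2
            extra.append((rec.gene, rec.chrom, rec.strand,
                          rec.tx_start, max(mid, rec.tx_start + 1)))
    if extra:
        transcripts = pd.concat(
            [transcripts, pd.DataFrame(extra, columns=transcripts.columns)],
            ignore_index=True)
    transcripts = transcripts.sort_values(
        ["chrom", "tx_start"], kind="stable").reset_index(drop=True)
    return GeneAnnotation(transcripts)


def _hi(interval):
    lo, hi = interval
    return lo, hi + 1


# --------------------------------------------------------------------------
# SNP map and haplotypes
# --------------------------------------------------------------------------

@dataclass
class SnpPanel:
    """Simulated SNP map plus the population haplotype allele frequencies."""

    snps: pd.DataFrame
    maf: np.ndarray
    chrom_starts: np.ndarray  # first SNP index of each chromosome


def simulate_snp_map(config: SimulationConfig,
                     annotation: GeneAnnotation) -> SnpPanel:
    """Place SNPs along each chromosome with the configured spacing and MAFs."""
    rng = _rng(config, "map")
    t = annotation.transcripts
    rows, mafs, starts = [], [], []
    snp_no = 0
    chroms = (sorted(t["chrom"].unique(), key=str) if len(t)
              else [str(i + 1) for i in range(config.n_chromosomes)])
    for chrom in chroms:
        span_end = int(t.loc[t["chrom"] == chrom, "tx_end"].max()) \
            if (t["chrom"] == chrom).any() else 0
        span_end += config.intergenic_gap_range[1]
        starts.append(snp_no)
        pos = 1 + int(rng.integers(*_hi(config.snp_spacing_range)))
        while pos <= span_end:
            snp_no += 1
            rows.append((f"rs{snp_no:06d}", chrom, pos, "A", "B"))
            mafs.append(rng.uniform(*config.maf_range))
            pos += int(rng.integers(*_hi(config.snp_spacing_range)))
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos",
                                       "allele1", "allele2"])
    return SnpPanel(snps, np.asarray(mafs), np.asarray(starts, dtype=int))


def _draw_haplotypes(panel: SnpPanel, n_hap: int, ld_rho: float,
                     rng: np.random.Generator) -> np.ndarray:
    """First-order copying model: adjacent alleles identical with
    probability ld_rho, otherwise a fresh Bernoulli(MAF) draw.  Copying
    never crosses a chromosome boundary."""
    n_snps = len(panel.maf)
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    fresh_start = set(panel.chrom_starts.tolist())
    for j in range(n_snps):
        fresh = rng.random(n_hap) < panel.maf[j]
        if j in fresh_start or ld_rho == 0.0:
            hap[:, j] = fresh
        else:
            copy = rng.random(n_hap) < ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def resolve_causal(config: SimulationConfig, panel: SnpPanel,
                   annotation: GeneAnnotation):
    """Resolve causal handles to (snp index array, per-SNP ln OR array).

    A handle is a SNP id from the panel or ``"gene:<id>"``, which selects
    the SNP nearest the gene's transcript midpoint.
    """
    snp_ids = {s: i for i, s in enumerate(panel.snps["snp"])}
    t = annotation.transcripts
    idx, ln_or = [], []
    for handle, orr in config.causal_spec:
        if handle.startswith("gene:"):
            gene = handle[5:]
            grp = t[t["gene"] == gene]
            if grp.empty:
                raise LookupError(f"causal handle {handle!r}: gene not found")
            chrom = grp["chrom"].iloc[0]
            mid = (grp["tx_start"].min() + grp["tx_end"].max()) / 2.0
            on_chrom = panel.snps.index[panel.snps["chrom"] == chrom]
            if len(on_chrom) == 0:
                raise LookupError(f"causal handle {handle!r}: no SNP on "
                                  f"chromosome {chrom}")
            pos = panel.snps.loc[on_chrom, "pos"].to_numpy()
            idx.append(int(on_chrom[np.argmin(np.abs(pos - mid))]))
        else:
            if handle not in snp_ids:
                raise LookupError(f"causal handle {handle!r}: SNP not found")
            idx.append(snp_ids[handle])
        ln_or.append(np.log(orr))
    return np.asarray(idx, dtype=int), np.asarray(ln_or)


def _case_probability(dosages: np.ndarray, causal_idx, causal_ln_or,
                      prevalence: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logit0 = np.log(prevalence / (1.0 - prevalence)) if prevalence > 0 \
            else -np.inf
    eta = np.full(dosages.shape[0], logit0)
    if len(causal_idx):
        eta = eta + dosages[:, causal_idx] @ causal_ln_or
    return 1.0 / (1.0 + np.exp(-eta))


def _inject_missing(dosages: np.ndarray, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        dosages = dosages.astype(float)
        dosages[rng.random(dosages.shape) < rate] = np.nan
    return np.asarray(dosages, dtype=float)


# --------------------------------------------------------------------------
# case-control sample
# --------------------------------------------------------------------------

def simulate_case_control(config: SimulationConfig,
                          annotation: GeneAnnotation,
                          panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Ascertain a case-control sample from the additive-log-odds model.

    Subjects are drawn from the haplotype population and kept as cases or
    controls until both quotas are filled; disease status follows
    ``logit P = logit(prevalence) + sum(dosage * lnOR)`` over the causal
    SNPs.  Missing calls are injected at ``missing_rate``.
    """
    if panel is None:
        panel = simulate_snp_map(config, annotation)
    rng = _rng(config, "case_control")
    causal_idx, causal_ln_or = resolve_causal(config, panel, annotation)

    need_cases, need_controls = config.n_cases, config.n_controls
    got_cases, got_controls = [], []
    drawn = 0
    batch = max(256, 2 * (need_cases + need_controls))
    while (len(got_cases) < need_cases or len(got_controls) < need_controls):
        if drawn >= config.trio_draw_cap:
            raise InfeasibleSimulationError(
                f"case-control ascertainment did not complete within "
                f"{config.trio_draw_cap} draws"
            )
        hap = _draw_haplotypes(panel, 2 * batch, config.ld_rho, rng)
        d = (hap[0::2] + hap[1::2]).astype(float)
        drawn += batch
        prob = _case_probability(d, causal_idx, causal_ln_or,
                                 config.baseline_prevalence)
        is_case = rng.random(batch) < prob
        for row, case in zip(d, is_case):
            if case and len(got_cases) < need_cases:
                got_cases.append(row)
            elif not case and len(got_controls) < need_controls:
                got_controls.append(row)

    d = np.array(got_cases + got_controls) if (got_cases or got_controls) \
        else np.empty((0, len(panel.maf)))
    d = _inject_missing(d, config.missing_rate, rng)
    n = len(d)
    subjects = pd.DataFrame({
        "family": [f"F{i + 1:05d}" for i in range(n)],
        "individual": [f"I{i + 1:05d}" for i in range(n)],
        "father": "0", "mother": "0", "sex": 0,
        "phenotype": [1.0] * len(got_cases) + [0.0] * len(got_controls),
    }, columns=SUBJECT_COLUMNS)
    return GenotypeMatrix(d, panel.snps.copy(), subjects)


# --------------------------------------------------------------------------
# trios
# --------------------------------------------------------------------------

def simulate_trios(config: SimulationConfig, annotation: GeneAnnotation,
                   panel: SnpPanel | None = None) -> TrioCollection:
    """Ascertained trios: parents from the population, child by Mendelian
    transmission, family kept only if the child is affected.

    With ``mendel_error_rate > 0``, genotype errors that violate Mendelian
    inheritance are injected into the child after ascertainment; the
    injected-cell mask is attached as ``trios.injected_mendel``.
    """
    if panel is None:
        panel = simulate_snp_map(config, annotation)
    rng = _rng(config, "trios")
    causal_idx, causal_ln_or = resolve_causal(config, panel, annotation)

    fathers, mothers, children = [], [], []
    drawn = 0
    batch = max(128, 2 * config.n_trios)
    while len(children) < config.n_trios:
        if drawn >= config.trio_draw_cap:
            raise InfeasibleSimulationError(
                f"trio ascertainment did not complete within "
                f"{config.trio_draw_cap} family draws"
            )
        hap = _draw_haplotypes(panel, 4 * batch, config.ld_rho, rng)
        drawn += batch
        fa1, fa2 = hap[0::4], hap[1::4]
        mo1, mo2 = hap[2::4], hap[3::4]
        pick_f = rng.integers(0, 2, size=fa1.shape[0])[:, None]
        pick_m = rng.integers(0, 2, size=fa1.shape[0])[:, None]
        ch = (np.where(pick_f == 0, fa1, fa2)
              + np.where(pick_m == 0, mo1, mo2)).astype(float)
        prob = _case_probability(ch, causal_idx, causal_ln_or,
                                 config.baseline_prevalence)
        affected = rng.random(len(ch)) < prob
        for i in np.flatnonzero(affected):
            if len(children) >= config.n_trios:
                break
            fathers.append((fa1[i] + fa2[i]).astype(float))
            mothers.append((mo1[i] + mo2[i]).astype(float))
            children.append(ch[i])

    n = config.n_trios
    shape = (n, len(panel.maf))
    father = np.array(fathers) if n else np.empty(shape)
    mother = np.array(mothers) if n else np.empty(shape)
    child = np.array(children) if n else np.empty(shape)

    injected = np.zeros(shape, dtype=bool)
    if config.mendel_error_rate > 0 and n:
        lo = (father == 2).astype(float) + (mother == 2).astype(float)
        hi = (father >= 1).astype(float) + (mother >= 1).astype(float)
        cells = rng.random(shape) < config.mendel_error_rate
        for i, j in zip(*cells.nonzero()):
            bad_values = [v for v in (0.0, 1.0, 2.0)
                          if not (lo[i, j] <= v <= hi[i, j])]
            if bad_values:
                child[i, j] = bad_values[int(rng.integers(len(bad_values)))]
                injected[i, j] = True

    father = _inject_missing(father, config.missing_rate, rng)
    mother = _inject_missing(mother, config.missing_rate, rng)
    child = _inject_missing(child, config.missing_rate, rng)
    injected &= ~np.isnan(child)

    families = pd.DataFrame({"family": [f"T{i + 1:05d}" for i in range(n)]})
    trios = TrioCollection(father, mother, child, panel.snps.copy(), families)
    trios.injected_mendel = injected
    return trios


# --------------------------------------------------------------------------
# gene sets
# --------------------------------------------------------------------------

def make_gene_sets(annotation: GeneAnnotation, planted_ids,
                   n_decoy_sets: int, decoy_size: int,
                   seed=0) -> GeneSetCollection:
    """One named "planted" set plus random decoy sets.

    Decoys are sampled without replacement from the non-planted genes, so
    every decoy is disjoint from the planted set.
    """
    rng = np.random.default_rng(seed)
    genes = annotation.gene_ids
    planted = list(planted_ids)
    missing = set(planted) - set(genes)
    if missing:
        raise LookupError(f"planted ids not in annotation: {sorted(missing)}")
    pool = [g for g in genes if g not in set(planted)]
    if decoy_size > len(pool):
        raise ValueError(
            f"decoy_size {decoy_size} exceeds the {len(pool)} available "
            f"non-planted genes"
        )
    sets = {"planted": planted}
    descriptions = {"planted": "gene set carrying the causal SNPs"}
    for k in range(n_decoy_sets):
        name = f"decoy_{k + 1:03d}"
        sets[name] = list(rng.choice(pool, size=decoy_size, replace=False))
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets, descriptions)
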