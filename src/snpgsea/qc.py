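"""SNP and sample quality control.

Filters mirror a standard GWAS QC battery: per-sample call rate, per-SNP call
rate, design-specific minor-allele-frequency minima, and the exact test of
Hardy-Weinberg equilibrium evaluated in the design-specific stratum (controls
for a case-control sample, parents for trios, the whole sample for a
population-based design).  Family data additionally get Mendelian-consistency
cleaning and a transmission-informativeness filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import QcThresholds
from .datamodel import GenotypeMatrix, TrioCollection
from .errors import ConfigurationError, UndefinedResultError

_TIE_REL_TOL = 1e-12


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts)
    if n == 0:
        raise UndefinedResultError("HWE test undefined for an all-missing SNP")
    n_rare = 2 * n_hom_minor + n_het
    n_rare = min(n_rare, 2 * n - n_rare)  # orient to the rarer allele

    # attainable heterozygote counts share the parity of the rare-allele count
    h = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - h) // 2
    hom_common = n - h - hom_rare
    valid = hom_common >= 0
    h, hom_rare, hom_common = h[valid], hom_rare[valid], hom_common[valid]

    # log P(h | allele counts) up to a shared constant
    logp = (h * np.log(2.0)
            - gammaln(hom_common + 1) - gammaln(h + 1) - gammaln(hom_rare + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()

    obs = min(n_het, n_rare)
    p_obs = prob[np.searchsorted(h, obs)]
    p = prob[prob <= p_obs * (1.0 + _TIE_REL_TOL)].sum()
    return float(min(p, 1.0))


def hwe_exact_vector(counts: np.ndarray) -> np.ndarray:
    """Exact HWE p-value for each row of an (n_snps, 3) count array.

    Rows are (hom-major, het, hom-minor); all-missing rows yield NaN.
    """
    out = np.full(len(counts), np.nan)
    for i, (a, het, b) in enumerate(counts):
        if a + het + b > 0:
            out[i] = hwe_exact(int(a), int(het), int(b))
    return out


@dataclass
class QcReport:
    """Per-filter exclusion counts and the surviving SNP mask."""

    keep: np.ndarray
    excluded_call_rate: int
    excluded_maf: int
    excluded_hwe: int
    excluded_not_informative: int = 0

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filter": ["call_rate", "maf", "hwe", "transmission_informative",
                       "kept"],
            "n": [self.excluded_call_rate, self.excluded_maf,
                  self.excluded_hwe, self.excluded_not_informative,
                  self.n_kept],
        })


def sample_qc_mask(matrix: GenotypeMatrix,
                   thresholds: QcThresholds) -> np.ndarray:
    """Keep-mask over subjects: genome-wide call rate >= the threshold."""
    return matrix.sample_call_rate() >= thresholds.sample_call_rate_min


def snp_qc_mask(matrix: GenotypeMatrix, thresholds: QcThresholds,
                design: str = "case-control") -> QcReport:
    """Per-SNP keep-mask with per-filter exclusion counts.

    A SNP survives iff call rate, design-specific MAF and stratum HWE all
    pass; each excluded SNP is counted once, under the first failed filter
    (order: call rate, MAF, HWE).  For ``design="parents-of-trios"`` pass the
    parent matrix (see :meth:`TrioCollection.parent_matrix`).
    """
    if design == "case-control":
        maf_min = thresholds.maf_min_cc
        hwe_mask = matrix.phenotype == 0  # controls
    elif design == "parents-of-trios":
        maf_min = thresholds.maf_min_parents
        hwe_mask = np.ones(matrix.n_subjects, dtype=bool)
    elif design == "population":
        maf_min = thresholds.maf_min_cc
        hwe_mask = np.ones(matrix.n_subjects, dtype=bool)
    else:
        raise ConfigurationError(f"design: unknown design {design!r}")

    cr_ok = matrix.snp_call_rate() >= thresholds.snp_call_rate_min
    with np.errstate(invalid="ignore"):
        maf = matrix.maf()
        maf_ok = np.nan_to_num(maf, nan=-1.0) >= maf_min

    hwe_p = hwe_exact_vector(matrix.genotype_counts(subject_mask=hwe_mask))
    hwe_ok = np.nan_to_num(hwe_p, nan=-1.0) >= thresholds.hwe_p_min

    keep = cr_ok & maf_ok & hwe_ok
    n_cr = int((~cr_ok).sum())
    n_maf = int((cr_ok & ~maf_ok).sum())
    n_hwe = int((cr_ok & maf_ok & ~hwe_ok).sum())
    return QcReport(keep, n_cr, n_maf, n_hwe)


def mendelian_flags(trios: TrioCollection) -> np.ndarray:
    """(n_families, n_snps) boolean: genotype triple impossible under
    biallelic Mendelian inheritance.  Triples with any missing member are
    not assessable and flagged False."""
    f, m, c = trios.father, trios.mother, trios.child
    lo = (f == 2).astype(float) + (m == 2).astype(float)
    hi = (f >= 1).astype(float) + (m >= 1).astype(float)
    with np.errstate(invalid="ignore"):
        bad = (c < lo) | (c > hi)
    missing = np.isnan(f) | np.isnan(m) | np.isnan(c)
    bad[missing] = False
    return bad


def mendelian_check(trios: TrioCollection,
                    thresholds: QcThresholds | None = None):
    """Flag Mendelian-inconsistent calls, set them missing, drop bad families.

    All three members of an inconsistent triple are set missing at that SNP;
    families whose per-trio inconsistency fraction exceeds
    ``mendel_fraction_max`` are dropped.  Returns ``(cleaned, flags,
    family_keep_mask)`` with flags indexed on the *input* families.
    """
    thresholds = thresholds or QcThresholds()
    flags = mendelian_flags(trios)
    frac = flags.mean(axis=1) if trios.n_snps else np.zeros(trios.n_families)
    fam_keep = frac <= thresholds.mendel_fraction_max

    father, mother, child = (trios.father.copy(), trios.mother.copy(),
                             trios.child.copy())
    father[flags] = np.nan
    mother[flags] = np.nan
    child[flags] = np.nan
    cleaned = TrioCollection(father[fam_keep], mother[fam_keep],
                             child[fam_keep], trios.snps.copy(),
                             trios.families.loc[fam_keep])
    return cleaned, flags, fam_keep


def transmission_informative(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-SNP informativeness: at least one minor-allele transmission (b)
    and one non-transmission (c) from heterozygous parents."""
    return (np.asarray(b) >= 1) & (np.asarray(c) >= 1)
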