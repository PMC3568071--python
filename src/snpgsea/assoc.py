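"""Per-SNP association statistics.

Case-control samples are tested with the Cochran-Armitage trend test (scores
0/1/2, additive inheritance); trios with the transmission disequilibrium test
(TDT) on minor-allele transmissions from heterozygous parents.  Both paths
also produce an allelic log odds ratio with its standard error, which is what
the fixed-effect meta-analysis layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import TrioCollection
from .errors import UndefinedResultError

_CATT_WEIGHTS = np.array([0.0, 1.0, 2.0])


@dataclass
class AssocResult:
    """One SNP's association summary for one design."""

    snp: str
    design: str
    statistic: float
    p: float
    ln_or: float
    se_ln_or: float
    counts: tuple
    haldane_correction: bool = False


# --------------------------------------------------------------------------
# Cochran-Armitage trend test
# --------------------------------------------------------------------------

def catt_statistic(case_counts: np.ndarray,
                   control_counts: np.ndarray) -> np.ndarray:
    """Vectorised trend chi-square for (n, 3) genotype-class count arrays.

    Returns NaN where the statistic is undefined (monomorphic SNP or a
    degenerate margin).
    """
    r = np.atleast_2d(np.asarray(case_counts, dtype=float))
    s = np.atleast_2d(np.asarray(control_counts, dtype=float))
    n_col = r + s
    n = n_col.sum(axis=1)
    big_r = r.sum(axis=1)

    t = r @ _CATT_WEIGHTS
    wn = n_col @ _CATT_WEIGHTS
    w2n = n_col @ (_CATT_WEIGHTS ** 2)

    num = n * (n * t - big_r * wn) ** 2
    den = big_r * (n - big_r) * (n * w2n - wn ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, num / den, np.nan)
    stat[n == 0] = np.nan
    return stat


def allelic_log_or(case_counts, control_counts):
    """Minor-allele lnOR and SE from the allelic 2x2 table.

    A 0.5 Haldane-Anscombe correction is applied to every cell only when a
    zero cell occurs; the return flags its use.
    """
    r0, r1, r2 = (float(x) for x in case_counts)
    s0, s1, s2 = (float(x) for x in control_counts)
    a = r1 + 2 * r2          # minor alleles, cases
    b = 2 * r0 + r1          # major alleles, cases
    c = s1 + 2 * s2          # minor alleles, controls
    d = 2 * s0 + s1          # major alleles, controls
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ln_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(ln_or), float(se), corrected


def catt(case_counts, control_counts, snp: str = "") -> AssocResult:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    ``case_counts``/``control_counts`` are (n0, n1, n2) counts of minor-allele
    dosage classes.  Raises :class:`UndefinedResultError` for monomorphic
    tables.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.sum() + s.sum() <= 0:
        raise UndefinedResultError("empty genotype table")
    if (np.count_nonzero(r + s) < 2):
        raise UndefinedResultError("monomorphic SNP: trend test undefined")
    stat = float(catt_statistic(r, s)[0])
    if np.isnan(stat):
        raise UndefinedResultError("degenerate table: trend test undefined")
    p = float(stats.chi2.sf(stat, df=1))
    ln_or, se, corrected = allelic_log_or(r, s)
    return AssocResult(snp, "case-control", stat, max(p, np.finfo(float).tiny),
                       ln_or, se, (tuple(r), tuple(s)), corrected)


def catt_scan(matrix, phenotype=None):
    """Trend test across all SNPs of a GenotypeMatrix.

    Returns (stat, p) arrays with NaN at undefined SNPs.
    """
    y = matrix.phenotype if phenotype is None else np.asarray(phenotype, float)
    case = matrix.genotype_counts(subject_mask=y == 1)
    ctrl = matrix.genotype_counts(subject_mask=y == 0)
    stat = catt_statistic(case, ctrl)
    p = chi2_sf_1df(stat)
    return stat, p


def chi2_sf_1df(stat: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return stats.chi2.sf(stat, df=1)


# --------------------------------------------------------------------------
# Transmission disequilibrium test
# --------------------------------------------------------------------------

def count_transmissions(trios: TrioCollection):
    """Per-family, per-SNP minor-allele transmission tallies (B, C).

    ``B[f, j]`` counts minor-allele transmissions from heterozygous parents
    of family ``f`` at SNP ``j``; ``C`` the non-transmissions.  Families with
    a missing genotype at a SNP contribute nothing there.  With both parents
    heterozygous and a heterozygous child, the haplotypic origin is ambiguous
    and the standard allele-counting rule applies: one transmission and one
    non-transmission.
    """
    f, m, c = trios.father, trios.mother, trios.child
    valid = ~(np.isnan(f) | np.isnan(m) | np.isnan(c))
    het_f = (f == 1) & valid
    het_m = (m == 1) & valid
    n_het = het_f.astype(int) + het_m.astype(int)

    hom_minor_contrib = ((f == 2).astype(float) + (m == 2).astype(float))

    b = np.zeros(f.shape)
    cc = np.zeros(f.shape)

    one = valid & (n_het == 1)
    t1 = np.where(one, c - hom_minor_contrib, 0.0)
    t1 = np.clip(t1, 0.0, 1.0)  # out-of-range only if Mendelian-inconsistent
    b += np.where(one, t1, 0.0)
    cc += np.where(one, 1.0 - t1, 0.0)

    two = valid & (n_het == 2)
    t2 = np.where(two, np.clip(c, 0.0, 2.0), 0.0)
    b += np.where(two, t2, 0.0)
    cc += np.where(two, 2.0 - t2, 0.0)
    return b, cc


def tdt_statistic(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised TDT chi-square (b-c)^2/(b+c); NaN where b+c = 0."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    tot = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tot > 0, (b - c) ** 2 / tot, np.nan)


def tdt(b: float, c: float, snp: str = "") -> AssocResult:
    """TDT from total transmission counts b (transmitted) and c (not)."""
    if b + c < 1:
        raise UndefinedResultError("TDT undefined: no informative transmissions")
    stat = float(tdt_statistic(b, c))
    p = float(stats.chi2.sf(stat, df=1))
    corrected = b == 0 or c == 0
    bb, cc = (b + 0.5, c + 0.5) if corrected else (b, c)
    ln_or = float(np.log(bb / cc))
    se = float(np.sqrt(1 / bb + 1 / cc))
    return AssocResult(snp, "trios", stat, max(p, np.finfo(float).tiny),
                       ln_or, se, (b, c), corrected)


def tdt_scan(trios: TrioCollection):
    """TDT across all SNPs: returns (b, c, stat, p) per-SNP arrays."""
    bf, cf = count_transmissions(trios)
    b, c = bf.sum(axis=0), cf.sum(axis=0)
    stat = tdt_statistic(b, c)
    return b, c, stat, chi2_sf_1df(stat)
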