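"""Gene-wise corrected p-values.

For individual-level data, a gene's score is the empirical probability, under
phenotype permutation, that the gene's best single-SNP p-value is as small as
observed.  One permutation stream is shared across all SNPs per replicate
(one label vector, or one transmission-flip vector per family), so the null
preserves the cross-SNP LD structure and gene scores live on a common null
GWAS.  An adaptive schedule refines small gene p-values: genes with
P_g <= 0.01 (0.001) after 10,000 replicates are re-evaluated with 100,000
(1,000,000).

When only summary statistics exist (meta-analysis), gene scores are instead
corrected by regressing -log10(best p) on per-gene confounders (gene size,
SNP count, independent-SNP count, optional user columns) and ranking the
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import chi2_sf_1df, tdt_statistic
from .errors import ConfigurationError

DEFAULT_SCHEDULE = (10_000, 100_000, 1_000_000)
DEFAULT_ESCALATION = (0.01, 0.001)
_BATCH = 512


# --------------------------------------------------------------------------
# permutation streams (spec'd generators; the engines below draw the same
# objects in batches)
# --------------------------------------------------------------------------

def permutation_null_cc(phenotype: np.ndarray, rng: np.random.Generator):
    """Yield uniformly random case/control label reassignments.

    Each replicate is one label vector applied to all SNPs; case and control
    counts are preserved exactly.
    """
    y = np.asarray(phenotype, dtype=float)
    while True:
        yield rng.permutation(y)


def permutation_null_tdt(n_families: int, rng: np.random.Generator):
    """Yield per-family transmission-flip indicators (independent fair coins).

    One flip decision per family per replicate, applied across all SNPs.
    """
    while True:
        yield rng.random(n_families) < 0.5


def _permuted_label_batch(y: np.ndarray, rng: np.random.Generator,
                          size: int) -> np.ndarray:
    keys = rng.random((size, y.size))
    return y[np.argsort(keys, axis=1, kind="stable")]


# --------------------------------------------------------------------------
# gene score containers
# --------------------------------------------------------------------------

@dataclass
class GeneScoreTable:
    """Per-gene scores: best SNP, observed min p, corrected P_g.

    ``scores`` columns: gene, best_snp, p_min, p_gene, n_perms, n_snps,
    zero_count (True where no null replicate reached the observed minimum,
    i.e. P_g is reported as < 1/n_perms with the count 0 retained).
    """

    scores: pd.DataFrame

    def __len__(self):
        return len(self.scores)


def _gene_best(stat: np.ndarray, p: np.ndarray, model_table) -> pd.DataFrame:
    """Observed per-gene best SNP and min p (max statistic)."""
    m = model_table.models
    snps_col, pmin_col, stat_col = [], [], []
    for idx in m["snp_indices"]:
        s = stat[idx]
        s = np.where(np.isnan(s), -1.0, s)
        k = int(np.argmax(s))
        stat_col.append(s[k])
        pmin_col.append(p[idx][k] if s[k] >= 0 else 1.0)
        snps_col.append(int(idx[k]))
    return pd.DataFrame({
        "gene": m["gene"], "best_snp_idx": snps_col,
        "p_min": pmin_col, "obs_stat": stat_col,
        "n_snps": m["n_snps"],
    })


def _flat_index(snp_index_lists):
    flat = np.concatenate([np.asarray(x, dtype=int) for x in snp_index_lists])
    lengths = np.array([len(x) for x in snp_index_lists])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return flat, offsets


def _count_exceedances(stat_batch_fn, n_replicates, obs_gene_stat,
                       flat, offsets):
    """# of replicates whose per-gene max statistic >= the observed one."""
    counts = np.zeros(len(obs_gene_stat), dtype=np.int64)
    done = 0
    while done < n_replicates:
        b = min(_BATCH, n_replicates - done)
        stat = stat_batch_fn(b)                   # (b, n_snps)
        stat = np.where(np.isnan(stat), -1.0, stat)
        gene_max = np.maximum.reduceat(stat[:, flat], offsets, axis=1)
        counts += (gene_max >= obs_gene_stat).sum(axis=0)
        done += b
    return counts


class _CaseControlNull:
    """Batched permuted-label trend statistics via indicator matmuls."""

    def __init__(self, matrix, phenotype, rng):
        d = matrix.dosages
        y = np.asarray(phenotype, dtype=float)
        labelled = ~np.isnan(y)
        d = d[labelled]
        self.y = y[labelled]
        self.g1 = (d == 1).astype(float)
        self.g2 = (d == 2).astype(float)
        self.nonmiss = (~np.isnan(d)).astype(float)
        n1 = self.g1.sum(axis=0)
        n2 = self.g2.sum(axis=0)
        self.n = self.nonmiss.sum(axis=0)
        self.w = n1 + 2 * n2
        self.w2 = n1 + 4 * n2
        self.rng = rng

    def statistics(self, y_batch: np.ndarray) -> np.ndarray:
        t = y_batch @ self.g1 + 2 * (y_batch @ self.g2)
        big_r = y_batch @ self.nonmiss
        num = self.n * (self.n * t - big_r * self.w) ** 2
        den = big_r * (self.n - big_r) * (self.n * self.w2 - self.w ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def __call__(self, size: int) -> np.ndarray:
        return self.statistics(_permuted_label_batch(self.y, self.rng, size))


class _TdtNull:
    """Batched transmission-flip TDT statistics."""

    def __init__(self, b_fam, c_fam, rng):
        self.delta = c_fam - b_fam            # flip adds c_f - b_f to b
        self.b0 = b_fam.sum(axis=0)
        self.tot = (b_fam + c_fam).sum(axis=0)
        self.rng = rng

    def statistics(self, flips: np.ndarray) -> np.ndarray:
        b = self.b0 + flips @ self.delta
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.tot > 0, (2 * b - self.tot) ** 2 / self.tot,
                            np.nan)

    def __call__(self, size: int) -> np.ndarray:
        flips = (self.rng.random((size, self.delta.shape[0])) < 0.5)
        return self.statistics(flips.astype(float))


def _adaptive_gene_p(null_fn, obs: pd.DataFrame, model_table,
                     schedule, escalation) -> pd.DataFrame:
    m = model_table.models
    counts = np.zeros(len(m), dtype=np.int64)
    n_used = np.full(len(m), schedule[0], dtype=np.int64)
    active = np.ones(len(m), dtype=bool)
    obs_stat = obs["obs_stat"].to_numpy()

    for stage, n_rep in enumerate(schedule):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        flat, offsets = _flat_index(m["snp_indices"].iloc[idx])
        stage_counts = _count_exceedances(null_fn, n_rep, obs_stat[idx],
                                          flat, offsets)
        counts[idx] = stage_counts
        n_used[idx] = n_rep
        if stage == len(schedule) - 1:
            break
        p_stage = stage_counts / n_rep
        active[idx] = p_stage <= escalation[stage]

    p_gene = counts / n_used
    return pd.DataFrame({
        "gene": m["gene"].to_numpy(),
        "best_snp_idx": obs["best_snp_idx"].to_numpy(),
        "p_min": obs["p_min"].to_numpy(),
        "p_gene": p_gene,
        "n_perms": n_used,
        "n_snps": m["n_snps"].to_numpy(),
        "zero_count": counts == 0,
    })


def gene_scores_cc(matrix, model_table, phenotype=None,
                   schedule=DEFAULT_SCHEDULE, escalation=DEFAULT_ESCALATION,
                   rng=None) -> GeneScoreTable:
    """Permutation gene scores for a case-control sample.

    The observed per-SNP trend statistics give each gene its best SNP and
    P_min; the permutation null flips affection status for all SNPs at once.
    P_g is the fraction of replicates whose per-gene minimal p-value is equal
    to or smaller than the observed one (ties count).
    """
    rng = np.random.default_rng(rng)
    y = matrix.phenotype if phenotype is None else np.asarray(phenotype, float)
    null = _CaseControlNull(matrix, y, rng)
    obs_stat = null.statistics(null.y[None, :])[0]
    obs_p = chi2_sf_1df(obs_stat)
    obs = _gene_best(obs_stat, obs_p, model_table)
    scores = _adaptive_gene_p(null, obs, model_table, schedule, escalation)
    return _attach_snp_ids(scores, matrix.snps)


def gene_scores_tdt(b_fam, c_fam, snps, model_table,
                    schedule=DEFAULT_SCHEDULE, escalation=DEFAULT_ESCALATION,
                    rng=None) -> GeneScoreTable:
    """Permutation gene scores for trios via random transmission flips."""
    rng = np.random.default_rng(rng)
    null = _TdtNull(b_fam, c_fam, rng)
    b, tot = null.b0, null.tot
    obs_stat = tdt_statistic(b, tot - b)
    obs_p = chi2_sf_1df(obs_stat)
    obs = _gene_best(obs_stat, obs_p, model_table)
    scores = _adaptive_gene_p(null, obs, model_table, schedule, escalation)
    return _attach_snp_ids(scores, snps)


def _attach_snp_ids(scores: pd.DataFrame, snps: pd.DataFrame) -> GeneScoreTable:
    ids = snps["snp"].to_numpy()
    scores = scores.copy()
    scores.insert(1, "best_snp", ids[scores.pop("best_snp_idx").to_numpy()])
    return GeneScoreTable(scores)


def empirical_gene_p(observed_min_p: float, null_min_p_source,
                     schedule=DEFAULT_SCHEDULE,
                     escalation=DEFAULT_ESCALATION):
    """Adaptive empirical gene p-value from a null min-p source.

    ``null_min_p_source(n)`` must return ``n`` fresh draws of the null
    per-gene minimal p-value.  Returns ``(p_gene, n_used, count)``; a zero
    count means P_g < 1/n_used.
    """
    for stage, n_rep in enumerate(schedule):
        draws = np.asarray(null_min_p_source(n_rep))
        count = int((draws <= observed_min_p).sum())
        p = count / n_rep
        last = stage == len(schedule) - 1
        if last or p > escalation[stage]:
            return p, n_rep, count
    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# confounders and regression-based correction
# --------------------------------------------------------------------------

def independent_snp_count(dosages: np.ndarray,
                          r2_threshold: float = 0.8) -> int:
    """Greedy LD pruning count for one gene's SNPs (columns in map order).

    A SNP is kept iff its composite-LD r^2 (dosage correlation on complete
    pairs) with every previously kept SNP is below the threshold.
    """
    n_snps = dosages.shape[1]
    kept: list[int] = []
    for j in range(n_snps):
        xj = dosages[:, j]
        ok = True
        for k in kept:
            xk = dosages[:, k]
            pair = ~(np.isnan(xj) | np.isnan(xk))
            if pair.sum() < 2:
                continue
            a, b = xj[pair], xk[pair]
            if a.std() == 0 or b.std() == 0:
                r2 = 1.0 if np.array_equal(a, b) else 0.0
            else:
                r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return len(kept)


def confounder_table(model_table, dosages: np.ndarray,
                     r2_threshold: float = 0.8,
                     extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene confounders: size (kb), SNP count, independent-SNP count.

    ``extra`` may carry additional pre-computed columns (e.g. recombination
    hotspots, genetic distance) indexed by gene id.
    """
    m = model_table.models
    rows = []
    for rec in m.itertuples(index=False):
        idx = np.asarray(rec.snp_indices, dtype=int)
        rows.append((
            rec.gene,
            (rec.end - rec.start + 1) / 1000.0,
            len(idx),
            independent_snp_count(dosages[:, idx], r2_threshold),
        ))
    out = pd.DataFrame(rows, columns=["gene", "size_kb", "n_snps",
                                      "n_independent_snps"])
    if extra is not None:
        out = out.merge(extra, on="gene", how="left")
    return out


def regression_corrected_p(best_snp_p: np.ndarray,
                           confounders: pd.DataFrame) -> np.ndarray:
    """Confounder-corrected gene p-values from summary statistics.

    Regresses the gene score -log10(best-SNP p) on the confounder columns
    (OLS with intercept), then converts each residual to its empirical
    upper-tail rank: p_g = #{genes with residual >= residual_g} / (N + 1),
    so the most extreme positive residual attains 1/(N+1).  Collinear
    confounder columns are dropped (later column loses) with a warning.
    """
    p = np.asarray(best_snp_p, dtype=float)
    n = len(p)
    cols = [c for c in confounders.columns if c != "gene"]
    if n < 10 * (len(cols) + 1):
        raise ConfigurationError(
            f"regression correction needs >= 10x more genes ({n}) than "
            f"confounder columns ({len(cols)})"
        )
    score = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))

    x = np.ones((n, 1))
    for c in cols:
        cand = np.column_stack([x, confounders[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > x.shape[1]:
            x = cand
        else:
            warnings.warn(f"dropping collinear confounder column {c!r}")
    beta, *_ = np.linalg.lstsq(x, score, rcond=None)
    resid = score - x @ beta
    # upper-tail rank (ties share the larger count)
    count_ge = stats.rankdata(-resid, method="max")
    return count_ge / (n + 1.0)
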