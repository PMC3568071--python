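"""Gene-set enrichment tests on gene-wise corrected p-values.

The primary test is the leading-edge-fraction comparison: the fraction of a
set's genes whose gene p-values fall below a percentile-defined cut-off of
the genome-wide gene p-value distribution is compared against repeatedly
sampling the same number of gene p-values from the full distribution; the
enrichment p-value is the fraction of samplings with an equal or larger
leading-edge fraction.  Alternative one-sided tests (Wilcoxon-Mann-Whitney,
Kolmogorov-Smirnov, Welch t on -log10 p) probe robustness.  Before any set
test, genes sharing an identical best SNP are collapsed to the one with the
lowest gene p-value, so a single association signal cannot be counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedResultError

DEFAULT_PERCENTILES = (95, 75, 50)
DEFAULT_N_SAMPLINGS = 10_000


def prune_clustered(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse physically clustered genes: one gene per best SNP.

    Within each group of genes sharing the identical best SNP only the gene
    with the lowest gene p-value is retained (ties: first in table order).
    Applied genome-wide, before intersecting with any gene set.
    """
    order = scores.reset_index(drop=True)
    keep_idx = order.groupby("best_snp", sort=False)["p_gene"].idxmin()
    return order.loc[np.sort(keep_idx.to_numpy())].reset_index(drop=True)


def percentile_cutoff(all_gene_p, percentile: float) -> float:
    """P-value threshold at the given percentile of the gene-p distribution.

    The "95th percentile" cut-off isolates the top 5% most significant
    genes, i.e. it is the 5% quantile of the p-values themselves (linear
    interpolation between order statistics).
    """
    p = np.asarray(all_gene_p, dtype=float)
    if p.size == 0:
        raise UndefinedResultError("empty gene p-value list")
    return float(np.quantile(p, (100.0 - percentile) / 100.0,
                             method="linear"))


def leading_edge_test(set_gene_p, all_gene_p, percentile: float,
                      n_samplings: int = DEFAULT_N_SAMPLINGS,
                      rng=None, with_replacement: bool = False):
    """Leading-edge-fraction test of one gene set against the genome.

    Returns ``(fraction, threshold, p)``.  The null samples ``len(set)``
    gene p-values from the full list — without replacement by default, so
    the below-threshold count of one sampling is exactly a hypergeometric
    draw, which is how the counts are generated; ``with_replacement=True``
    switches to binomial draws.  The tie rule is "equal or larger" on the
    null fractions and the p-value is floored at ``1/n_samplings``.
    """
    rng = np.random.default_rng(rng)
    set_p = np.asarray(set_gene_p, dtype=float)
    all_p = np.asarray(all_gene_p, dtype=float)
    if set_p.size == 0:
        raise UndefinedResultError("gene set empty after pruning/intersection")
    thr = percentile_cutoff(all_p, percentile)
    m = set_p.size
    k_obs = int((set_p <= thr).sum())
    f_obs = k_obs / m

    n_below = int((all_p <= thr).sum())
    if with_replacement:
        null_counts = rng.binomial(m, n_below / all_p.size, size=n_samplings)
    else:
        null_counts = rng.hypergeometric(n_below, all_p.size - n_below, m,
                                         size=n_samplings)
    p = (null_counts >= k_obs).sum() / n_samplings
    return f_obs, thr, float(max(p, 1.0 / n_samplings))


def rank_tests(set_gene_p, complement_gene_p):
    """One-sided WMW, KS and Welch-t tests: are the set's p-values smaller?

    WMW is exact when the smaller group has <= 20 members and there are no
    ties, otherwise normal approximation with tie correction.  KS uses the
    one-sided statistic sensitive to the set's ECDF lying above the
    complement's.  The t-test runs on -log10(p) (a t-test on raw bounded
    p-values is ill-behaved), one-sided with the set greater.
    """
    set_p = np.asarray(set_gene_p, dtype=float)
    comp_p = np.asarray(complement_gene_p, dtype=float)
    if set_p.size == 0 or comp_p.size == 0:
        raise UndefinedResultError("empty group in rank tests")

    pooled = np.concatenate([set_p, comp_p])
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if min(set_p.size, comp_p.size) <= 20 and not has_ties
              else "asymptotic")
    p_wmw = stats.mannwhitneyu(set_p, comp_p, alternative="less",
                               method=method).pvalue

    p_ks = stats.ks_2samp(set_p, comp_p, alternative="greater").pvalue

    tiny = np.finfo(float).tiny
    p_t = stats.ttest_ind(-np.log10(np.clip(set_p, tiny, 1.0)),
                          -np.log10(np.clip(comp_p, tiny, 1.0)),
                          equal_var=False, alternative="greater").pvalue
    return float(p_wmw), float(p_ks), float(p_t)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment over ``m`` gene sets: min(1, p*m)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)


@dataclass
class EnrichmentResult:
    """One gene set's full test panel (one output row)."""

    set_name: str
    n_genes_total: int
    n_genes_effective: int
    n_snps_involved: int
    pct_autosomal_snps: float
    p_wmw: float
    p_ks: float
    p_t: float
    cutoffs: dict        # percentile -> p-value threshold
    fractions: dict      # percentile -> leading-edge fraction
    p_gsea: dict         # percentile -> enrichment p

    def to_row(self) -> dict:
        row = {
            "set": self.set_name,
            "n_genes_total": self.n_genes_total,
            "n_genes_effective": self.n_genes_effective,
            "n_snps_involved": self.n_snps_involved,
            "pct_autosomal_snps": self.pct_autosomal_snps,
            "p_wmw": self.p_wmw, "p_ks": self.p_ks, "p_t": self.p_t,
        }
        for pct in self.cutoffs:
            row[f"cutoff_{pct}"] = self.cutoffs[pct]
            row[f"fraction_{pct}"] = self.fractions[pct]
            row[f"p_gsea_{pct}"] = self.p_gsea[pct]
        return row


def enrichment_analysis(pruned_scores: pd.DataFrame, gene_sets,
                        percentiles=DEFAULT_PERCENTILES,
                        n_samplings: int = DEFAULT_N_SAMPLINGS,
                        rng=None, model_table=None,
                        n_autosomal_snps: int | None = None,
                        with_replacement: bool = False) -> list[EnrichmentResult]:
    """Run the full test battery for every gene set.

    ``pruned_scores`` is the genome-wide gene-score table after
    :func:`prune_clustered`.  ``model_table`` (with SNP assignments) and
    ``n_autosomal_snps`` are only needed for the SNP-involvement columns.
    """
    rng = np.random.default_rng(rng)
    universe = pruned_scores.set_index("gene")["p_gene"]
    all_p = universe.to_numpy()

    snp_lookup = {}
    if model_table is not None:
        snp_lookup = dict(zip(model_table.models["gene"],
                              model_table.models["snp_indices"]))
    results = []
    for name, genes in gene_sets:
        in_universe = [g for g in genes if g in universe.index]
        set_p = universe.loc[in_universe].to_numpy()
        comp_p = universe.drop(index=in_universe).to_numpy()

        uniq = set()
        for g in genes:
            uniq.update(np.asarray(snp_lookup.get(g, ()), dtype=int).tolist())
        pct_snps = (100.0 * len(uniq) / n_autosomal_snps
                    if n_autosomal_snps else np.nan)

        if len(set_p) == 0:
            results.append(EnrichmentResult(
                name, len(genes), 0, len(uniq), pct_snps,
                np.nan, np.nan, np.nan, {}, {}, {}))
            continue

        p_wmw, p_ks, p_t = rank_tests(set_p, comp_p)
        cutoffs, fractions, p_gsea = {}, {}, {}
        for pct in percentiles:
            f, thr, p = leading_edge_test(set_p, all_p, pct, n_samplings,
                                          rng, with_replacement)
            cutoffs[pct], fractions[pct], p_gsea[pct] = thr, f, p
        results.append(EnrichmentResult(
            name, len(genes), len(set_p), len(uniq), pct_snps,
            p_wmw, p_ks, p_t, cutoffs, fractions, p_gsea))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
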