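"""Fixed-effect meta-analysis across designs and summary-based enrichment.

Per-SNP log odds ratios from the case-control trend analysis and from trio
TDTs (lnOR = ln(b/c)) are pooled by inverse-variance weighting under a
fixed-effect model (the core of the Kazeem-Farrell case-control + trio
combination).  Because phenotype permutation is impossible on pooled summary
statistics, gene-wise significance downstream of the meta-analysis uses the
regression-based correction from :mod:`snpgsea.scores`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import (
    DEFAULT_N_SAMPLINGS,
    DEFAULT_PERCENTILES,
    EnrichmentResult,
    enrichment_analysis,
    prune_clustered,
)
from .errors import SchemaError, UndefinedResultError
from .scores import confounder_table, regression_corrected_p


@dataclass
class MetaSnpResult:
    """One SNP's fixed-effect combination across studies."""

    snp: str
    ln_or: float
    se: float
    z: float
    p: float
    n_studies: int
    study_ln_or: tuple
    study_se: tuple


def inverse_variance_meta(estimates, snp: str = "") -> MetaSnpResult:
    """Fixed-effect inverse-variance pooling of (lnOR, se) pairs.

    Weights are 1/se^2; the combined SE is 1/sqrt(sum of weights) and the
    two-sided p comes from the normal distribution of z = lnOR/se.
    """
    est = [(lo, se) for lo, se in estimates if np.isfinite(lo) and
           np.isfinite(se) and se > 0]
    if not est:
        raise UndefinedResultError("no usable (lnOR, se) estimate")
    lo = np.array([e[0] for e in est])
    se = np.array([e[1] for e in est])
    w = 1.0 / se ** 2
    combined = float((w * lo).sum() / w.sum())
    se_c = float(1.0 / np.sqrt(w.sum()))
    z = combined / se_c
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaSnpResult(snp, combined, se_c, float(z),
                         max(p, np.finfo(float).tiny), len(est),
                         tuple(lo), tuple(se))


def combine_cc_tdt(cc, tdt) -> MetaSnpResult:
    """Kazeem-Farrell-style combination of one SNP's CC and TDT evidence.

    Both inputs are :class:`~snpgsea.assoc.AssocResult` objects whose lnOR
    must already be oriented to the same (minor) allele.
    """
    return inverse_variance_meta([(cc.ln_or, cc.se_ln_or),
                                  (tdt.ln_or, tdt.se_ln_or)],
                                 snp=cc.snp or tdt.snp)


REQUIRED_STUDY_COLUMNS = ("snp", "ln_or", "se")


def harmonize_alleles(study: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Orient one study's lnOR to the reference study's effect allele.

    Both frames need snp/allele1/allele2 columns; where a study's allele1 is
    the reference's allele2 the lnOR sign is flipped.
    """
    ref = reference.drop_duplicates("snp").set_index("snp")
    out = study.copy()
    a1_ref = out["snp"].map(ref["allele1"])
    a2_ref = out["snp"].map(ref["allele2"])
    flip = out["allele1"].eq(a2_ref) & out["allele2"].eq(a1_ref)
    out.loc[flip, "ln_or"] = -out.loc[flip, "ln_or"]
    return out


def meta_scan(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-SNP fixed-effect combination over study summary frames.

    Each frame needs columns snp, ln_or, se (aligned to the same effect
    allele).  SNPs present in only a subset of studies are combined over the
    available ones; ``n_studies`` records the contribution count.
    """
    for i, s in enumerate(studies):
        missing = [c for c in REQUIRED_STUDY_COLUMNS if c not in s.columns]
        if missing:
            raise SchemaError(f"study {i}: missing column(s) {missing}")
    long = pd.concat(
        [s[["snp", "ln_or", "se"]].assign(study=i)
         for i, s in enumerate(studies)],
        ignore_index=True,
    ).dropna(subset=["ln_or", "se"])
    long = long[long["se"] > 0]

    grouped = long.groupby("snp", sort=False)
    w = 1.0 / long["se"] ** 2
    long = long.assign(w=w, wlo=w * long["ln_or"])
    agg = long.groupby("snp", sort=False).agg(
        sw=("w", "sum"), swlo=("wlo", "sum"), n_studies=("study", "nunique"))
    ln_or = agg["swlo"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    z = ln_or / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "snp": agg.index, "ln_or": ln_or.to_numpy(), "se": se.to_numpy(),
        "z": z.to_numpy(), "p": np.maximum(p, np.finfo(float).tiny),
        "n_studies": agg["n_studies"].to_numpy(),
    }).reset_index(drop=True)


def meta_gene_scores(meta_results: pd.DataFrame, snps: pd.DataFrame,
                     model_table, dosages: np.ndarray,
                     extra_confounders: pd.DataFrame | None = None,
                     r2_threshold: float = 0.8) -> pd.DataFrame:
    """Regression-corrected gene scores from meta-analysis p-values.

    The gene score is the best (smallest) meta p among the gene's SNPs,
    corrected for gene size, SNP count and independent-SNP count via
    :func:`~snpgsea.scores.regression_corrected_p`.  ``dosages`` is a
    reference genotype panel on the same SNP map, used only to estimate LD.
    """
    p_by_snp = pd.Series(meta_results["p"].to_numpy(),
                         index=meta_results["snp"]).reindex(snps["snp"])
    p_arr = p_by_snp.to_numpy()
    snp_ids = snps["snp"].to_numpy()

    m = model_table.models
    best_p, best_snp = [], []
    for idx in m["snp_indices"]:
        idx = np.asarray(idx, dtype=int)
        pg = p_arr[idx]
        if np.all(np.isnan(pg)):
            best_p.append(np.nan)
            best_snp.append(None)
            continue
        k = int(np.nanargmin(pg))
        best_p.append(pg[k])
        best_snp.append(snp_ids[idx[k]])

    conf = confounder_table(model_table, dosages, r2_threshold,
                            extra_confounders)
    keep = ~np.isnan(best_p)
    corrected = np.full(len(m), np.nan)
    corrected[keep] = regression_corrected_p(
        np.asarray(best_p)[keep], conf.loc[keep])
    return pd.DataFrame({
        "gene": m["gene"].to_numpy(), "best_snp": best_snp,
        "p_min": best_p, "p_gene": corrected,
        "n_perms": 0, "n_snps": m["n_snps"].to_numpy(),
        "zero_count": False,
    }).dropna(subset=["p_gene"]).reset_index(drop=True)


def meta_gsea(meta_results: pd.DataFrame, snps: pd.DataFrame, model_table,
              dosages: np.ndarray, gene_sets,
              percentiles=DEFAULT_PERCENTILES,
              n_samplings: int = DEFAULT_N_SAMPLINGS, rng=None,
              extra_confounders: pd.DataFrame | None = None,
              n_autosomal_snps: int | None = None) -> list[EnrichmentResult]:
    """Summary-statistic enrichment: meta p -> corrected gene scores ->
    clustering pruning -> leading-edge + rank tests (identical downstream
    machinery to the individual-level path)."""
    scores = meta_gene_scores(meta_results, snps, model_table, dosages,
                              extra_confounders)
    pruned = prune_clustered(scores)
    return enrichment_analysis(pruned, gene_sets, percentiles, n_samplings,
                               rng, model_table=model_table,
                               n_autosomal_snps=n_autosomal_snps)
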