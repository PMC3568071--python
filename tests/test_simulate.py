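"""Generator correctness: construction invariants, ascertainment oracles,
Hardy-Weinberg calibration, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from snpgsea.config import SimulationConfig
from snpgsea.errors import ConfigurationError, InfeasibleSimulationError
from snpgsea.mapping import merge_transcripts
from snpgsea.qc import hwe_exact_vector, mendelian_flags
from snpgsea.simulate import (
    make_gene_sets,
    simulate_annotation,
    simulate_case_control,
    simulate_snp_map,
    simulate_trios,
)


def tiny_config(**kwargs):
    base = dict(n_cases=50, n_controls=50, n_trios=30, n_chromosomes=1,
                genes_per_chromosome=3, gene_length_range=(30_000, 60_000),
                intergenic_gap_range=(10_000, 20_000),
                snp_spacing_range=(8_000, 15_000),
                maf_range=(0.3, 0.3), seed=5)
    base.update(kwargs)
    return SimulationConfig(**base)


class TestAnnotation:
    def test_zero_genes_gives_empty_annotation(self):
        cfg = tiny_config(genes_per_chromosome=0)
        assert len(simulate_annotation(cfg)) == 0

    def test_tiling_invariants(self):
        cfg = tiny_config(n_chromosomes=2, genes_per_chromosome=10)
        ann = simulate_annotation(cfg)
        t = ann.transcripts
        assert len(t) == 20
        assert (t["tx_start"] < t["tx_end"]).all()
        for _, grp in t.groupby("chrom"):
            assert grp["tx_start"].is_monotonic_increasing

    def test_split_transcript_flagging_matches_independent_scan(self):
        cfg = tiny_config(n_chromosomes=3, genes_per_chromosome=40,
                          split_transcript_fraction=0.05,
                          second_transcript_fraction=0.1, seed=7)
        ann = simulate_annotation(cfg)
        excluded = set(merge_transcripts(ann).exclusions["gene"])
        # independent scan of the emitted table
        expected = set()
        for gene, grp in ann.transcripts.groupby("gene"):
            if grp["chrom"].nunique() > 1:
                expected.add(gene)
                continue
            starts = np.sort(grp["tx_start"].to_numpy())
            ends = grp.sort_values("tx_start")["tx_end"].to_numpy()
            run_end = np.maximum.accumulate(ends)
            if len(grp) > 1 and (starts[1:] - run_end[:-1] > 1e6).any():
                expected.add(gene)
        assert excluded == expected
        assert len(excluded) > 0

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="maf_range"):
            tiny_config(maf_range=(0.0, 0.5))


def ascertained_case_maf(maf, odds_ratio, prevalence):
    """Expected case-group minor-allele frequency by integrating the
    logistic model over the three HWE genotype classes."""
    g = np.array([0, 1, 2])
    prior = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    logit = np.log(prevalence / (1 - prevalence)) + g * np.log(odds_ratio)
    p_case = 1 / (1 + np.exp(-logit))
    post = prior * p_case
    return (g * post).sum() / (2 * post.sum())


class TestCaseControl:
    def test_null_allele_frequencies_balanced(self, null_big):
        _, _, _, m = null_big
        y = m.phenotype
        f_case = m.maf(subject_mask=y == 1)
        f_ctrl = m.maf(subject_mask=y == 0)
        n = (y == 1).sum()
        se = np.sqrt(f_case * (1 - f_case) / (2 * n)
                     + f_ctrl * (1 - f_ctrl) / (2 * n))
        frac_ok = (np.abs(f_case - f_ctrl) <= 3 * se).mean()
        assert frac_ok >= 0.95

    def test_case_frequency_matches_integration_oracle(self):
        cfg = tiny_config(n_cases=800, n_controls=50, baseline_prevalence=0.1)
        ann = simulate_annotation(cfg)
        panel = simulate_snp_map(cfg, ann)
        snp = panel.snps["snp"].iloc[2]
        cfg = replace(cfg, causal_spec=[(snp, 2.0)])
        m = simulate_case_control(cfg, ann, panel)
        j = int(np.flatnonzero(m.snps["snp"] == snp)[0])
        f_obs = m.maf(subject_mask=m.phenotype == 1)[j]
        f_exp = ascertained_case_maf(0.3, 2.0, 0.1)
        se = np.sqrt(f_exp * (1 - f_exp) / (2 * 800))
        assert abs(f_obs - f_exp) <= 3 * se

    def test_raising_or_raises_case_frequency(self):
        freqs = []
        for orr in (1.0, 1.5, 2.0):
            cfg = tiny_config(n_cases=600, n_controls=20, seed=9)
            ann = simulate_annotation(cfg)
            panel = simulate_snp_map(cfg, ann)
            snp = panel.snps["snp"].iloc[0]
            cfg = replace(cfg, causal_spec=[(snp, orr)])
            m = simulate_case_control(cfg, ann, panel)
            freqs.append(m.maf(subject_mask=m.phenotype == 1)[0])
        assert freqs[0] < freqs[1] < freqs[2]

    def test_seed_determinism(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        m1 = simulate_case_control(cfg, ann)
        m2 = simulate_case_control(cfg, ann)
        np.testing.assert_array_equal(m1.dosages, m2.dosages)

    def test_unknown_causal_handle(self):
        cfg = tiny_config(causal_spec=[("rs999999", 2.0)])
        ann = simulate_annotation(cfg)
        with pytest.raises(LookupError):
            simulate_case_control(cfg, ann)

    def test_hwe_holds_without_ld_or_effects(self, null_big):
        """Exact HWE at alpha = 0.001 rejects for at most 0.5% of > 2000
        simulated SNPs."""
        _, _, _, m = null_big
        counts = m.genotype_counts()
        p = hwe_exact_vector(counts)
        assert (p < 0.001).mean() <= 0.005

    def test_adjacent_ld_is_induced(self):
        cfg = tiny_config(ld_rho=0.8, n_cases=200, n_controls=200,
                          genes_per_chromosome=4)
        ann = simulate_annotation(cfg)
        m = simulate_case_control(cfg, ann)
        d = m.dosages
        r = [abs(np.corrcoef(d[:, j], d[:, j + 1])[0, 1])
             for j in range(d.shape[1] - 1)]
        assert np.mean(r) > 0.4


def trio_transmission_oracle(maf, odds_ratio, prevalence):
    """Expected minor-allele transmission probability from heterozygous
    parents to an ascertained affected child, by enumerating parental
    haplotypes and transmissions."""
    e_b = e_c = 0.0
    for fa in ((0, 0), (0, 1), (1, 0), (1, 1)):
        for mo in ((0, 0), (0, 1), (1, 0), (1, 1)):
            w_geno = np.prod([maf if a else 1 - maf for a in fa + mo])
            for tf in (0, 1):
                for tm in (0, 1):
                    w = w_geno / 4.0
                    child = fa[tf] + mo[tm]
                    logit = (np.log(prevalence / (1 - prevalence))
                             + child * np.log(odds_ratio))
                    p_aff = 1 / (1 + np.exp(-logit))
                    b = c = 0
                    if fa[0] != fa[1]:
                        b += fa[tf]
                        c += 1 - fa[tf]
                    if mo[0] != mo[1]:
                        b += mo[tm]
                        c += 1 - mo[tm]
                    e_b += w * p_aff * b
                    e_c += w * p_aff * c
    return e_b / (e_b + e_c)


class TestTrios:
    def test_null_transmissions_balanced(self):
        cfg = tiny_config(n_trios=400, genes_per_chromosome=4,
                          maf_range=(0.1, 0.5), seed=13)
        ann = simulate_annotation(cfg)
        trios = simulate_trios(cfg, ann)
        from snpgsea.assoc import count_transmissions

        b_fam, c_fam = count_transmissions(trios)
        b, c = b_fam.sum(axis=0), c_fam.sum(axis=0)
        ok = np.abs(b - c) <= 3 * np.sqrt(b + c)
        assert ok.mean() >= 0.95

    def test_causal_transmission_matches_enumeration_oracle(self):
        cfg = tiny_config(n_trios=600, baseline_prevalence=0.1, seed=17)
        ann = simulate_annotation(cfg)
        panel = simulate_snp_map(cfg, ann)
        snp = panel.snps["snp"].iloc[1]
        cfg = replace(cfg, causal_spec=[(snp, 2.0)])
        trios = simulate_trios(cfg, ann, panel)
        from snpgsea.assoc import count_transmissions

        j = int(np.flatnonzero(panel.snps["snp"] == snp)[0])
        b_fam, c_fam = count_transmissions(trios)
        b, c = b_fam[:, j].sum(), c_fam[:, j].sum()
        pi_exp = trio_transmission_oracle(0.3, 2.0, 0.1)
        pi_obs = b / (b + c)
        se = np.sqrt(pi_exp * (1 - pi_exp) / (b + c))
        assert abs(pi_obs - pi_exp) <= 3 * se

    def test_clean_trios_mendelian_consistent_and_deterministic(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        t1 = simulate_trios(cfg, ann)
        t2 = simulate_trios(cfg, ann)
        assert mendelian_flags(t1).sum() == 0
        np.testing.assert_array_equal(t1.child, t2.child)

    def test_injected_inconsistencies_found_by_checker(self):
        cfg = tiny_config(n_trios=100, mendel_error_rate=0.01,
                          genes_per_chromosome=5, seed=21)
        ann = simulate_annotation(cfg)
        trios = simulate_trios(cfg, ann)
        flags = mendelian_flags(trios)
        np.testing.assert_array_equal(flags, trios.injected_mendel)
        assert flags.sum() > 0

    def test_zero_prevalence_is_infeasible(self):
        cfg = tiny_config(baseline_prevalence=0.0, trio_draw_cap=2000)
        ann = simulate_annotation(cfg)
        with pytest.raises(InfeasibleSimulationError):
            simulate_trios(cfg, ann)


class TestGeneSets:
    def test_planted_set_named_and_sized(self, small_annotation):
        genes = small_annotation.gene_ids
        sets = make_gene_sets(small_annotation, genes[:16], 0, 5, seed=1)
        assert sets["planted"] == genes[:16]

    def test_decoys_disjoint_exact_size_and_contained(self, small_annotation):
        genes = small_annotation.gene_ids
        planted = genes[:5]
        sets = make_gene_sets(small_annotation, planted, 10, 7, seed=3)
        for name, members in sets:
            if name == "planted":
                continue
            assert len(members) == 7
            assert not set(members) & set(planted)
            assert set(members) <= set(genes)

    def test_oversized_decoy_raises(self, small_annotation):
        genes = small_annotation.gene_ids
        with pytest.raises(ValueError, match="decoy_size"):
            make_gene_sets(small_annotation, genes[:5], 1,
                           len(genes), seed=0)

    def test_unknown_planted_id(self, small_annotation):
        with pytest.raises(LookupError):
            make_gene_sets(small_annotation, ["NOPE"], 1, 3, seed=0)
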