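"""Permutation nulls, adaptive empirical gene p-values, LD pruning counts,
and the regression-based correction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpgsea.assoc import catt
from snpgsea.errors import ConfigurationError, UndefinedResultError
from snpgsea.mapping import map_genes
from snpgsea.scores import (
    empirical_gene_p,
    gene_scores_cc,
    gene_scores_tdt,
    independent_snp_count,
    permutation_null_cc,
    permutation_null_tdt,
    regression_corrected_p,
)

from conftest import toy_annotation, toy_matrix


class TestPermutationStreams:
    def test_case_count_preserved(self):
        y = np.r_[np.ones(7), np.zeros(13)]
        gen = permutation_null_cc(y, np.random.default_rng(0))
        for _ in range(50):
            assert next(gen).sum() == 7

    def test_label_assignments_uniform_over_enumeration(self):
        """3 cases among 6 subjects: the 20 distinct assignments occur with
        frequencies consistent with uniform (chi-square GoF p > 0.001)."""
        y = np.r_[np.ones(3), np.zeros(3)]
        gen = permutation_null_cc(y, np.random.default_rng(1))
        keys = {}
        for combo in combinations(range(6), 3):
            keys[combo] = 0
        for _ in range(20_000):
            v = next(gen)
            keys[tuple(np.flatnonzero(v == 1))] += 1
        counts = np.array(list(keys.values()))
        assert len(counts) == 20
        gof = stats.chisquare(counts).pvalue
        assert gof > 0.001

    def test_same_seed_same_stream(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        g1 = permutation_null_cc(y, np.random.default_rng(42))
        g2 = permutation_null_cc(y, np.random.default_rng(42))
        for _ in range(10):
            np.testing.assert_array_equal(next(g1), next(g2))

    def test_tdt_flip_involution_and_definition(self):
        rng = np.random.default_rng(2)
        b = rng.integers(0, 3, size=(10, 6)).astype(float)
        c = rng.integers(0, 3, size=(10, 6)).astype(float)
        flips = next(permutation_null_tdt(10, np.random.default_rng(5)))
        s = flips.astype(float)
        b_flipped = (1 - s) @ b + s @ c
        # definition: flipped families contribute c_f to b'
        manual = sum((c[f] if flips[f] else b[f]) for f in range(10))
        np.testing.assert_allclose(b_flipped, manual)
        # flipping the same families again restores the original tallies
        b_back = (1 - s) @ np.where(s[:, None], c, b) + \
            s @ np.where(s[:, None], b, c)
        np.testing.assert_allclose(b_back, b.sum(axis=0))


def exhaustive_label_gene_p(dosages, y):
    """Exact P_g for a single-SNP gene by enumerating all case assignments."""
    n = len(y)
    k = int(y.sum())
    d = dosages[:, 0]

    def p_of(case_idx):
        case_mask = np.zeros(n, dtype=bool)
        case_mask[list(case_idx)] = True
        r = tuple((d[case_mask] == g).sum() for g in range(3))
        s = tuple((d[~case_mask] == g).sum() for g in range(3))
        try:
            return catt(r, s).p
        except UndefinedResultError:
            return 1.0

    obs = p_of(tuple(np.flatnonzero(y == 1)))
    null = [p_of(combo) for combo in combinations(range(n), k)]
    return sum(pv <= obs + 1e-12 for pv in null) / len(null), obs


class TestEmpiricalGeneP:
    def make_single_snp_setup(self):
        d = np.array([[0], [1], [2], [0], [1], [2.0]])
        y = np.r_[1.0, 1, 0, 0, 1, 0]
        m = toy_matrix(d, y)
        ann = toy_annotation([("G1", "1", "+", 0, 2000)])
        table, _ = map_genes(ann, m.snps)
        return m, y, table

    def test_matches_exhaustive_enumeration(self):
        m, y, table = self.make_single_snp_setup()
        exact, _ = exhaustive_label_gene_p(m.dosages, y)
        scores = gene_scores_cc(m, table, schedule=(20_000,), escalation=(),
                                rng=0)
        pg = scores.scores["p_gene"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(pg - exact) <= 3 * se + 1e-9

    def test_zero_count_boundary(self):
        calls = []

        def source(n):
            calls.append(n)
            return np.full(n, 0.5)

        p, n_used, count = empirical_gene_p(1e-6, source,
                                            schedule=(100, 1000),
                                            escalation=(0.01,))
        assert count == 0 and p == 0.0 and n_used == 1000
        assert calls == [100, 1000]

    def test_median_gives_half(self):
        rng = np.random.default_rng(3)

        def source(n):
            return rng.uniform(0, 1, n)

        p, n_used, _ = empirical_gene_p(0.5, source, schedule=(10_000,),
                                        escalation=())
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 10_000))

    def test_adaptive_agrees_with_fixed_run(self):
        m, y, table = self.make_single_snp_setup()
        adaptive = gene_scores_cc(m, table, schedule=(500, 5000),
                                  escalation=(1.0,), rng=1)
        fixed = gene_scores_cc(m, table, schedule=(5000,), escalation=(),
                               rng=2)
        pa = adaptive.scores["p_gene"].iloc[0]
        pf = fixed.scores["p_gene"].iloc[0]
        se = np.sqrt(max(pf * (1 - pf), 0.01) / 5000)
        assert abs(pa - pf) <= 3 * se


class TestTdtGeneScores:
    def test_exhaustive_flip_null(self):
        """Exhaustive 2^8 transmission flips reproduce the Monte-Carlo gene
        p within sampling error."""
        rng = np.random.default_rng(4)
        n_fam = 8
        b = rng.integers(0, 3, size=(n_fam, 1)).astype(float)
        c = rng.integers(0, 3, size=(n_fam, 1)).astype(float)
        tot = (b + c).sum()
        obs_stat = (b.sum() - c.sum()) ** 2 / tot

        exact_count = 0
        for mask in range(2 ** n_fam):
            bits = np.array([(mask >> f) & 1 for f in range(n_fam)])
            bp = np.where(bits, c[:, 0], b[:, 0]).sum()
            stat = (2 * bp - tot) ** 2 / tot
            if stat >= obs_stat - 1e-12:
                exact_count += 1
        exact = exact_count / 2 ** n_fam

        snps = pd.DataFrame({"snp": ["s0"], "chrom": "1", "pos": [1000],
                             "allele1": "A", "allele2": "B"})
        ann = toy_annotation([("G1", "1", "+", 0, 2000)])
        table, _ = map_genes(ann, snps)
        scores = gene_scores_tdt(b, c, snps, table, schedule=(20_000,),
                                 escalation=(), rng=0)
        pg = scores.scores["p_gene"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(pg - exact) <= 3 * se + 1e-9


class TestIndependentSnpCount:
    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(200, 5)).astype(float)
        assert independent_snp_count(d) == 5

    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=(100, 1)).astype(float)
        d = np.hstack([x, x])
        assert independent_snp_count(d) == 1

    def test_matches_brute_force_reconstruction(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=(80, 4)).astype(float)
        noisy = np.clip(base + (rng.random((80, 4)) < 0.1), 0, 2)
        d = np.hstack([base, noisy])[:, rng.permutation(8)]

        def brute(dosages, thr=0.8):
            kept = []
            for j in range(dosages.shape[1]):
                if all(np.corrcoef(dosages[:, j], dosages[:, k])[0, 1] ** 2
                       < thr for k in kept):
                    kept.append(j)
            return kept

        assert independent_snp_count(d) == len(brute(d))


class TestRegressionCorrectedP:
    def test_constant_confounders_reduce_to_rank_transform(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        conf = pd.DataFrame({"gene": [f"G{i}" for i in range(50)],
                             "size_kb": 7.0})
        corrected = regression_corrected_p(p, conf)
        # order preserved: smallest raw p -> smallest corrected p
        assert stats.spearmanr(p, corrected).statistic == pytest.approx(1.0)

    def test_max_residual_attains_minimum(self):
        rng = np.random.default_rng(6)
        n = 40
        p = rng.uniform(0.1, 1, n)
        p[17] = 1e-8  # far-outlying score
        conf = pd.DataFrame({"gene": [f"G{i}" for i in range(n)],
                             "n_snps": rng.integers(1, 50, n)})
        corrected = regression_corrected_p(p, conf)
        assert corrected[17] == pytest.approx(1 / (n + 1))

    def test_confounder_effect_removed(self):
        """Scores built as a pure linear function of gene size plus noise:
        corrected p is near-uniform and rank-uncorrelated with size."""
        rng = np.random.default_rng(7)
        n = 2000
        size = rng.uniform(1, 500, n)
        score = 0.01 * size + rng.normal(0, 1, n)
        p = 10.0 ** (-np.clip(score, 0, None))
        conf = pd.DataFrame({"gene": [f"G{i}" for i in range(n)],
                             "size_kb": size})
        corrected = regression_corrected_p(p, conf)
        rho = stats.spearmanr(size, corrected).statistic
        assert abs(rho) < 0.05
        ks = stats.kstest(corrected, "uniform").statistic
        assert ks < 0.05

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        n = 60
        conf = pd.DataFrame({"gene": [f"G{i}" for i in range(n)],
                             "a": rng.normal(size=n)})
        conf["b"] = 2 * conf["a"] + 1
        with pytest.warns(UserWarning, match="collinear"):
            regression_corrected_p(rng.uniform(0, 1, n), conf)

    def test_too_few_genes_raises(self):
        conf = pd.DataFrame({"gene": ["G1", "G2"], "a": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            regression_corrected_p(np.array([0.5, 0.5]), conf)
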