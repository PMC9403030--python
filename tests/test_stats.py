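"""Association machinery: trends, bootstrap, odds ratios, nulls, exact tests."""

import itertools
import math
from math import comb

import numpy as np
import pytest
import statsmodels.api as sm

from foldspec.io import AnchorRecord, GeneModel
from foldspec.stats import (
    ContingencyTable,
    binned_trend,
    bootstrap_se,
    build_or_table,
    downsample_specificity,
    group_compare,
    mantel_haenszel,
    odds_ratio,
    shuffle_null,
    sign_binomial_test,
)


class TestBinnedTrend:
    def test_identity_relation(self):
        x = np.arange(40.0)
        tr = binned_trend(x, x, n_bins=20)
        assert np.all(np.diff(tr.bin_means) > 0)
        assert tr.rho == pytest.approx(1.0)
        assert np.all(tr.bin_sizes == 2)

    def test_constant_y_reported_as_flagged_zero(self):
        x = np.arange(40.0)
        tr = binned_trend(x, np.ones(40), n_bins=20)
        assert np.ptp(tr.bin_means) == 0
        assert tr.rho == 0.0 and not tr.rho_defined

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            binned_trend(np.arange(10.0), np.arange(10.0), n_bins=20)

    def test_remainder_goes_to_leading_bins(self):
        tr = binned_trend(np.arange(43.0), np.arange(43.0), n_bins=20)
        assert list(tr.bin_sizes[:3]) == [3, 3, 3] and set(tr.bin_sizes[3:]) == {2}


class TestBootstrapSE:
    def test_constant_values(self):
        assert bootstrap_se(np.ones(50), seed=0) == 0.0

    def test_se_of_mean_matches_analytic(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        se = bootstrap_se(x, n_boot=1000, seed=1)
        assert se == pytest.approx(1 / math.sqrt(200), rel=0.2)

    def test_seed_determinism(self):
        x = np.random.default_rng(2).normal(size=50)
        assert bootstrap_se(x, seed=7) == bootstrap_se(x, seed=7)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_se(np.arange(10.0), n_boot=1)


class TestOddsRatios:
    def test_symmetric_quadrants(self):
        s = np.array([2.0, 2, 2, 2, 2, 0, 0, 0, 0, 0] * 2)
        cov = np.array([1.0, 1, 1, 1, 1, 1, 1, 1, 1, 1]
                       + [-1.0] * 10)
        t = build_or_table(s, cov)
        assert (t.a, t.b, t.c, t.d) == (6, 6, 6, 6)
        assert odds_ratio(t) == 1.0

    def test_pseudocount_arithmetic(self):
        # raw cells (3,1,1,3) -> (4,2,2,4) -> OR = 16/4 = 4
        t = ContingencyTable(4, 2, 2, 4)
        assert odds_ratio(t) == 4.0

    def test_row_swap_inverts_or(self):
        t = ContingencyTable(5, 2, 3, 7)
        swapped = ContingencyTable(t.c, t.d, t.a, t.b)
        assert odds_ratio(swapped) == pytest.approx(1 / odds_ratio(t))

    def test_or2_flips_covariate_axis(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=50)
        cov = rng.uniform(size=50)
        t1 = build_or_table(s, cov, "OR1")
        t2 = build_or_table(s, cov, "OR2")
        assert (t2.a, t2.b) == (t1.b, t1.a)
        assert (t2.c, t2.d) == (t1.d, t1.c)

    def test_no_common_sites(self):
        with pytest.raises(ValueError):
            build_or_table(np.array([np.nan, 1.0]), np.array([1.0, np.nan]))

    def test_cells_at_least_one(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 1, 1, 1)


class TestMantelHaenszel:
    def test_single_table_equals_or(self):
        t = ContingencyTable(6, 3, 2, 5)
        or_mh, _chi2, _p = mantel_haenszel([t])
        assert or_mh == pytest.approx(odds_ratio(t))

    def test_identical_tables_unchanged(self):
        t = ContingencyTable(6, 3, 2, 5)
        or_mh, _c, _p = mantel_haenszel([t] * 5)
        assert or_mh == pytest.approx(odds_ratio(t))

    def test_balanced_opposite_tables_combine_to_one(self):
        # ORs 2 and 0.5 with equal margins -> combined OR 1 (hand evaluation)
        t1 = ContingencyTable(4, 2, 2, 2)
        t2 = ContingencyTable(2, 4, 2, 2)
        or_mh, _c, _p = mantel_haenszel([t1, t2])
        assert or_mh == pytest.approx(1.0)

    def test_combined_or_within_per_table_range(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            tabs = [
                ContingencyTable(*(1 + rng.integers(0, 30, size=4)))
                for _ in range(rng.integers(2, 8))
            ]
            ors = [odds_ratio(t) for t in tabs]
            or_mh, _c, _p = mantel_haenszel(tabs)
            assert min(ors) - 1e-12 <= or_mh <= max(ors) + 1e-12

    def test_against_statsmodels(self):
        rng = np.random.default_rng(21)
        tabs = [ContingencyTable(*(1 + rng.integers(0, 25, size=4))) for _ in range(6)]
        arrays = [np.array([[t.a, t.b], [t.c, t.d]]) for t in tabs]
        st = sm.stats.StratifiedTable(arrays)
        or_mh, chi2, p = mantel_haenszel(tabs, correction=True)
        assert or_mh == pytest.approx(st.oddsratio_pooled, rel=1e-10)
        ref = st.test_null_odds(correction=True)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-8)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)


class TestShuffleNull:
    @staticmethod
    def _tracks(rng, n_genes=20, n_sites=60, beta=0.0):
        tracks = {}
        for g in range(n_genes):
            s = rng.uniform(size=n_sites)
            cov = beta * s + rng.normal(size=n_sites)
            tracks[f"g{g}"] = (s, cov)
        return tracks

    def test_reproducible_under_seed(self):
        tracks = self._tracks(np.random.default_rng(0))
        a = shuffle_null(tracks, reps=5, seed=3)
        b = shuffle_null(tracks, reps=5, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_correlations_centered(self):
        tracks = self._tracks(np.random.default_rng(1))
        nd = shuffle_null(tracks, reps=50, seed=0)
        se = nd.values.std() / math.sqrt(len(nd.values))
        assert abs(nd.values.mean()) < 2 * se + 0.01

    def test_detects_coupling_by_ks(self):
        rng = np.random.default_rng(2)
        coupled = shuffle_null(self._tracks(rng, beta=3.0), reps=50, seed=0)
        assert coupled.ks_p < 1e-3
        nullish = shuffle_null(self._tracks(rng, beta=0.0), reps=50, seed=0)
        assert nullish.ks_p > 0.01


class TestSignBinomial:
    def test_within_gene_correlation_count_worked_example(self):
        # 101 of 166 genes positive vs null expectation of 83
        assert sign_binomial_test(101, 166) == pytest.approx(0.006, abs=5e-4)

    def test_even_split_gives_one(self):
        assert sign_binomial_test(10, 20) == 1.0

    def test_matches_enumeration_for_small_n(self):
        for n in range(1, 13):
            probs = [comb(n, j) * 0.5**n for j in range(n + 1)]
            for k in range(n + 1):
                expect = sum(pj for pj in probs if pj <= probs[k] + 1e-12)
                assert sign_binomial_test(k, n) == pytest.approx(expect, abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sign_binomial_test(5, 4)


class TestGroupCompare:
    def test_identical_groups(self):
        x = np.arange(10.0)
        _u, p = group_compare(x, x)
        assert p > 0.9

    def test_fully_separated_groups(self):
        u, p = group_compare([1.0, 2, 3], [10.0, 11, 12])
        assert u == 0.0
        assert p < 0.2

    def test_all_tied_flagged(self):
        with pytest.raises(ValueError, match="tied"):
            group_compare([1.0, 1], [1.0, 1])

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            data = rng.permutation(np.arange(8.0))[:7]
            x, y = data[:4], data[4:]
            u_obs, p = group_compare(x, y)
            pooled = np.concatenate([x, y])
            mu = len(x) * len(y) / 2
            devs = []
            for idx in itertools.combinations(range(7), 4):
                xi = pooled[list(idx)]
                yi = np.delete(pooled, list(idx))
                u = sum(a > b for a in xi for b in yi)
                devs.append(abs(u - mu))
            expect = np.mean(np.array(devs) >= abs(u_obs - mu))
            assert p == pytest.approx(expect, abs=1e-12)


class TestDownsample:
    @staticmethod
    def _toy(n_genes=8, depth=9, seed=0):
        rng = np.random.default_rng(seed)
        models, recs = {}, {}
        for g in range(n_genes):
            gid = f"g{g}"
            models[gid] = GeneModel(gid, 300)
            rows = []
            for _ in range(depth):
                i, j = sorted(rng.choice(300, size=2, replace=False))
                rows.append(AnchorRecord(gid, int(i), int(j)))
            recs[gid] = rows
        return models, recs

    def test_full_depth_reproduces_full_data_s(self):
        from conftest import binned_map
        from foldspec.specificity import gene_specificity

        models, recs = self._toy()
        cov = {g: float(i) for i, g in enumerate(models)}
        res = downsample_specificity(recs, models, cov, k=9, reps=4, seed=0)
        full = [gene_specificity(binned_map(recs[g], models[g])).s for g in res.genes_used]
        rho_full = __import__("scipy.stats", fromlist=["stats"]).spearmanr(
            full, [cov[g] for g in res.genes_used]
        ).statistic
        assert np.allclose(res.rho_per_rep, rho_full)

    def test_genes_below_depth_excluded(self):
        models, recs = self._toy()
        recs["g0"] = recs["g0"][:3]
        res = downsample_specificity(recs, models, {g: 1.0 * i for i, g in enumerate(models)},
                                     k=5, reps=3, seed=0)
        assert "g0" in res.genes_excluded

    def test_identical_read_multisets_give_zero_rho(self):
        models, _ = self._toy()
        shared = [AnchorRecord("x", 10, 200), AnchorRecord("x", 50, 250)] * 3
        recs = {g: [AnchorRecord(g, r.pos5, r.pos3) for r in shared] for g in models}
        cov = {g: float(i) for i, g in enumerate(models)}
        res = downsample_specificity(recs, models, cov, k=5, reps=5, seed=1)
        assert res.mean_rho == 0.0
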