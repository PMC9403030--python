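"""Entropy specificity statistic and circularization subsetting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldspec.io import AnchorRecord, GeneModel
from foldspec.specificity import (
    circularization_score,
    entropy_specificity,
    gene_specificity,
    region_specificity,
    site_specificity,
    site_specificity_track,
    specificity_by_circularization,
)

from conftest import binned_map, random_records


def theil_index(w):
    """Independent Theil T implementation: (1/n) sum (x/mu) ln(x/mu)."""
    w = np.asarray(w, float)
    mu = w.mean()
    return float(np.mean((w / mu) * np.log(w / mu)))


class TestEntropySpecificity:
    def test_single_pair_has_zero_specificity(self):
        res = entropy_specificity([1.0])
        assert res.n == 1
        assert res.s == 0.0

    def test_uniform_weights_have_zero_specificity(self):
        assert entropy_specificity([1, 1, 1]).s == pytest.approx(0.0, abs=1e-12)

    def test_three_one_worked_example(self):
        # ln 2 - (0.75 ln(4/3) + 0.25 ln 4), frozen from direct evaluation
        assert entropy_specificity([3, 1]).s == pytest.approx(0.130812035941137, abs=1e-9)

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [-1.0, 2.0], [np.inf]])
    def test_invalid_weights_rejected(self, bad):
        with pytest.raises(ValueError):
            entropy_specificity(bad)

    def test_theil_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            w = rng.uniform(0.01, 10.0, size=rng.integers(2, 40))
            assert entropy_specificity(w).s == pytest.approx(theil_index(w), abs=1e-12)

    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_entropy_bounds_and_scale_invariance(self, weights):
        res = entropy_specificity(weights)
        assert -1e-12 <= res.s <= math.log(len(weights)) + 1e-12
        scaled = entropy_specificity([w * 37.5 for w in weights])
        assert scaled.s == pytest.approx(res.s, abs=1e-9)

    def test_merging_equal_pairs_increases_specificity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            w = [1.0] * n
            merged = [2.0] + [1.0] * (n - 2)
            assert entropy_specificity(merged).s > entropy_specificity(w).s


class TestGeneSpecificity:
    def test_all_distinct_distant_pairs_give_zero(self, gene400):
        recs = [AnchorRecord("g", 30 * k, 30 * k + 200) for k in range(5)]
        cm = binned_map(recs, gene400)
        assert gene_specificity(cm).s == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_pair_with_background(self, gene400):
        # 4 reads on one pair + 1 distant read: binned weights {4, 1}
        recs = [AnchorRecord("g", 50, 250)] * 4 + [AnchorRecord("g", 100, 350)]
        cm = binned_map(recs, gene400)
        # frozen from the entropy oracle: ln2 - H(0.8, 0.2)
        # (weights {4,1}: Mnorm are {4/16, 1} but binned scores keep the
        #  {0.25, 1} ratio -> same S as {1, 4} by scale invariance per pair)
        w = cm.mstar
        expect = entropy_specificity(w).s
        assert gene_specificity(cm).s == pytest.approx(expect)
        assert gene_specificity(cm).n == 2

    def test_raw_and_binned_agree_for_isolated_pairs(self, gene400):
        rng = np.random.default_rng(5)
        recs = [AnchorRecord("g", 10, 150), AnchorRecord("g", 60, 250),
                AnchorRecord("g", 110, 350)]
        cm = binned_map(recs, gene400)
        assert gene_specificity(cm, "raw").s == pytest.approx(
            gene_specificity(cm, "binned").s
        )

    def test_empty_map_undefined(self, gene400):
        from foldspec.io import build_contact_map

        assert gene_specificity(build_contact_map([], gene400)) is None


class TestRegionSpecificity:
    def test_whole_gene_region_equals_gene_value(self, gene400):
        rng = np.random.default_rng(2)
        cm = binned_map(random_records(rng, gene400, 20), gene400)
        whole = region_specificity(cm, [(0, 400)])
        assert whole.s == pytest.approx(gene_specificity(cm).s)

    def test_single_pair_region_zero(self, gene400):
        recs = [AnchorRecord("g", 50, 90), AnchorRecord("g", 200, 300)]
        cm = binned_map(recs, gene400)
        res = region_specificity(cm, [(40, 100)])
        assert res.n == 1 and res.s == 0.0

    def test_region_without_pairs_undefined(self, gene400):
        cm = binned_map([AnchorRecord("g", 50, 90)], gene400)
        assert region_specificity(cm, [(200, 300)]) is None

    def test_cds_only_duplexes(self, gene400):
        # duplexes only within the CDS: UTR undefined, CDS equals gene value
        recs = [AnchorRecord("g", 60, 200)] * 3 + [AnchorRecord("g", 100, 300)]
        cm = binned_map(recs, gene400)
        assert region_specificity(cm, "utr", model=gene400) is None
        cds = region_specificity(cm, "cds", model=gene400)
        assert cds.s == pytest.approx(gene_specificity(cm).s)


class TestSiteSpecificity:
    def test_single_partner_site_zero(self, gene400):
        cm = binned_map([AnchorRecord("g", 50, 250)], gene400)
        assert site_specificity(cm, 50) == 0.0

    def test_uncovered_site_missing(self, gene400):
        cm = binned_map([AnchorRecord("g", 50, 250)], gene400)
        assert math.isnan(site_specificity(cm, 100))

    def test_out_of_range_site(self, gene400):
        cm = binned_map([AnchorRecord("g", 50, 250)], gene400)
        with pytest.raises(IndexError):
            site_specificity(cm, 400)

    def test_two_partner_site_weights(self, gene400):
        # site 50 pairs with 250 (3 reads) and with 350 (1 read); partners are
        # far apart so binned weights keep the 3:1 ratio scaled by coverage
        recs = [AnchorRecord("g", 50, 250)] * 3 + [AnchorRecord("g", 50, 350)]
        cm = binned_map(recs, gene400)
        keep = (cm.pair_i == 50) | (cm.pair_j == 50)
        expect = entropy_specificity(cm.mstar[keep]).s
        assert site_specificity(cm, 50) == pytest.approx(expect)

    def test_track_matches_per_site_loop(self, gene400):
        rng = np.random.default_rng(9)
        cm = binned_map(random_records(rng, gene400, 40), gene400)
        track = site_specificity_track(cm)
        for pos in range(gene400.length):
            one = site_specificity(cm, pos)
            if math.isnan(one):
                assert not track.defined()[pos]
            else:
                assert track.s[pos] == pytest.approx(one, abs=1e-10)
                assert track.support[pos] > 0


class TestCircularization:
    def test_score_examples(self):
        gene = GeneModel("g", 200)
        assert circularization_score(AnchorRecord("g", 10, 110), gene).score == 0.5
        assert circularization_score(AnchorRecord("g", 7, 8), gene).score == pytest.approx(1 / 200)
        assert circularization_score(AnchorRecord("g", 0, 199), gene).score == pytest.approx(199 / 200)

    def test_full_fraction_equals_full_data(self, gene400):
        rng = np.random.default_rng(4)
        recs = random_records(rng, gene400, 25)
        full = specificity_by_circularization({"g": recs}, {"g": gene400}, fraction=1.0)
        cm = binned_map(recs, gene400)
        assert full["g"].s == pytest.approx(gene_specificity(cm).s)

    def test_proximal_subset_keeps_short_range_reads(self, gene400):
        short = [AnchorRecord("g", 100 + k, 130 + k) for k in range(5)]
        long = [AnchorRecord("g", 20 + k, 370 + k) for k in range(5)]
        recs = short + long
        # sorting oracle: bottom-50% circularization scores are the short reads
        scores = sorted(recs, key=lambda r: abs(r.pos3 - r.pos5) / 400)
        assert set(id(r) for r in scores[:5]) == set(id(r) for r in short)
        prox = specificity_by_circularization(
            {"g": recs}, {"g": gene400}, fraction=0.5, side="proximal"
        )
        expect = gene_specificity(binned_map(short, gene400)).s
        assert prox["g"].s == pytest.approx(expect)

    def test_empty_gene_dropped(self, gene400):
        out = specificity_by_circularization({"g": []}, {"g": gene400}, fraction=0.05)
        assert out == {}

    def test_invalid_fraction(self, gene400):
        with pytest.raises(ValueError):
            specificity_by_circularization({"g": []}, {"g": gene400}, fraction=0.0)
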