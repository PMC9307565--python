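import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from radharm import (centre_pair_jsd, compare_methods, correlation_filter,
                     jsd, jsd_hist, summarise)
from radharm.variability import bonferroni

from _oracles import correlation_filter_oracle
from test_combat import make_table


class TestCorrelationFilter:
    def test_duplicated_column_removed(self, rng):
        x = rng.normal(0, 1, (30, 3))
        x[:, 2] = x[:, 0]
        t = make_table(x, ["B0"] * 30)
        filtered, removed = correlation_filter(t, 0.9)
        assert removed == ["LV|firstorder|F02"]
        assert filtered.data.shape[1] == 2

    def test_independent_columns_survive(self, rng):
        x = rng.normal(0, 1, (500, 8))
        t = make_table(x, ["B0"] * 500)
        filtered, removed = correlation_filter(t, 0.9)
        assert removed == []
        assert filtered.data.shape[1] == 8

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        """Correlated random tables of <= 10 features: the greedy filter must
        keep exactly the columns the exhaustive scan keeps."""
        rng = np.random.default_rng(seed)
        n, p = 40, int(rng.integers(2, 11))
        base = rng.normal(0, 1, (n, max(2, p // 2)))
        x = np.empty((n, p))
        for j in range(p):
            src = base[:, rng.integers(0, base.shape[1])]
            x[:, j] = src + rng.normal(0, rng.uniform(0.01, 2.0), n)
        t = make_table(x, ["B0"] * n)
        filtered, _ = correlation_filter(t, 0.9)
        kept = correlation_filter_oracle(x, 0.9)
        expected = [t.data.columns[j] for j in kept]
        assert list(filtered.data.columns) == expected

    def test_zero_variance_column_removed_with_warning(self, rng):
        x = rng.normal(0, 1, (20, 3))
        x[:, 1] = 2.0
        t = make_table(x, ["B0"] * 20)
        with pytest.warns(UserWarning, match="zero-variance"):
            filtered, removed = correlation_filter(t, 0.9)
        assert "LV|firstorder|F01" in removed

    def test_bad_threshold_rejected(self, rng):
        t = make_table(rng.normal(0, 1, (5, 2)), ["B0"] * 5)
        with pytest.raises(ValueError):
            correlation_filter(t, 0.0)


class TestJSD:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(0, 1, 200)
        assert jsd(x, x) == 0.0

    def test_disjoint_supports_give_one(self, rng):
        a = rng.uniform(0, 1, 500)
        b = rng.uniform(10, 11, 500)
        assert jsd(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_three_bin_case(self):
        assert jsd_hist([0.5, 0.5, 0.0], [0.0, 0.5, 0.5],
                        eps=0.0) == pytest.approx(0.5)

    def test_matches_scipy_on_histograms(self, rng):
        """Independent route: scipy's jensenshannon (distance = sqrt JSD)."""
        for _ in range(50):
            p = rng.random(12)
            q = rng.random(12)
            ours = jsd_hist(p, q, eps=0.0)
            theirs = jensenshannon(p, q, base=2) ** 2
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_symmetry_and_bounds_fuzz(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(2, 40)))
            q = rng.random(p.size)
            a, b = jsd_hist(p, q), jsd_hist(q, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0

    def test_degenerate_support_warns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert jsd(np.full(5, 2.0), np.full(7, 2.0)) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.array([]), np.array([1.0]))


def _multicentre_table(rng, n_centres=3, n_per=12, n_feat=4, shift=0.0):
    blocks, centres = [], []
    for c in range(n_centres):
        blocks.append(rng.normal(shift * c, 1, (n_per, n_feat)))
        centres += [f"C{c + 1}"] * n_per
    return make_table(np.vstack(blocks), centres)


class TestCentrePairJSD:
    def test_all_pairs_covered(self, rng):
        t = _multicentre_table(rng, n_centres=5)
        records = centre_pair_jsd(t, r2_threshold=None)
        df = pd.DataFrame([r.__dict__ for r in records])
        pairs = df.groupby("feature").size()
        assert (pairs == 10).all()  # C(5, 2)

    def test_identical_centres_give_zero(self, rng):
        block = rng.normal(0, 1, (10, 3))
        t = make_table(np.vstack([block, block]), ["C1"] * 10 + ["C2"] * 10)
        records = centre_pair_jsd(t, r2_threshold=None)
        assert all(r.jsd == 0.0 for r in records)

    def test_location_shift_raises_jsd_monotonically(self, rng):
        vals = []
        for shift in (0.0, 1.0, 3.0):
            t = _multicentre_table(rng, n_centres=2, n_per=60, n_feat=1,
                                   shift=shift)
            rec = centre_pair_jsd(t, r2_threshold=None)
            vals.append(np.mean([r.jsd for r in rec]))
        assert vals[0] < vals[1] < vals[2]

    def test_single_centre_rejected(self, rng):
        t = make_table(rng.normal(0, 1, (6, 2)), ["C1"] * 6)
        with pytest.raises(ValueError, match="2 centres"):
            centre_pair_jsd(t)

    def test_healthy_only_default(self, rng):
        x = rng.normal(0, 1, (20, 2))
        t = make_table(x, ["C1"] * 10 + ["C2"] * 10,
                       pathology=["healthy"] * 5 + ["HCM"] * 5
                       + ["healthy"] * 5 + ["HCM"] * 5)
        records = centre_pair_jsd(t, r2_threshold=None, min_subjects=2)
        assert records  # healthy rows suffice


class TestSummarise:
    def _records(self, jsds):
        t_rng = np.random.default_rng(0)
        t = _multicentre_table(t_rng, n_centres=2, n_per=5, n_feat=len(jsds))
        records = centre_pair_jsd(t, r2_threshold=None)
        for r, v in zip(records, jsds):
            r.jsd = v
        return records

    def test_threshold_counting(self):
        rep = summarise(self._records([0.009, 0.012]), tau=0.01)
        assert rep.proportions["mean"].iloc[0] == pytest.approx(50.0)

    def test_all_zero_jsd_gives_hundred_percent(self):
        rep = summarise(self._records([0.0, 0.0, 0.0]), tau=0.01)
        assert (rep.proportions["mean"] == 100.0).all()

    def test_tau_zero_strict_inequality(self):
        rep = summarise(self._records([0.0, 0.0]), tau=0.0)
        assert (rep.proportions["mean"] == 0.0).all()

    def test_permutation_invariant_to_record_order(self, rng):
        t = _multicentre_table(rng, n_centres=3, n_per=15, n_feat=5, shift=0.5)
        records = centre_pair_jsd(t, r2_threshold=None)
        rep_a = summarise(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        rep_b = summarise(shuffled)
        pd.testing.assert_frame_equal(rep_a.proportions, rep_b.proportions)
        pd.testing.assert_frame_equal(
            rep_a.family_summary, rep_b.family_summary)


class TestCompareMethods:
    def test_identical_groups_maximal_p(self):
        res = compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test == "mannwhitneyu"
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_u_statistic(self):
        res = compare_methods([1.0, 2.0], [3.0, 4.0])
        # U for the first group under complete separation is 0
        assert min(res.statistic, 2 * 2 - res.statistic) == 0.0

    def test_three_groups_use_kruskal(self, rng):
        res = compare_methods(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                              rng.normal(5, 1, 10))
        assert res.test == "kruskal"
        assert res.p_value < 0.01

    def test_bonferroni_adjustment(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.002)
        res = compare_methods([1, 2, 3], [4, 5, 6], n_comparisons=5)
        assert res.alpha_adjusted == pytest.approx(0.002)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([], [1.0])
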