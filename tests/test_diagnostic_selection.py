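"""Binning, carry-over quotas, participant exclusion, final selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glossbench import diagnostic_selection as ds


def _binary_table(means, n_obs=10):
    """Response table whose per-image means equal ``means`` exactly."""
    rows = []
    for ii, m in enumerate(means):
        ones = int(round(m * n_obs))
        for oi in range(n_obs):
            rows.append((f"o{oi}", f"i{ii}", "binary", 1.0 if oi < ones else 0.0, 0))
    return pd.DataFrame(rows, columns=["observer_id", "image_id", "task", "response", "repeat_index"])


class TestBinning:
    def test_binary_sevenths_edge_arithmetic(self):
        bins = ds.bin_by_mean_response(_binary_table([0.0, 0.5, 1.0]), 7)
        assert bins.loc["i0"] == 1 and bins.loc["i1"] == 4 and bins.loc["i2"] == 7

    def test_identical_means_share_one_bin(self):
        bins = ds.bin_by_mean_response(_binary_table([0.4] * 5), 7)
        assert bins.nunique() == 1

    def test_interior_edge_goes_to_higher_bin(self):
        bins = ds.bin_by_mean_response(_binary_table([0.5]), 2)
        assert bins.loc["i0"] == 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            ds.bin_by_mean_response(_binary_table([0.5]), 1)


class TestCarryover:
    def _bins(self, sizes):
        data = {}
        k = 0
        for b, n in enumerate(sizes, start=1):
            for _ in range(n):
                data[f"i{k}"] = b
                k += 1
        return pd.Series(data)

    def test_hand_traced_carryover(self):
        """Bins (1,2,10) with targets (4,4,4): take 1, 2, then 9 = 12."""
        sel = ds.select_with_carryover(self._bins([1, 2, 10]), [4, 4, 4], [1, 2, 3], seed=0)
        assert len(sel) == 12

    def test_exact_supply_is_deterministic_union(self):
        bins = self._bins([3, 3, 3])
        a = ds.select_with_carryover(bins, [3, 3, 3], [1, 2, 3], seed=0)
        b = ds.select_with_carryover(bins, [3, 3, 3], [1, 2, 3], seed=99)
        assert sorted(a) == sorted(b) == sorted(bins.index)

    def test_paper_quota_pattern(self):
        """7 ample bins, 108 from the first visited and 107 elsewhere: 750."""
        bins = self._bins([120] * 7)
        sel = ds.select_with_carryover(bins, [108] + [107] * 6, [7, 6, 5, 4, 3, 2, 1], seed=1)
        assert len(sel) == 750
        assert len(set(sel)) == 750

    def test_infeasible_supply_reports_deficit(self):
        with pytest.raises(ValueError, match="short by"):
            ds.select_with_carryover(self._bins([1, 1]), [2, 2], [1, 2], seed=0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 12), min_size=2, max_size=6), st.data())
    def test_total_selected_equals_quota_whenever_feasible(self, sizes, data):
        """Against a feasibility oracle: supply >= quota implies exact total."""
        bins = self._bins(sizes)
        targets = [data.draw(st.integers(0, 8)) for _ in sizes]
        order = list(range(1, len(sizes) + 1))
        feasible = sum(sizes) >= sum(targets)
        if feasible:
            sel = ds.select_with_carryover(bins, targets, order, seed=3)
            assert len(sel) == sum(targets)
            assert len(set(sel)) == len(sel)
        else:
            with pytest.raises(ValueError):
                ds.select_with_carryover(bins, targets, order, seed=3)


class TestExcludeParticipants:
    def _rating_table(self, n_obs, violators=(), n_images=5, wrong_count=()):
        rows = []
        for oi in range(n_obs):
            obs = f"o{oi}"
            imgs = range(n_images - 1) if obs in wrong_count else range(n_images)
            for ii in imgs:
                rows.append((obs, f"i{ii}", "rating5", 3, 0))
            teapot = 2 if obs in violators else 5
            sandcastle = 4 if obs in violators else 1
            rows.append((obs, "catch_teapot", "rating5", teapot, 0))
            rows.append((obs, "catch_sandcastle", "rating5", sandcastle, 0))
        return pd.DataFrame(rows, columns=["observer_id", "image_id", "task", "response", "repeat_index"])

    def test_low_teapot_rating_excluded(self):
        t = self._rating_table(3, violators={"o1"})
        out = ds.exclude_participants(t, expected_trials=7)
        assert set(out["observer_id"]) == {"o0", "o2"}

    def test_compliant_observer_kept(self):
        t = self._rating_table(1)
        out = ds.exclude_participants(t, expected_trials=7)
        assert set(out["observer_id"]) == {"o0"}
        assert not out["image_id"].str.startswith("catch").any()

    def test_wrong_trial_count_excluded(self):
        t = self._rating_table(3, wrong_count={"o2"})
        out = ds.exclude_participants(t, expected_trials=7)
        assert "o2" not in set(out["observer_id"])

    def test_crowd_panel_99_minus_35_leaves_64(self):
        """The synthetic crowd: 99 raters, 35 rule violators, 64 survivors."""
        violators = {f"o{i}" for i in range(0, 70, 2)}  # 35 observers
        t = self._rating_table(99, violators=violators)
        out = ds.exclude_participants(t, expected_trials=7)
        assert out["observer_id"].nunique() == 64


class TestFinalSelection:
    def _candidates(self, per_cell=12, seed=0):
        """Bins are equal-width over the observed rating range; anchor the
        range at exactly [1, 5] so cells align with nominal fifths."""
        rng = np.random.default_rng(seed)
        rows, ratings = [], {}
        k = 0
        for material in ("high", "low"):
            for b in (1, 2, 3, 4, 5):
                n = per_cell if b in (2, 3, 4) else 2
                for j in range(n):
                    iid = f"c{k}"
                    rows.append((iid, material))
                    lo = 1.0 + (b - 1) * 0.8
                    ratings[iid] = rng.uniform(lo + 1e-6, lo + 0.8 - 1e-6)
                    k += 1
        ratings["c0"] = 1.0  # range anchors
        ratings[f"c{k - 1}"] = 5.0
        return pd.DataFrame(rows, columns=["image_id", "material"]), pd.Series(ratings)

    def test_final_set_is_60_balanced(self):
        cand, ratings = self._candidates()
        out = ds.select_final_diagnostic(cand, ratings, seed=4)
        assert len(out) == 60
        assert (out["material"].value_counts() == 30).all()
        assert (out.groupby(["material", "bin"]).size() == 10).all()

    def test_exact_cells_are_deterministic(self):
        cand, ratings = self._candidates(per_cell=10)
        a = ds.select_final_diagnostic(cand, ratings, seed=1)
        b = ds.select_final_diagnostic(cand, ratings, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_same_seed_reproduces_selection(self):
        cand, ratings = self._candidates()
        a = ds.select_final_diagnostic(cand, ratings, seed=7)
        b = ds.select_final_diagnostic(cand, ratings, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_short_cell_error_names_cell(self):
        cand, ratings = self._candidates(per_cell=9)
        with pytest.raises(ValueError, match="material=high, bin=2"):
            ds.select_final_diagnostic(cand, ratings, seed=0)


class TestDecorrelationCheck:
    def test_means_equal_labels(self):
        means = pd.Series({"a": 1.0, "b": 0.0, "c": 1.0, "d": 0.0})
        truth = pd.Series({"a": "high", "b": "low", "c": "high", "d": "low"})
        r, acc = ds.decorrelation_check(means, truth)
        assert r == pytest.approx(1.0) and acc == 1.0

    def test_independent_means_near_chance(self):
        rng = np.random.default_rng(11)
        ids = [f"i{k}" for k in range(400)]
        means = pd.Series(rng.uniform(1, 5, 400), index=ids)
        truth = pd.Series(rng.choice(["high", "low"], 400), index=ids)
        r, acc = ds.decorrelation_check(means, truth)
        assert abs(r) < 0.15
        assert 0.4 < acc < 0.6
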