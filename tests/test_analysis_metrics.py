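"""Summary metrics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from glossbench import analysis_metrics as am


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx**0.5 * vy**0.5)


class TestPearson:
    def test_matches_bruteforce_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y = rng.random(100), rng.random(100)
            assert am.pearson_r(x, y) == pytest.approx(brute_force_pearson(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            am.pearson_r(np.ones(3), np.ones(4))


class TestLooCorrelations:
    def _table(self, vectors):
        rows = []
        for oi, v in enumerate(vectors):
            for ii, val in enumerate(v):
                rows.append((f"o{oi}", f"i{ii}", "binary", float(val), 0))
        return pd.DataFrame(rows, columns=["observer_id", "image_id", "task", "response", "repeat_index"])

    def test_identical_observers_correlate_fully(self):
        v = [0.0, 1.0, 0.5, 0.2, 0.9]
        loo = am.loo_human_correlations(self._table([v, v, v, v]))
        assert np.allclose(loo, 1.0)

    def test_anticorrelated_observer_scores_minus_one(self):
        v = np.array([0.0, 1.0, 0.5, 0.2, 0.9])
        loo = am.loo_human_correlations(self._table([v, v, v, 1 - v]))
        assert loo["o3"] == pytest.approx(-1.0)
        assert np.allclose(loo[["o0", "o1", "o2"]], 1.0)

    def test_too_few_observers_rejected(self):
        with pytest.raises(ValueError):
            am.loo_human_correlations(self._table([[0, 1], [1, 0]]))


def _records_with_exact_rho(rhos, depths, n=3):
    """Per depth, three (accuracy, objective) points with exact Pearson rho."""
    rows = []
    trial = 0
    a = np.array([-1.0, 0.0, 1.0])
    b = np.array([1.0, -2.0, 1.0])
    b = b / np.linalg.norm(b) * np.linalg.norm(a)
    for d, rho in zip(depths, rhos):
        obj = rho * a + np.sqrt(max(0.0, 1 - rho**2)) * b
        for acc, o in zip(a, obj):
            rows.append((d, trial, o, 0.5 + 0.1 * acc, False))
            trial += 1
    return pd.DataFrame(rows, columns=["depth", "trial", "objective", "val_accuracy", "dead"])


class TestDepthTrend:
    def test_constructed_rhos_cross_between_three_and_four(self):
        rhos = (0.6, 0.4, 0.1, -0.1, -0.3)
        trend = am.depth_trend(_records_with_exact_rho(rhos, (1, 2, 3, 4, 5)))
        assert np.allclose(trend.per_depth_rho.to_numpy(), rhos, atol=1e-9)
        # oracle: roots of the same quadratic fit
        want = np.roots(np.polyfit([1, 2, 3, 4, 5], rhos, 2))
        want = min(r.real for r in want if 1 <= r.real <= 5)
        assert trend.zero_crossing == pytest.approx(want)
        assert 3.0 < trend.zero_crossing < 4.0

    def test_accuracy_equal_to_objective_gives_unit_rhos_no_root(self):
        rows = []
        for trial, (d, v) in enumerate([(d, v) for d in (1, 2, 3) for v in (0.1, 0.5, 0.9)]):
            rows.append((d, trial, v, v, False))
        rec = pd.DataFrame(rows, columns=["depth", "trial", "objective", "val_accuracy", "dead"])
        trend = am.depth_trend(rec)
        assert np.allclose(trend.per_depth_rho, 1.0)
        assert trend.zero_crossing is None

    def test_zero_variance_depth_excluded_with_warning(self):
        rec = _records_with_exact_rho((0.5, -0.5, 0.2), (1, 2, 3))
        rec.loc[rec["depth"] == 2, "val_accuracy"] = 0.7
        with pytest.warns(RuntimeWarning):
            trend = am.depth_trend(rec)
        assert 2 not in trend.per_depth_rho.index


class TestTopDecile:
    def _records(self, n=100, depth_of=lambda i: 1 + i % 5, r_of=lambda i: i / 100):
        return pd.DataFrame(
            {
                "depth": [depth_of(i) for i in range(n)],
                "trial": range(n),
                "objective": [r_of(i) for i in range(n)],
                "val_accuracy": 0.8,
                "dead": False,
            }
        )

    def test_hundred_unique_scores_select_ten(self):
        props = am.top_decile_composition(self._records())
        assert props.sum() == pytest.approx(1.0)
        # top 10 of r=i/100 are i=90..99, depths cycle 1..5 evenly
        assert (props == 0.2).all()

    def test_single_depth_dominance(self):
        rec = self._records(depth_of=lambda i: 1 if i >= 90 else 2)
        props = am.top_decile_composition(rec)
        assert props.loc[1] == pytest.approx(1.0)

    def test_boundary_ties_break_by_trial_id(self):
        rec = self._records(r_of=lambda i: 0.5)  # all tied
        props = am.top_decile_composition(rec)
        # deterministic: trials 0..9 selected, depths 1..5 cycling twice
        assert (props == 0.2).all()
        again = am.top_decile_composition(rec)
        pd.testing.assert_series_equal(props, again)


class TestTriangle:
    @pytest.mark.parametrize(
        "point,gloss,real",
        [((0.0, 0.0), 0.0, 0.0), ((1.0, 0.0), 1.0, 0.0), ((0.5, 1.0), 0.5, 1.0), ((0.625, 0.5), 0.75, 0.5)],
    )
    def test_known_points(self, point, gloss, real):
        g, r = am.triangle_decompose([point])
        assert g[0] == pytest.approx(gloss)
        assert r[0] == pytest.approx(real)

    def test_outside_point_rejected(self):
        with pytest.raises(ValueError):
            am.triangle_decompose([(0.1, 0.9)])

    def test_invariant_to_canvas_scaling(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 1, 50)
        x = y / 2 + rng.uniform(0, 1, 50) * (1 - y)
        pts = np.c_[x, y]
        g1, r1 = am.triangle_decompose(pts)
        g2, r2 = am.triangle_decompose(pts * 7.5, canvas=7.5)
        assert np.allclose(g1, g2) and np.allclose(r1, r2)


class TestRatingAccuracyAndDprime:
    def test_perfect_separation(self):
        g = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        assert am.rating_accuracy(g, labels) == 1.0

    def test_midpoint_counts_incorrect(self):
        assert am.rating_accuracy(np.array([0.5, 0.5]), np.array([1, 0])) == 0.0

    def test_identical_groups_give_zero(self):
        g = np.array([0.2, 0.5, 0.8])
        assert am.dprime(g, g) == 0.0

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(2)
        h = rng.normal(0.7, 0.1, 100_000)
        l = rng.normal(0.6, 0.1, 100_000)
        assert am.dprime(h, l) == pytest.approx(1.0, abs=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        h, l = rng.normal(1, 0.3, 500), rng.normal(0, 0.3, 500)
        assert am.dprime(2.5 * h - 7, 2.5 * l - 7) == pytest.approx(am.dprime(h, l), abs=1e-10)

    def test_zero_variance_sentinel(self):
        assert am.dprime(np.array([0.9, 0.9]), np.array([0.1, 0.1])) == np.inf
        assert am.dprime(np.array([0.1, 0.1]), np.array([0.9, 0.9])) == -np.inf
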