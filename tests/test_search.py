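"""Human-likeness search: objective, samplers, plan bookkeeping."""

import numpy as np
import pytest

from glossbench import cnn_zoo as cz
from glossbench import human_likeness_search as hls


class _StubModel:
    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=float)

    def predict_proba(self, X):
        return self.outputs


def _record(outputs, dead=False):
    hp = cz.TrainingHyperParams(0.1, 0.9, 0.0, val_interval=1, patience=1, max_steps=5)
    return cz.TrainRecord(None, hp, [(1, 0.5, 0.5)], 1, 0.5, 0.5, dead, model=_StubModel(outputs))


class TestObjective:
    def test_perfect_match_and_inversion(self):
        means = np.array([0.2, 0.5, 0.8])
        imgs = np.zeros((3, 3, 8, 8))
        assert hls.objective(_record(means), imgs, means) == pytest.approx(1.0)
        assert hls.objective(_record(1 - means), imgs, means) == pytest.approx(-1.0)

    def test_three_point_value_matches_bruteforce(self):
        """Closed-form Pearson of (0.1,0.4,0.9) vs (0.2,0.5,0.8)."""
        x, y = np.array([0.1, 0.4, 0.9]), np.array([0.2, 0.5, 0.8])
        dx, dy = x - x.mean(), y - y.mean()
        want = float(dx @ dy / np.sqrt((dx @ dx) * (dy @ dy)))
        got = hls.objective(_record(x), np.zeros((3, 3, 8, 8)), y)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.989743, abs=1e-6)

    def test_zero_variance_returns_none(self):
        assert hls.objective(_record([0.5, 0.5, 0.5]), np.zeros((3, 3, 8, 8)), np.array([0.1, 0.5, 0.9])) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hls.objective(_record([0.5, 0.6]), np.zeros((2, 3, 8, 8)), np.array([0.1, 0.5, 0.9]))


class TestSamplers:
    def _defs(self):
        return hls.SearchSpace().param_defs(depth=2)

    def _history(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        hist = []
        for _ in range(n):
            p = hls.RandomSampler().propose(self._defs(), [], rng)
            hist.append((p, float(rng.uniform(-1, 1))))
        return hist

    @pytest.mark.parametrize("sampler", ["tpe", "gp-ei", "random"])
    def test_proposals_respect_domains(self, sampler):
        defs = self._defs()
        s = hls.SAMPLERS[sampler]()
        p = s.propose(defs, self._history(), np.random.default_rng(1))
        space = hls.SearchSpace()
        assert space.lr_min <= p["lr"] <= space.lr_max
        assert space.momentum_min <= p["momentum"] <= space.momentum_max
        assert space.l2_min <= p["l2"] <= space.l2_max
        for i in range(2):
            assert space.filters_min <= p[f"filters_{i}"] <= space.filters_max
            assert p[f"kernel_{i}"] in space.kernel_choices

    def test_random_sampler_deterministic(self):
        defs = self._defs()
        a = hls.RandomSampler().propose(defs, [], np.random.default_rng(7))
        b = hls.RandomSampler().propose(defs, [], np.random.default_rng(7))
        assert a == b

    def test_deep_space_includes_pool_free_choice(self):
        defs = hls.SearchSpace().param_defs(depth=8)
        p = hls.RandomSampler().propose(defs, [], np.random.default_rng(2))
        assert len(p["pool_free"]) == 2
        spec = hls.params_to_spec(8, p, input_size=256)
        assert spec.depth == 8


class TestPlanManifest:
    def test_full_scale_plan_is_2700_trials(self):
        plan = hls.plan_manifest([1, 2, 3, 4, 5, 6, 7, 8, 12], 300)
        assert len(plan) == 2700

    def test_single_row(self):
        assert len(hls.plan_manifest([3], 1)) == 1

    def test_contiguous_per_depth_indices(self):
        plan = hls.plan_manifest([1, 2], 3)
        assert len(plan) == 6
        for d in (1, 2):
            assert list(plan[plan["depth"] == d]["trial_index"]) == [0, 1, 2]


class TestRunSearch:
    def _tiny_setup(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.tile([0.0, 1.0], n // 2)
        X = rng.standard_normal((n, 3, 16, 16)) * 0.2
        X[y == 1, 0, 4:8, 4:8] += 1.0
        data = cz.TrainData(X[:32], y[:32], X[32:], y[32:])
        diag = X[: 10]
        means = np.clip(y[:10] * 0.6 + 0.2 + rng.normal(0, 0.05, 10), 0, 1)
        hp = cz.TrainingHyperParams(0.05, 0.9, 1e-4, batch_size=8, val_interval=10, patience=3, max_steps=60)
        return data, diag, means, hp

    def test_random_search_reproducible(self):
        data, diag, means, hp = self._tiny_setup()
        kw = dict(data=data, diagnostic_images=diag, human_means=means, input_size=16, base_hp=hp)
        a = hls.run_search(1, 4, hls.SearchSpace(filters_max=8), sampler="random", seed=5, **kw)
        b = hls.run_search(1, 4, hls.SearchSpace(filters_max=8), sampler="random", seed=5, **kw)
        assert [t.params for t in a.trials] == [t.params for t in b.trials]
        assert [t.objective for t in a.trials] == [t.objective for t in b.trials]

    def test_search_is_resumable(self):
        data, diag, means, hp = self._tiny_setup()
        kw = dict(data=data, diagnostic_images=diag, human_means=means, input_size=16, base_hp=hp)
        full = hls.run_search(1, 4, hls.SearchSpace(filters_max=8), sampler="random", seed=6, **kw)
        part = hls.run_search(1, 2, hls.SearchSpace(filters_max=8), sampler="random", seed=6, **kw)
        resumed = hls.run_search(1, 4, hls.SearchSpace(filters_max=8), sampler="random", seed=6, record=part, **kw)
        assert [t.params for t in resumed.trials] == [t.params for t in full.trials]

    def test_dead_trials_carry_no_objective_and_isolate_bookkeeping(self):
        data, diag, means, hp = self._tiny_setup()
        rec = hls.run_search(
            1, 3, hls.SearchSpace(filters_max=8), sampler="random", seed=7,
            data=data, diagnostic_images=diag, human_means=means, input_size=16, base_hp=hp,
        )
        before = {t.index: t.objective for t in rec.alive}
        rec.trials.append(hls.Trial(99, {}, None, float("nan"), dead=True))
        after = {t.index: t.objective for t in rec.alive}
        assert before == after
        for t in rec.trials:
            if t.dead:
                assert t.objective is None

    def test_record_serializes_to_jsonl(self):
        data, diag, means, hp = self._tiny_setup()
        rec = hls.run_search(
            1, 2, hls.SearchSpace(filters_max=8), sampler="random", seed=8,
            data=data, diagnostic_images=diag, human_means=means, input_size=16, base_hp=hp,
        )
        lines = rec.to_jsonl().splitlines()
        assert len(lines) == 2
        import json

        parsed = json.loads(lines[0])
        assert {"index", "params", "objective", "val_accuracy", "dead"} <= set(parsed)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            hls.run_search(1, 0, hls.SearchSpace(), data=None, diagnostic_images=None, human_means=None)
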