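"""Bayesian hyperparameter search for human-like networks.

The search trains networks of a fixed depth while varying architecture
hyperparameters (per-layer filter counts and kernel sizes, pool-free layer
positions for deep stacks) and training hyperparameters (learning rate,
momentum, L2 weight decay). The objective being *maximized* is not task
accuracy but the Pearson correlation between the trained network's
responses, P(high gloss), on the diagnostic image set and the mean
(simulated) observer response on those images.

Three samplers are provided behind one interface: an independent
tree-structured Parzen estimator (the default "Bayesian" backend), a
Gaussian-process expected-improvement sampler, and pure random sampling.
Dead networks (failed training or constant output) are recorded but
excluded from the optimization history.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .analysis_metrics import pearson_r
from .cnn_zoo import (
    ArchitectureError,
    TrainData,
    TrainRecord,
    TrainingHyperParams,
    build_architecture,
    is_dead,
    train_with_early_stopping,
)


# -- search space -----------------------------------------------------------
@dataclass(frozen=True)
class SearchSpace:
    """Per-depth hyperparameter ranges (desk-scale defaults)."""

    filters_min: int = 4
    filters_max: int = 32
    kernel_choices: tuple[int, ...] = (3, 5, 7)
    lr_min: float = 1e-4
    lr_max: float = 1e-1
    momentum_min: float = 0.0
    momentum_max: float = 0.99
    l2_min: float = 1e-6
    l2_max: float = 1e-2

    def param_defs(self, depth: int) -> list[tuple[str, str, object]]:
        """(name, kind, domain) triples; kind in {log, uniform, logint, choice}."""
        defs: list[tuple[str, str, object]] = [
            ("lr", "log", (self.lr_min, self.lr_max)),
            ("momentum", "uniform", (self.momentum_min, self.momentum_max)),
            ("l2", "log", (self.l2_min, self.l2_max)),
        ]
        for i in range(depth):
            defs.append((f"filters_{i}", "logint", (self.filters_min, self.filters_max)))
            defs.append((f"kernel_{i}", "choice", self.kernel_choices))
        if depth > 6:
            opts = tuple(tuple(sorted(c)) for c in combinations(range(depth), depth - 6))
            defs.append(("pool_free", "choice", opts))
        return defs


def _sample_param(kind: str, domain, rng: np.random.Generator):
    if kind == "log":
        lo, hi = domain
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if kind == "uniform":
        lo, hi = domain
        return float(rng.uniform(lo, hi))
    if kind == "logint":
        lo, hi = domain
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    if kind == "choice":
        return domain[int(rng.integers(len(domain)))]
    raise ValueError(kind)


class RandomSampler:
    """Independent draws from the prior; fully deterministic given the seed."""

    def propose(self, defs, history, rng):
        return {name: _sample_param(kind, dom, rng) for name, kind, dom in defs}


class TPESampler:
    """Independent tree-structured Parzen estimator.

    After ``n_startup`` random trials, each parameter's observed values are
    split into a "good" fraction (top ``gamma`` by objective) and the rest;
    1-D kernel density estimates l(x) and g(x) are fit to the two groups,
    candidates are drawn from l, and the candidate maximizing the product
    of l(x)/g(x) across parameters is proposed. Categorical parameters use
    smoothed frequency ratios.
    """

    def __init__(self, n_startup: int = 5, gamma: float = 0.25, n_candidates: int = 24):
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    @staticmethod
    def _to_internal(kind, dom, v):
        if kind in ("log", "logint"):
            return math.log(v)
        return float(v)

    @staticmethod
    def _from_internal(kind, dom, u):
        if kind == "log":
            lo, hi = dom
            return float(np.clip(math.exp(u), lo, hi))
        if kind == "logint":
            lo, hi = dom
            return int(np.clip(round(math.exp(u)), lo, hi))
        lo, hi = dom
        return float(np.clip(u, lo, hi))

    @staticmethod
    def _kde_logpdf(samples: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
        bw = max(1.06 * samples.std() * len(samples) ** -0.2, 0.05 * span, 1e-6)
        d = (x[:, None] - samples[None, :]) / bw
        return np.log(np.mean(np.exp(-0.5 * d * d), axis=1) / (bw * np.sqrt(2 * np.pi)) + 1e-300)

    def propose(self, defs, history, rng):
        scored = [(p, obj) for p, obj in history if obj is not None]
        if len(scored) < self.n_startup:
            return RandomSampler().propose(defs, history, rng)
        scored.sort(key=lambda t: t[1], reverse=True)
        n_good = max(2, int(np.ceil(self.gamma * len(scored))))
        good = [p for p, _ in scored[:n_good]]
        bad = [p for p, _ in scored[n_good:]] or good
        out = {}
        for name, kind, dom in defs:
            if kind == "choice":
                opts = list(dom)
                cg = np.array([sum(1 for p in good if p[name] == o) for o in opts], dtype=float) + 1.0
                cb = np.array([sum(1 for p in good + bad if p[name] == o) for o in opts], dtype=float) + 1.0
                score = cg / cg.sum() / (cb / cb.sum())
                probs = cg / cg.sum()
                cand_idx = rng.choice(len(opts), size=self.n_candidates, p=probs)
                best = cand_idx[int(np.argmax(score[cand_idx]))]
                out[name] = opts[int(best)]
                continue
            gv = np.array([self._to_internal(kind, dom, p[name]) for p in good])
            bv = np.array([self._to_internal(kind, dom, p[name]) for p in bad])
            if kind in ("log", "logint"):
                span = math.log(dom[1]) - math.log(dom[0])
            else:
                span = dom[1] - dom[0]
            bw = max(1.06 * gv.std() * len(gv) ** -0.2, 0.05 * span, 1e-6)
            cands = gv[rng.integers(0, len(gv), self.n_candidates)] + rng.normal(0, bw, self.n_candidates)
            ei = self._kde_logpdf(gv, cands, span) - self._kde_logpdf(bv, cands, span)
            out[name] = self._from_internal(kind, dom, float(cands[int(np.argmax(ei))]))
        return out


class GPEISampler:
    """Gaussian-process surrogate with expected-improvement acquisition."""

    def __init__(self, n_startup: int = 5, n_candidates: int = 256):
        self.n_startup = n_startup
        self.n_candidates = n_candidates

    def _encode(self, defs, params) -> np.ndarray:
        x = []
        for name, kind, dom in defs:
            v = params[name]
            if kind == "choice":
                x.append(list(dom).index(v) / max(len(dom) - 1, 1))
            elif kind in ("log", "logint"):
                lo, hi = dom
                x.append((math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo)))
            else:
                lo, hi = dom
                x.append((v - lo) / (hi - lo))
        return np.array(x)

    def propose(self, defs, history, rng):
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        scored = [(p, obj) for p, obj in history if obj is not None]
        if len(scored) < self.n_startup:
            return RandomSampler().propose(defs, history, rng)
        X = np.array([self._encode(defs, p) for p, _ in scored])
        y = np.array([obj for _, obj in scored])
        gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        cands = [RandomSampler().propose(defs, history, rng) for _ in range(self.n_candidates)]
        Xc = np.array([self._encode(defs, c) for c in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = y.max()
        z = (mu - best) / np.maximum(sd, 1e-9)
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        return cands[int(np.argmax(ei))]


SAMPLERS = {"tpe": TPESampler, "gp-ei": GPEISampler, "random": RandomSampler}


# -- objective and records --------------------------------------------------
def objective(record: TrainRecord, diagnostic_images: np.ndarray, human_means: np.ndarray) -> float | None:
    """Pearson r between model P(high gloss) and mean observer responses.

    Returns None (trial to be marked dead) if the model's responses have
    zero variance, instead of propagating NaN.
    """
    if len(diagnostic_images) != len(human_means):
        raise ValueError("diagnostic_images and human_means length mismatch")
    if record.model is None or record.dead:
        return None
    resp = record.model.predict_proba(diagnostic_images)
    if np.std(resp) < 1e-12 or np.std(human_means) < 1e-12:
        return None
    return float(pearson_r(resp, np.asarray(human_means, dtype=float)))


@dataclass
class Trial:
    index: int
    params: dict
    objective: float | None
    val_accuracy: float
    dead: bool
    record: TrainRecord | None = None

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in ("index", "params", "objective", "val_accuracy", "dead")}
        d["params"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d["params"].items()}
        return json.dumps(d)


@dataclass
class SearchRecord:
    depth: int
    budget: int
    sampler: str
    seed: int
    trials: list[Trial] = field(default_factory=list)

    @property
    def alive(self) -> list[Trial]:
        return [t for t in self.trials if not t.dead]

    def best(self) -> Trial | None:
        alive = self.alive
        return max(alive, key=lambda t: t.objective) if alive else None

    def to_jsonl(self) -> str:
        return "\n".join(t.to_json() for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depth,
                "trial": [t.index for t in self.trials],
                "objective": [t.objective for t in self.trials],
                "val_accuracy": [t.val_accuracy for t in self.trials],
                "dead": [t.dead for t in self.trials],
            }
        )


def params_to_spec(depth: int, params: dict, input_size: int):
    filters = [params[f"filters_{i}"] for i in range(depth)]
    kernels = [params[f"kernel_{i}"] for i in range(depth)]
    pool_free = set(params["pool_free"]) if depth > 6 else None
    return build_architecture(depth, filters, kernels, pool_free, input_size=input_size)


def run_search(
    depth: int,
    budget: int,
    space: SearchSpace,
    sampler: str = "tpe",
    seed: int = 0,
    *,
    data: TrainData,
    diagnostic_images: np.ndarray,
    human_means: np.ndarray,
    input_size: int = 32,
    base_hp: TrainingHyperParams | None = None,
    record: SearchRecord | None = None,
) -> SearchRecord:
    """Sequential propose -> train -> score loop.

    Resumable: pass a partial ``record`` to continue its trial sequence.
    The random sampler's proposal sequence depends only on (seed, space);
    the Bayesian samplers additionally condition on earlier objectives.
    All-dead searches return normally with a warning.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base_hp = base_hp or TrainingHyperParams(learning_rate=0.01, momentum=0.9, l2=1e-4, val_interval=50, patience=5, max_steps=600)
    defs = SearchSpace.param_defs(space, depth)
    sampler_obj = SAMPLERS[sampler]()
    rec = record or SearchRecord(depth=depth, budget=budget, sampler=sampler, seed=seed)
    while len(rec.trials) < budget:
        i = len(rec.trials)
        rng = np.random.default_rng([seed, depth, i])
        history = [(t.params, t.objective) for t in rec.trials if not t.dead]
        params = sampler_obj.propose(defs, history, rng)
        try:
            spec = params_to_spec(depth, params, input_size)
        except (ArchitectureError, ValueError):
            rec.trials.append(Trial(i, params, None, float("nan"), dead=True))
            continue
        hp = TrainingHyperParams(
            learning_rate=params["lr"],
            momentum=params["momentum"],
            l2=params["l2"],
            batch_size=base_hp.batch_size,
            val_interval=base_hp.val_interval,
            patience=base_hp.patience,
            max_steps=base_hp.max_steps,
            init_seed=int(np.random.default_rng([seed, depth, i, 99]).integers(2**31 - 1)),
        )
        trec = train_with_early_stopping(spec, hp, data)
        dead = trec.dead or is_dead(trec, diagnostic_images)
        obj = None if dead else objective(trec, diagnostic_images, human_means)
        if obj is None:
            dead = True
        rec.trials.append(Trial(i, params, obj, trec.val_accuracy, dead, record=trec))
    if not rec.alive:
        warnings.warn(f"search (depth={depth}) produced only dead trials", RuntimeWarning)
    return rec


def plan_manifest(depths: list[int], budget_per_depth: int, seed: int = 0) -> pd.DataFrame:
    """Full experiment plan: one row per (depth, trial) with a derived seed."""
    rows = []
    for d in depths:
        for t in range(budget_per_depth):
            s = int(np.random.default_rng([seed, d, t]).integers(2**31 - 1))
            rows.append((d, t, s))
    return pd.DataFrame(rows, columns=["depth", "trial_index", "seed"])
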