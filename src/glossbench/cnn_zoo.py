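"""Depth-parameterized CNN classifier family.

Architectures have ``depth`` convolutional layers (3x3..7x7 kernels,
rectified-linear activations, "same" padding). Up to six layers, every
convolution is followed by a stride-2 max-pool; deeper networks have
exactly ``depth - 6`` pool-free layers whose positions are themselves
hyperparameters, because further pooling would collapse the spatial map.
The head is a single linear unit with logistic squashing, so a model's
response to an image is P(high gloss) in [0, 1].

Training is SGD with momentum and L2 weight decay under an early-stopping
contract: validation loss is computed every ``val_interval`` steps and
training stops after ``patience`` consecutive validations without strict
improvement, returning the best-loss checkpoint. Models that diverge or
produce constant outputs are flagged "dead" and excluded from analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import _nn
from .stimulus_synth import GlossParams, HIGH_GLOSS_W, LOW_GLOSS_W, compose_image, generate_scene_components

DEAD_STD_EPS = 1e-6
ALLOWED_DEPTHS = (1, 2, 3, 4, 5, 6, 7, 8, 12)


class ArchitectureError(ValueError):
    """Spatial schedule collapses below 1x1 (or pooling is inconsistent)."""


@dataclass(frozen=True)
class ArchitectureSpec:
    depth: int
    filters: tuple[int, ...]
    kernels: tuple[int, ...]
    pool_free_positions: frozenset[int]
    input_size: int = 128
    in_channels: int = 3

    def pooled(self, layer: int) -> bool:
        return layer not in self.pool_free_positions

    def spatial_schedule(self) -> list[int]:
        """Spatial size after each conv(+pool) layer."""
        size = self.input_size
        out = []
        for i in range(self.depth):
            if self.pooled(i):
                size //= 2
            out.append(size)
        return out

    def param_count(self) -> int:
        """Closed-form parameter count (convs + biases + linear head)."""
        n = 0
        c = self.in_channels
        for f, k in zip(self.filters, self.kernels):
            n += f * c * k * k + f
            c = f
        final = self.spatial_schedule()[-1]
        n += c * final * final + 1
        return n


def build_architecture(
    depth: int,
    filters: list[int],
    kernels: list[int],
    pool_free_positions: set[int] | None = None,
    input_size: int = 128,
) -> ArchitectureSpec:
    """Validate and build an :class:`ArchitectureSpec`.

    ``pool_free_positions`` are 0-based conv-layer indices; they are only
    legal (and then mandatory, exactly ``depth - 6`` of them) for depths
    beyond six. Schedules that reach a spatial size below 1x1, or pool an
    odd spatial size, are rejected.
    """
    if not 1 <= depth <= 12:
        raise ValueError(f"depth must be in 1..12, got {depth}")
    if len(filters) != depth or len(kernels) != depth:
        raise ValueError("filters and kernels must have length = depth")
    if any(k % 2 == 0 for k in kernels):
        raise ValueError("kernels must be odd (same padding)")
    pf = frozenset(pool_free_positions or set())
    if depth <= 6:
        if pf:
            raise ValueError("pool_free_positions only apply to depth > 6")
    else:
        if len(pf) != depth - 6:
            raise ValueError(f"depth {depth} requires exactly {depth - 6} pool-free positions")
        if not all(0 <= p < depth for p in pf):
            raise ValueError("pool_free_positions out of range")
    spec = ArchitectureSpec(depth, tuple(filters), tuple(kernels), pf, input_size)
    size = input_size
    for i in range(depth):
        if spec.pooled(i):
            if size % 2 != 0:
                raise ArchitectureError(f"layer {i}: cannot pool odd size {size}")
            size //= 2
        if size < 1:
            raise ArchitectureError(f"spatial size collapsed at layer {i}")
    return spec


def default_pool_free(depth: int) -> set[int] | None:
    """Place any pool-free layers at the end of the stack."""
    return set(range(6, depth)) if depth > 6 else None


@dataclass(frozen=True)
class TrainingHyperParams:
    learning_rate: float
    momentum: float
    l2: float
    batch_size: int = 32
    val_interval: int = 100
    patience: int = 5
    max_steps: int = 2000
    init_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "val_interval", "patience", "max_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.momentum < 0 or self.l2 < 0:
            raise ValueError("momentum and l2 must be >= 0")
        if self.val_interval * self.patience > self.max_steps:
            raise ValueError("val_interval * patience must not exceed max_steps")


@dataclass
class TrainRecord:
    spec: ArchitectureSpec | None
    hyperparams: TrainingHyperParams
    history: list[tuple[int, float, float]]  # (step, val_loss, val_accuracy)
    stop_step: int
    val_loss: float
    val_accuracy: float
    dead: bool
    model: object | None = None
    artifact_path: str | None = None


@dataclass
class TrainData:
    """In-memory supervised split: NCHW images and {0,1} labels."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray


def images_from_manifest(manifest: pd.DataFrame, size: int = 32) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regenerate and compose every manifest image; returns (X, y, image_ids)."""
    X, y, ids = [], [], []
    cache: dict[int, object] = {}
    for _, row in manifest.iterrows():
        s = int(row["seed"])
        if s not in cache:
            cache[s] = generate_scene_components(s, size=size)
        c = cache[s]
        w = HIGH_GLOSS_W if row["material"] == "high" else LOW_GLOSS_W
        X.append(compose_image(c, GlossParams(w)).transpose(2, 0, 1))
        y.append(1.0 if row["material"] == "high" else 0.0)
        ids.append(row["image_id"])
    return np.array(X, dtype=np.float32), np.array(y, dtype=np.float32), np.array(ids)


def train_data_from_split(manifest: pd.DataFrame, size: int = 32) -> TrainData:
    tr = manifest[manifest["split"] == "train"]
    va = manifest[manifest["split"] == "validation"]
    if tr.empty or va.empty:
        raise ValueError("manifest needs nonempty train and validation splits")
    Xtr, ytr, _ = images_from_manifest(tr, size)
    Xva, yva, _ = images_from_manifest(va, size)
    return TrainData(Xtr, ytr, Xva, yva)


class GlossCNN:
    """A concrete network instantiated from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, init_seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(init_seed)
        self.layers: list[tuple[object, object, object | None]] = []
        c = spec.in_channels
        for i in range(spec.depth):
            conv = _nn.Conv2D(c, spec.filters[i], spec.kernels[i], rng)
            pool = _nn.MaxPool2() if spec.pooled(i) else None
            self.layers.append((conv, _nn.ReLU(), pool))
            c = spec.filters[i]
        final = spec.spatial_schedule()[-1]
        self.head = _nn.Dense(c * final * final, 1, rng)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        h = X
        for conv, relu, pool in self.layers:
            h = conv.forward(h)
            h = relu.forward(h)
            if pool is not None:
                h = pool.forward(h)
        self._feat_shape = h.shape
        return self.head.forward(h.reshape(h.shape[0], -1))

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits).reshape(self._feat_shape)
        for conv, relu, pool in reversed(self.layers):
            if pool is not None:
                dh = pool.backward(dh)
            dh = relu.backward(dh)
            dh = conv.backward(dh)

    def sgd_step(self, hp: TrainingHyperParams) -> None:
        for conv, _, _ in self.layers:
            _nn.sgd_update(conv, hp.learning_rate, hp.momentum, hp.l2)
        _nn.sgd_update(self.head, hp.learning_rate, hp.momentum, hp.l2)

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch):
            out.append(_nn.sigmoid(self.forward_logits(X[i : i + batch]).ravel()))
        return np.concatenate(out)

    def features(self, X: np.ndarray, layer_index: int) -> np.ndarray:
        """Post-activation (after ReLU and any pool) features of one layer."""
        if not 0 <= layer_index < self.spec.depth:
            raise ValueError(f"invalid layer_index {layer_index}")
        h = X
        for i, (conv, relu, pool) in enumerate(self.layers):
            h = relu.forward(conv.forward(h))
            if pool is not None:
                h = pool.forward(h)
            if i == layer_index:
                return h.reshape(h.shape[0], -1)
        raise AssertionError

    # -- weight snapshots ---------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        ws = []
        for conv, _, _ in self.layers:
            ws += [conv.W.copy(), conv.b.copy()]
        ws += [self.head.W.copy(), self.head.b.copy()]
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        it = iter(ws)
        for conv, _, _ in self.layers:
            conv.W, conv.b = next(it).copy(), next(it).copy()
        self.head.W, self.head.b = next(it).copy(), next(it).copy()

    def param_count_actual(self) -> int:
        return int(sum(w.size for w in self.get_weights()))


def _early_stopping_loop(
    step_fn: Callable[[int], float],
    validate_fn: Callable[[], tuple[float, float]],
    snapshot_fn: Callable[[], object],
    hp: TrainingHyperParams,
) -> tuple[list[tuple[int, float, float]], int, bool, object | None]:
    """Shared early-stopping driver.

    Runs ``step_fn`` per training step; every ``val_interval`` steps calls
    ``validate_fn`` -> (loss, acc). "Improvement" means strictly lower loss
    than the best so far; after ``patience`` consecutive non-improvements
    (or ``max_steps``) the loop ends. Non-finite losses abort with
    ``dead=True``. Returns (history, stop_step, dead, best_snapshot).
    """
    history: list[tuple[int, float, float]] = []
    best_loss = np.inf
    best_snap: object | None = None
    streak = 0
    step = 0
    dead = False
    while step < hp.max_steps:
        loss = step_fn(step)
        step += 1
        if not np.isfinite(loss):
            dead = True
            break
        if step % hp.val_interval == 0:
            vloss, vacc = validate_fn()
            history.append((step, vloss, vacc))
            if not np.isfinite(vloss):
                dead = True
                break
            if vloss < best_loss:
                best_loss = vloss
                best_snap = snapshot_fn()
                streak = 0
            else:
                streak += 1
                if streak >= hp.patience:
                    break
    return history, step, dead, best_snap


def _val_metrics(logits: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    loss, _ = _nn.bce_with_logits(logits, y)
    acc = float(((logits.ravel() > 0) == (y > 0.5)).mean())
    return loss, acc


def train_with_early_stopping(spec: ArchitectureSpec, hp: TrainingHyperParams, data: TrainData) -> TrainRecord:
    """Train a fresh network from random init under the early-stopping contract."""
    model = GlossCNN(spec, init_seed=hp.init_seed)
    rng = np.random.default_rng([hp.init_seed, 1])
    n = len(data.X_train)

    def step_fn(step: int) -> float:
        idx = rng.integers(0, n, size=min(hp.batch_size, n))
        logits = model.forward_logits(data.X_train[idx])
        loss, dlogits = _nn.bce_with_logits(logits, data.y_train[idx])
        model.backward(dlogits)
        model.sgd_step(hp)
        return loss

    def validate_fn() -> tuple[float, float]:
        logits = []
        for i in range(0, len(data.X_val), 256):
            logits.append(model.forward_logits(data.X_val[i : i + 256]))
        return _val_metrics(np.vstack(logits), data.y_val)

    history, stop_step, dead, best = _early_stopping_loop(step_fn, validate_fn, model.get_weights, hp)
    if best is not None:
        model.set_weights(best)
    if not history:
        dead = True
    best_idx = int(np.argmin([h[1] for h in history])) if history else -1
    vloss, vacc = (history[best_idx][1], history[best_idx][2]) if history else (np.nan, np.nan)
    return TrainRecord(spec, hp, history, stop_step, vloss, vacc, dead, model=model)


class ToyBackbone:
    """Small fixed-seed random CNN used as a frozen feature extractor.

    Stands in for a large pretrained trunk in readout experiments; random
    convolutional features are frozen and only the linear head is trained.
    """

    def __init__(self, input_size: int = 32, depth: int = 3, filters: int = 8, seed: int = 1234):
        spec = build_architecture(depth, [filters] * depth, [3] * depth, input_size=input_size)
        self.net = GlossCNN(spec, init_seed=seed)
        self.depth = depth
        self._frozen = [w.copy() for w in self.net.get_weights()]

    def features(self, X: np.ndarray, layer_index: int, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch):
            out.append(self.net.features(X[i : i + batch], layer_index))
        return np.vstack(out)

    def trunk_unchanged(self) -> bool:
        return all(np.array_equal(a, b) for a, b in zip(self._frozen, self.net.get_weights()))


class IdentityBackbone:
    """Features = flattened input pixels (layer 0 only); for contract tests."""

    depth = 1

    def features(self, X: np.ndarray, layer_index: int) -> np.ndarray:
        if layer_index != 0:
            raise ValueError("identity backbone has a single layer")
        return X.reshape(len(X), -1)


def readout_train(backbone, layer_index: int, hp: TrainingHyperParams, data: TrainData) -> TrainRecord:
    """Train only a linear readout head on frozen backbone features."""
    if not 0 <= layer_index < backbone.depth:
        raise ValueError(f"invalid layer_index {layer_index}")
    Ftr = backbone.features(data.X_train, layer_index)
    Fva = backbone.features(data.X_val, layer_index)
    rng = np.random.default_rng([hp.init_seed, 2])
    head = _nn.Dense(Ftr.shape[1], 1, np.random.default_rng(hp.init_seed))
    n = len(Ftr)

    def step_fn(step: int) -> float:
        idx = rng.integers(0, n, size=min(hp.batch_size, n))
        logits = head.forward(Ftr[idx])
        loss, dlogits = _nn.bce_with_logits(logits, data.y_train[idx])
        head.backward(dlogits)
        _nn.sgd_update(head, hp.learning_rate, hp.momentum, hp.l2)
        return loss

    def validate_fn() -> tuple[float, float]:
        return _val_metrics(head.forward(Fva), data.y_val)

    def snapshot() -> list[np.ndarray]:
        return [head.W.copy(), head.b.copy()]

    history, stop_step, dead, best = _early_stopping_loop(step_fn, validate_fn, snapshot, hp)
    if best is not None:
        head.W, head.b = best[0], best[1]
    if not history:
        dead = True

    class _ReadoutModel:
        def __init__(self, backbone, layer_index, head):
            self.backbone, self.layer_index, self.head = backbone, layer_index, head

        def predict_proba(self, X: np.ndarray) -> np.ndarray:
            F = self.backbone.features(X, self.layer_index)
            return _nn.sigmoid(self.head.forward(F).ravel())

    best_idx = int(np.argmin([h[1] for h in history])) if history else -1
    vloss, vacc = (history[best_idx][1], history[best_idx][2]) if history else (np.nan, np.nan)
    return TrainRecord(None, hp, history, stop_step, vloss, vacc, dead, model=_ReadoutModel(backbone, layer_index, head))


def is_dead(record: TrainRecord, probe_images: np.ndarray, eps: float = DEAD_STD_EPS) -> bool:
    """Dead = failed training OR (numerically) constant responses on probes."""
    if len(probe_images) == 0:
        raise ValueError("probe_images must be nonempty")
    if record.dead or record.model is None:
        return True
    out = record.model.predict_proba(probe_images)
    return bool(np.std(out) < eps or not np.all(np.isfinite(out)))
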