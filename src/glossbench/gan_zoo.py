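"""DCGAN architecture family derived from four scaling principles.

Starting from a reference deep convolutional GAN that generates 128x128
images with a five-layer generator, shallower family members (depths 1..5)
are derived by: (1) resolution doubles per generator (deconvolutional)
layer and halves per discriminator layer; (2) filter counts halve for
later generator layers and double for later discriminator layers; (3) a
depth-d generator starts deconvolution at 128 / 2^d pixels (4x4 for depth
5, 8x8 for depth 4, ...); (4) the latent input is 100x1 at every depth.

Each depth is trained twice — once on high-gloss and once on low-gloss
renderings — so generated images carry class labels by construction. The
training loop is a standard adversarial alternation at deliberately small
scale; it emits loss histories and a mode-collapse warning, with no
convergence guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn

LATENT_DIM = 100


@dataclass(frozen=True)
class DcganFamilySpec:
    depth: int
    base_filters: int = 32
    image_size: int = 128
    latent_dim: int = LATENT_DIM

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 5:
            raise ValueError(f"depth must be in 1..5, got {self.depth}")
        if self.image_size % (2**self.depth) != 0:
            raise ValueError("image_size must be divisible by 2^depth")

    @property
    def start_resolution(self) -> int:
        return self.image_size // (2**self.depth)

    def generator_filters(self) -> list[int]:
        """Channel count after the projection and each deconv layer.

        The projection outputs base_filters * 2^(depth-1) channels; each
        later layer halves the count; the final layer emits RGB.
        """
        chans = [self.base_filters * 2 ** (self.depth - 2 - i) for i in range(self.depth - 1)]
        return [self.base_filters * 2 ** (self.depth - 1)] + chans + [3]

    def discriminator_filters(self) -> list[int]:
        """Channel count after each strided conv layer (doubling)."""
        return [self.base_filters * 2**i for i in range(self.depth)]

    def generator_resolutions(self) -> list[int]:
        """Spatial size at the projection and after each deconv layer."""
        return [self.start_resolution * 2**i for i in range(self.depth + 1)]

    def discriminator_resolutions(self) -> list[int]:
        """Spatial size at the input and after each conv layer."""
        return [self.image_size // 2**i for i in range(self.depth + 1)]


def build_dcgan(depth: int, base_filters: int = 32, image_size: int = 128) -> DcganFamilySpec:
    """Validated family spec; generator output is ``image_size`` for all depths."""
    spec = DcganFamilySpec(depth=depth, base_filters=base_filters, image_size=image_size)
    res = spec.generator_resolutions()
    assert res[-1] == image_size and res[0] == spec.start_resolution
    return spec


class DcganGenerator:
    """latent 100x1 -> dense projection -> ``depth`` deconvolutional layers."""

    def __init__(self, spec: DcganFamilySpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        fs = spec.generator_filters()
        s0 = spec.start_resolution
        self.proj = _nn.Dense(spec.latent_dim, fs[0] * s0 * s0, rng)
        self.deconvs = []
        for i in range(spec.depth):
            self.deconvs.append((_nn.ConvTranspose2D(fs[i], fs[i + 1], 5, rng), _nn.ReLU() if i < spec.depth - 1 else None))

    def forward(self, z: np.ndarray) -> np.ndarray:
        s0 = self.spec.start_resolution
        h = _nn.ReLU().forward(self.proj.forward(z))
        self._proj_act = h
        h = h.reshape(len(z), -1, s0, s0)
        for deconv, act in self.deconvs:
            h = deconv.forward(h)
            if act is not None:
                h = act.forward(h)
        self._logits_shape = h.shape
        return _nn.sigmoid(h)

    def backward_and_step(self, dimg: np.ndarray, out: np.ndarray, lr: float, momentum: float) -> None:
        # d/dlogits of sigmoid output
        dh = dimg * out * (1.0 - out)
        for deconv, act in reversed(self.deconvs):
            if act is not None:
                dh = act.backward(dh)
            dh = deconv.backward(dh)
        dflat = dh.reshape(len(dh), -1)
        dflat = dflat * (self._proj_act > 0)
        self.proj.backward(dflat)
        for deconv, _ in self.deconvs:
            _nn.sgd_update(deconv, lr, momentum, 0.0)
        _nn.sgd_update(self.proj, lr, momentum, 0.0)

    def weights(self) -> list[np.ndarray]:
        ws = [self.proj.W.copy(), self.proj.b.copy()]
        for deconv, _ in self.deconvs:
            ws += [deconv.conv.W.copy(), deconv.conv.b.copy()]
        return ws

    def param_count(self) -> int:
        return int(sum(w.size for w in self.weights()))


class DcganDiscriminator:
    """Mirrored stack: strided convolutions halving resolution -> real/fake."""

    def __init__(self, spec: DcganFamilySpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        fs = spec.discriminator_filters()
        self.convs = []
        c = 3
        for f in fs:
            self.convs.append((_nn.Conv2D(c, f, 4, rng, stride=2, pad=1), _nn.LeakyReLU(0.2)))
            c = f
        s = spec.start_resolution
        self.head = _nn.Dense(c * s * s, 1, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act in self.convs:
            h = act.forward(conv.forward(h))
        self._feat_shape = h.shape
        return self.head.forward(h.reshape(len(x), -1))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits).reshape(self._feat_shape)
        for conv, act in reversed(self.convs):
            dh = conv.backward(act.backward(dh))
        return dh

    def step(self, lr: float, momentum: float) -> None:
        for conv, _ in self.convs:
            _nn.sgd_update(conv, lr, momentum, 0.0)
        _nn.sgd_update(self.head, lr, momentum, 0.0)

    def param_count(self) -> int:
        n = sum(conv.W.size + conv.b.size for conv, _ in self.convs)
        return int(n + self.head.W.size + self.head.b.size)


@dataclass
class DcganTrainResult:
    generator: DcganGenerator
    discriminator: DcganDiscriminator
    d_losses: list[float] = field(default_factory=list)
    g_losses: list[float] = field(default_factory=list)
    collapsed: bool = False


def train_dcgan(
    spec: DcganFamilySpec,
    images: np.ndarray,
    steps: int,
    seed: int = 0,
    lr: float = 2e-3,
    momentum: float = 0.5,
    batch_size: int = 8,
    collapse_eps: float = 1e-4,
) -> DcganTrainResult:
    """Adversarial training at desk scale on one material class.

    ``images`` is NCHW in [0,1], all of one material label. With
    ``steps=0`` the returned networks equal their seeded initialization.
    Emits a mode-collapse warning when generated-sample variance drops
    below ``collapse_eps``; never raises for it.
    """
    gen = DcganGenerator(spec, seed=seed)
    disc = DcganDiscriminator(spec, seed=seed + 1)
    rng = np.random.default_rng([seed, 3])
    res = DcganTrainResult(gen, disc)
    images = np.asarray(images, dtype=np.float32)
    n = len(images)
    for _ in range(steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        real = images[idx]
        z = rng.standard_normal((len(real), spec.latent_dim)).astype(np.float32)
        fake = gen.forward(z)
        # discriminator: real -> 1, fake -> 0
        logits_r = disc.forward(real)
        loss_r, dr = _nn.bce_with_logits(logits_r, np.ones(len(real)))
        disc.backward(dr)
        disc.step(lr, momentum)
        logits_f = disc.forward(fake)
        loss_f, df = _nn.bce_with_logits(logits_f, np.zeros(len(fake)))
        disc.backward(df)
        disc.step(lr, momentum)
        res.d_losses.append(loss_r + loss_f)
        # generator: non-saturating, push D(fake) -> 1
        z = rng.standard_normal((len(real), spec.latent_dim)).astype(np.float32)
        fake = gen.forward(z)
        logits_f = disc.forward(fake)
        g_loss, dg = _nn.bce_with_logits(logits_f, np.ones(len(fake)))
        dimg = disc.backward(dg)
        gen.backward_and_step(dimg, fake, lr, momentum)
        res.g_losses.append(g_loss)
    sample = sample_images(gen, n=8, seed=seed + 17)
    if float(sample.var()) < collapse_eps:
        res.collapsed = True
        warnings.warn("generator output variance below collapse threshold", RuntimeWarning)
    return res


def sample_images(generator: DcganGenerator, n: int, seed: int = 0, batch: int = 16) -> np.ndarray:
    """n generated images (N, H, W, 3) in [0,1], deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(0, n, batch):
        z = rng.standard_normal((min(batch, n - i), generator.spec.latent_dim)).astype(np.float32)
        out.append(generator.forward(z).transpose(0, 2, 3, 1))
    return np.concatenate(out)


def experiment_manifest(depths=(1, 2, 3, 4, 5), n_per_gan: int = 75) -> pd.DataFrame:
    """Triangle-rating stimulus bookkeeping: generated images + renderings.

    5 depths x 2 material classes x ``n_per_gan`` generated images, plus
    ``n_per_gan`` renderings per class (source "render"), balanced labels.
    """
    rows = []
    for d in depths:
        for material in ("high", "low"):
            for i in range(n_per_gan):
                rows.append((f"dcgan_d{d}_{material}_{i:03d}", "dcgan", d, material))
    for material in ("high", "low"):
        for i in range(n_per_gan):
            rows.append((f"render_{material}_{i:03d}", "render", None, material))
    return pd.DataFrame(rows, columns=["image_id", "source", "depth", "material"])
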