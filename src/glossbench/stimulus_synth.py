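"""Procedural gloss stimulus generation.

Each scene is a stack of five aligned component images — specular ``S``,
diffuse ``D``, multiplicative texture ``T``, object mask ``alpha`` and
background ``B`` — that are mixed into a single rendering by a linear
specular weight ``w``:

    I = S * w + D * T * (1 - w) + (1 - alpha) * B

The corpus pairs every scene at two weights, w = 0.98 (high gloss) and
w = 0.02 (low gloss), so the two material classes differ only in the
specular mixing coefficient. Scenes whose object covers less than 20% or
more than 90% of the frame are discarded and re-drawn.

The component generator is a procedural stand-in for physically based
renders: alpha is a thresholded low-pass noise blob, the diffuse component
is a smooth shading gradient, the specular component is a sparse
high-contrast warped-noise field, and the texture is a mid-frequency
marbled pattern. All randomness flows through one integer seed per scene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

HIGH_GLOSS_W = 0.98
LOW_GLOSS_W = 0.02
COVERAGE_LO = 0.20
COVERAGE_HI = 0.90
# fraction of scenes given a materially ambiguous appearance (soft
# reflections, or sharp bright texture marks); keeps observers imperfect
# and lets the diagnostic-set construction find genuinely confusable images
AMBIGUOUS_SCENE_RATE = 0.15

MANIFEST_COLUMNS = ["image_id", "scene_id", "material", "split", "seed"]


@dataclass(frozen=True)
class GlossParams:
    """Linear specular mixing weight; 0.98 / 0.02 are the corpus classes."""

    specular_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.specular_weight <= 1.0:
            raise ValueError(f"specular_weight must be in [0,1], got {self.specular_weight}")


@dataclass
class SceneComponents:
    """The five aligned component images of one scene view.

    specular/diffuse are linear-intensity, >= 0 and zero off the object;
    texture, alpha and background live in [0, 1].
    """

    scene_id: str
    specular: np.ndarray  # H x W x 3
    diffuse: np.ndarray  # H x W x 3
    texture: np.ndarray  # H x W x 3
    alpha: np.ndarray  # H x W x 1
    background: np.ndarray  # H x W x 3

    def validate(self) -> None:
        shapes = {a.shape[:2] for a in (self.specular, self.diffuse, self.texture, self.alpha, self.background)}
        if len(shapes) != 1:
            raise ValueError(f"component shapes disagree: {shapes}")
        if self.alpha.ndim != 3 or self.alpha.shape[2] != 1:
            raise ValueError("alpha must be H x W x 1")
        if self.alpha.min() < 0 or self.alpha.max() > 1:
            raise ValueError("alpha must lie in [0,1]")
        off = self.alpha[..., 0] == 0
        if not (np.all(self.specular[off] == 0) and np.all(self.diffuse[off] == 0)):
            raise ValueError("specular/diffuse must vanish where alpha is zero")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo + 1e-12)


def generate_scene_components(seed: int, size: int = 128) -> SceneComponents:
    """Generate one procedural component stack, deterministic in ``seed``.

    Raises
    ------
    ValueError
        If ``size`` < 16.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng(seed)

    # Object mask: threshold a low-pass blob at a random quantile so the
    # coverage distribution spans beyond both filter boundaries.
    blob = _smooth_noise(rng, size, sigma=size / 8)
    target_cov = rng.uniform(0.08, 0.97)
    thr = np.quantile(blob, 1.0 - target_cov)
    hard = (blob > thr).astype(float)
    alpha = ndimage.gaussian_filter(hard, size / 80.0)
    alpha = np.clip((alpha - 0.25) / 0.5, 0.0, 1.0)[..., None]

    mask = alpha[..., 0] > 0

    # Diffuse: a smooth directional shading gradient with gentle mottle.
    yy, xx = np.mgrid[0:size, 0:size] / size
    ang = rng.uniform(0, 2 * np.pi)
    shade = 0.35 + 0.45 * (np.cos(ang) * xx + np.sin(ang) * yy) + 0.25 * _smooth_noise(rng, size, size / 6)
    shade = np.clip(shade, 0.05, 1.2)
    tint = rng.uniform(0.6, 1.0, size=3)
    diffuse = shade[..., None] * tint[None, None, :]
    diffuse *= alpha

    # Specular: sparse, high-contrast warped highlights. Warp a fine noise
    # field, keep the bright tail, and sharpen contrast.
    fine = _smooth_noise(rng, size, sigma=max(1.0, size / 48))
    dx = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 10, mode="wrap") * (size / 24)
    dy = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 10, mode="wrap") * (size / 24)
    coords = np.mgrid[0:size, 0:size].astype(float)
    warped = ndimage.map_coordinates(fine, [coords[0] + dy, coords[1] + dx], order=1, mode="wrap")
    q = np.quantile(warped, 0.88)
    spec = np.clip((warped - q) / (1.0 - q + 1e-9), 0.0, 1.0) ** 1.5
    spec = spec * rng.uniform(1.2, 2.0)
    # heavy-tailed ambiguity: a minority of scenes have softened,
    # lower-frequency reflections (a glossy object under diffuse
    # illumination) with graded severity, so they read as anywhere from
    # slightly to fully matte
    r = rng.uniform()
    if r > 1.0 - AMBIGUOUS_SCENE_RATE:
        severity = (r - (1.0 - AMBIGUOUS_SCENE_RATE)) / AMBIGUOUS_SCENE_RATE
        spec = ndimage.gaussian_filter(spec, severity * size / 32)
    specular = np.repeat(spec[..., None], 3, axis=2) * rng.uniform(0.85, 1.0, size=3)[None, None, :]
    specular *= alpha

    # Texture: marbled mid-frequency pattern in [0,1] (keeps low-gloss
    # images from being separable by mean brightness alone).
    marble_base = _smooth_noise(rng, size, sigma=size / 16)
    marble = 0.5 + 0.5 * np.sin(2 * np.pi * (3 * marble_base + 0.3 * fine))
    texture = 0.25 + 0.75 * marble
    # the ambiguity counterpart: a minority of scenes get a dark varnished
    # look — the textured base fades while sparse bright glint marks
    # appear — so the matte material reads as anywhere up to fully glossy
    r2 = rng.uniform()
    if r2 > 1.0 - AMBIGUOUS_SCENE_RATE:
        severity2 = 0.7 + 0.3 * (r2 - (1.0 - AMBIGUOUS_SCENE_RATE)) / AMBIGUOUS_SCENE_RATE
        fine2 = _smooth_noise(rng, size, sigma=max(1.0, size / 48))
        q2 = np.quantile(fine2, 0.75)
        spots = np.clip((fine2 - q2) / (1.0 - q2 + 1e-9), 0.0, 1.0) ** 1.5
        texture = np.maximum(texture * (1.0 - 0.985 * severity2), np.clip(6.0 * severity2 * spots, 0.0, 1.0))
    texture = np.repeat(texture[..., None], 3, axis=2)

    # Background: low-contrast large-scale field.
    bg = 0.35 + 0.3 * _smooth_noise(rng, size, sigma=size / 5)
    background = np.repeat(bg[..., None], 3, axis=2) * rng.uniform(0.8, 1.0, size=3)[None, None, :]

    comps = SceneComponents(
        scene_id=f"scene{seed:08d}",
        specular=specular.astype(np.float64),
        diffuse=diffuse.astype(np.float64),
        texture=texture.astype(np.float64),
        alpha=alpha.astype(np.float64),
        background=np.clip(background, 0, 1).astype(np.float64),
    )
    if not mask.any():
        # Degenerate blob; alpha=0 everywhere still satisfies invariants and
        # is rejected later by the coverage filter.
        pass
    comps.validate()
    return comps


def compose_image(c: SceneComponents, g: GlossParams) -> np.ndarray:
    """Mix components: ``I = S*w + D*T*(1-w) + (1-alpha)*B`` in linear float.

    No clipping is applied; values above 1 are tone-mapped only at export.
    """
    w = g.specular_weight
    shapes = {a.shape[:2] for a in (c.specular, c.diffuse, c.texture, c.alpha, c.background)}
    if len(shapes) != 1:
        raise ValueError("component shape mismatch")
    return c.specular * w + c.diffuse * c.texture * (1.0 - w) + (1.0 - c.alpha) * c.background


def coverage(alpha: np.ndarray) -> float:
    """Fraction of pixels belonging to the object (alpha > 0.5)."""
    a = alpha[..., 0] if alpha.ndim == 3 else alpha
    return float(np.mean(a > 0.5))


def coverage_filter(alpha: np.ndarray) -> bool:
    """Keep scenes whose object covers between 20% and 90% of the frame.

    Boundary values are kept; the discard rule is strictly "less than 20%"
    or "more than 90%".
    """
    cov = coverage(alpha)
    return COVERAGE_LO <= cov <= COVERAGE_HI


def to_png_u8(img: np.ndarray, gamma: float = 2.2) -> np.ndarray:
    """Linear float -> display 8-bit with gamma encoding; clips at export only."""
    enc = np.clip(img, 0.0, 1.0) ** (1.0 / gamma)
    return (enc * 255.0 + 0.5).astype(np.uint8)


def _component_seed(seed: int, draw: int) -> int:
    return int(np.random.default_rng([seed, draw]).integers(0, 2**31 - 1))


def build_corpus(
    n_scenes: int,
    seed: int,
    size: int = 128,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate scenes until ``n_scenes`` pass the coverage filter.

    Every retained scene contributes exactly two manifest rows sharing its
    components: a high-gloss image (w=0.98) and a low-gloss image (w=0.02).
    Rejected draws are re-drawn, so the returned manifest always has
    ``2 * n_scenes`` balanced rows. If ``out_dir`` is given, composed images
    are written as gamma-encoded PNGs alongside the manifest CSV.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    rows = []
    kept = 0
    draw = 0
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    while kept < n_scenes:
        comp_seed = _component_seed(seed, draw)
        draw += 1
        c = generate_scene_components(comp_seed, size=size)
        if not coverage_filter(c.alpha):
            continue
        kept += 1
        for material, w in (("high", HIGH_GLOSS_W), ("low", LOW_GLOSS_W)):
            image_id = f"{c.scene_id}_{material}"
            rows.append((image_id, c.scene_id, material, "train", comp_seed))
            if out is not None:
                img = compose_image(c, GlossParams(w))
                iio.imwrite(out / f"{image_id}.png", to_png_u8(img))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# linear intensities (specular/diffuse can exceed 1) are stored in 16-bit
# PNGs scaled by this factor; texture/alpha/background are stored directly
HDR_PNG_SCALE = 4.0


def save_components(c: SceneComponents, out_dir: str | Path) -> Path:
    """Write one scene's component stack as 16-bit linear PNGs.

    RGB components are stored one 16-bit grayscale PNG per channel
    (``specular.r.png`` etc.), since 16-bit RGB PNG encoding is not
    universally supported.
    """
    d = Path(out_dir) / c.scene_id
    d.mkdir(parents=True, exist_ok=True)

    def u16(x: np.ndarray, scale: float = 1.0) -> np.ndarray:
        return (np.clip(x / scale, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)

    for name, arr, scale in (
        ("specular", c.specular, HDR_PNG_SCALE),
        ("diffuse", c.diffuse, HDR_PNG_SCALE),
        ("texture", c.texture, 1.0),
        ("background", c.background, 1.0),
    ):
        for ch, tag in enumerate("rgb"):
            iio.imwrite(d / f"{name}.{tag}.png", u16(arr[..., ch], scale))
    iio.imwrite(d / "alpha.png", u16(c.alpha[..., 0]))
    return d


def load_components(scene_dir: str | Path) -> SceneComponents:
    """Read a component stack written by :func:`save_components` (or any
    user-supplied stack in the same layout)."""
    d = Path(scene_dir)

    def rgb(name: str, scale: float = 1.0) -> np.ndarray:
        chans = [iio.imread(d / f"{name}.{tag}.png").astype(np.float64) / 65535.0 * scale for tag in "rgb"]
        return np.stack(chans, axis=2)

    alpha = (iio.imread(d / "alpha.png").astype(np.float64) / 65535.0)[..., None]
    return SceneComponents(
        scene_id=d.name,
        specular=rgb("specular", HDR_PNG_SCALE),
        diffuse=rgb("diffuse", HDR_PNG_SCALE),
        texture=rgb("texture"),
        alpha=alpha,
        background=rgb("background"),
    )


def manifest_bookkeeping_counts(n_scenes: int) -> dict[str, int]:
    """Closed-form corpus arithmetic: rows and per-material counts."""
    return {"rows": 2 * n_scenes, "per_material": n_scenes}


def plan_corpus_manifest(n_scenes: int, seed: int) -> pd.DataFrame:
    """Bookkeeping-only manifest with the same shape as a rendered corpus.

    Emits the ``2 * n_scenes`` balanced rows of :func:`build_corpus` without
    generating any pixels, so full-scale corpus arithmetic (e.g. 74,961
    scenes -> 149,922 rows) runs in seconds. Scene seeds are the raw draw
    seeds; a rendered corpus additionally re-draws scenes that fail the
    coverage filter, which changes which seeds are kept but never the counts
    or balance.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    draws = np.arange(n_scenes)
    seeds = np.array([_component_seed(seed, int(d)) for d in draws])
    rows = []
    for s in seeds:
        sid = f"scene{s:08d}"
        rows.append((f"{sid}_high", sid, "high", "train", s))
        rows.append((f"{sid}_low", sid, "low", "train", s))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def components_for_row(row: pd.Series | dict, size: int = 128) -> SceneComponents:
    """Regenerate the component stack for a manifest row from its seed."""
    return generate_scene_components(int(row["seed"]), size=size)


def split_corpus(
    manifest: pd.DataFrame,
    withheld_scenes: set[str],
    val_frac: float,
    seed: int,
) -> pd.DataFrame:
    """Mark withheld scenes and carve a balanced validation split.

    Both images of a withheld scene are marked ``withheld``. Of the
    remaining pool, per material class ``floor(val_frac * pool_per_class)``
    images are sampled without replacement as ``validation``; the rest stay
    ``train``. This floor-per-class rule reproduces the bookkeeping
    149,922 -> 148,922 -> 134,030 train / 14,892 validation.
    """
    if not 0.0 <= val_frac < 1.0:
        raise ValueError(f"val_frac must be in [0,1), got {val_frac}")
    known = set(manifest["scene_id"])
    extra = set(withheld_scenes) - known
    if extra:
        raise ValueError(f"unknown withheld scenes: {sorted(extra)[:5]}")
    out = manifest.copy()
    out["split"] = "train"
    out.loc[out["scene_id"].isin(withheld_scenes), "split"] = "withheld"
    rng = np.random.default_rng(seed)
    for material in ("high", "low"):
        pool = out.index[(out["split"] == "train") & (out["material"] == material)].to_numpy()
        n_val = int(np.floor(val_frac * len(pool)))
        chosen = rng.choice(pool, size=n_val, replace=False)
        out.loc[chosen, "split"] = "validation"
    return out
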