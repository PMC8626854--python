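"""Specular-highlight manipulation probes.

Three manipulations of the specular component test what a trained
classifier has learned about highlights:

* **contrast** — recompose the scene at specular weights
  {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0};
* **size** — grayscale erosion / dilation of the specular component with a
  disk structuring element (radii 2..5 px) before composition;
* **orientation** — rotate the specular component about the image center
  (±10°..±90° in 10° steps); because rotation moves reflections off the
  object, each rotated image is paired with a coverage-matched *control*
  whose reflections keep the correct orientation but are cut to the same
  overlap mask, so response differences isolate orientation per se.

Size and orientation probes use an intermediate base specular weight of
0.1 so responses have headroom in both directions. Effect sizes are the
response contrasts between extreme conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, erosion, dilation

from .stimulus_synth import GlossParams, SceneComponents, compose_image, coverage_filter, generate_scene_components, _component_seed

CONTRAST_LEVELS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
MORPH_RADII = (2, 3, 4, 5)
ROTATION_ANGLES = tuple(a for mag in range(10, 100, 10) for a in (mag, -mag))
BASE_PROBE_W = 0.1
SUPPORT_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ProbeCondition:
    kind: str  # contrast | erode | dilate | rotate
    parameter: float

    def __post_init__(self) -> None:
        if self.kind == "contrast":
            if self.parameter not in CONTRAST_LEVELS:
                raise ValueError(f"contrast level {self.parameter} not in {CONTRAST_LEVELS}")
        elif self.kind in ("erode", "dilate"):
            if int(self.parameter) not in MORPH_RADII:
                raise ValueError(f"radius {self.parameter} not in {MORPH_RADII}")
        elif self.kind == "rotate":
            if self.parameter not in ROTATION_ANGLES:
                raise ValueError(f"angle {self.parameter} not in allowed set")
        else:
            raise ValueError(f"unknown probe kind {self.kind!r}")


def probe_contrast(c: SceneComponents, w_levels: tuple[float, ...] = CONTRAST_LEVELS) -> dict[float, np.ndarray]:
    """Recompose one scene at each specular weight."""
    return {w: compose_image(c, GlossParams(w)) for w in w_levels}


def morph_specular(S: np.ndarray, op: str, radius: int) -> np.ndarray:
    """Per-channel grayscale morphology of the specular image with a disk."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(S.shape[0], S.shape[1]) // 2:
        raise ValueError("radius exceeds half the image size")
    if op not in ("erode", "dilate"):
        raise ValueError(f"op must be erode or dilate, got {op!r}")
    fn = erosion if op == "erode" else dilation
    footprint = disk(radius)
    return np.stack([fn(S[..., ch], footprint) for ch in range(S.shape[2])], axis=2)


def probe_size(c: SceneComponents, op: str, radius: int, base_w: float = BASE_PROBE_W) -> np.ndarray:
    """Compose the scene with a morphologically resized specular component."""
    S2 = morph_specular(c.specular, op, radius)
    mod = SceneComponents(c.scene_id, S2, c.diffuse, c.texture, c.alpha, c.background)
    return compose_image(mod, GlossParams(base_w))


@dataclass
class RotationProbe:
    manipulated: np.ndarray
    control: np.ndarray
    overlap_mask: np.ndarray  # H x W boolean specular-coverage mask (shared)


def rotate_specular(
    c: SceneComponents,
    angle: float,
    base_w: float = BASE_PROBE_W,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> RotationProbe:
    """Rotated-highlight image plus its coverage-matched control.

    The specular component (and its support) is rotated about the image
    center with bilinear interpolation; the shared overlap mask is the
    rotated support intersected with the object mask. The manipulated
    image composes the *rotated* specular restricted to that mask; the
    control composes the *unrotated* specular restricted to the same mask,
    so both images have identical specular coverage.
    """
    S = c.specular
    support = (S > support_threshold).any(axis=2).astype(float)
    if angle == 0:
        mask = (support > 0.5) & (c.alpha[..., 0] > 0)
    else:
        rot_support = ndimage.rotate(support, angle, reshape=False, order=1, mode="constant", cval=0.0)
        mask = (rot_support > 0.5) & (c.alpha[..., 0] > 0)
    m3 = mask[..., None].astype(float)
    if angle == 0:
        S_rot = S
    else:
        S_rot = np.clip(
            np.stack(
                [ndimage.rotate(S[..., ch], angle, reshape=False, order=1, mode="constant", cval=0.0) for ch in range(3)],
                axis=2,
            ),
            0.0,
            None,
        )
    manip = SceneComponents(c.scene_id, S_rot * m3, c.diffuse, c.texture, c.alpha, c.background)
    ctrl = SceneComponents(c.scene_id, S * m3, c.diffuse, c.texture, c.alpha, c.background)
    return RotationProbe(
        manipulated=compose_image(manip, GlossParams(base_w)),
        control=compose_image(ctrl, GlossParams(base_w)),
        overlap_mask=mask,
    )


def build_probe_scenes(n_scenes: int = 120, seed: int = 2024, size: int = 32) -> list[SceneComponents]:
    """Fresh coverage-filtered scenes, disjoint from any training corpus
    that used a different master seed."""
    scenes = []
    draw = 0
    while len(scenes) < n_scenes:
        c = generate_scene_components(_component_seed(seed, draw), size=size)
        draw += 1
        if coverage_filter(c.alpha):
            scenes.append(c)
    return scenes


def probe_responses(model, scenes: list[SceneComponents], angles=ROTATION_ANGLES) -> dict:
    """Mean model response per probe condition over a scene set.

    Keys: ("contrast", w), ("erode"/"dilate", radius), ("unmanipulated", 0),
    ("rotate", angle) and ("rotate_control", angle).
    """

    def respond(images: list[np.ndarray]) -> float:
        X = np.stack([im.transpose(2, 0, 1) for im in images])
        return float(np.mean(model.predict_proba(X)))

    out: dict = {}
    for w in CONTRAST_LEVELS:
        out[("contrast", w)] = respond([compose_image(c, GlossParams(w)) for c in scenes])
    out[("unmanipulated", 0)] = respond([compose_image(c, GlossParams(BASE_PROBE_W)) for c in scenes])
    for op in ("erode", "dilate"):
        for r in MORPH_RADII:
            out[(op, r)] = respond([probe_size(c, op, r) for c in scenes])
    for a in angles:
        probes = [rotate_specular(c, a) for c in scenes]
        out[("rotate", a)] = respond([p.manipulated for p in probes])
        out[("rotate_control", a)] = respond([p.control for p in probes])
    return out


@dataclass
class EffectSizeReport:
    contrast: float
    erode: float
    dilate: float
    rotate: float


def effect_sizes(responses: dict) -> EffectSizeReport:
    """Extreme-condition response contrasts.

    contrast: R(w=1.0) - R(w=0.01); erode: R(unmanipulated) - R(erode r=5);
    dilate: R(dilate r=5) - R(unmanipulated); rotate: max over angles of
    R(control) - R(rotated). Raises KeyError naming a missing condition.
    """
    for key in (("contrast", 1.0), ("contrast", 0.01), ("unmanipulated", 0), ("erode", 5), ("dilate", 5)):
        if key not in responses:
            raise KeyError(f"missing probe condition {key}")
    angles = sorted({k[1] for k in responses if k[0] == "rotate"})
    if not angles:
        raise KeyError("missing probe condition ('rotate', *)")
    for a in angles:
        if ("rotate_control", a) not in responses:
            raise KeyError(f"missing probe condition ('rotate_control', {a})")
    rot = max(responses[("rotate_control", a)] - responses[("rotate", a)] for a in angles)
    return EffectSizeReport(
        contrast=responses[("contrast", 1.0)] - responses[("contrast", 0.01)],
        erode=responses[("unmanipulated", 0)] - responses[("erode", 5)],
        dilate=responses[("dilate", 5)] - responses[("unmanipulated", 0)],
        rotate=rot,
    )
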