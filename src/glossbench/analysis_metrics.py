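"""Summary analyses: human-likeness, depth trends, triangle ratings, d'.

These are the statistics computed over trained-network search records and
observer response tables: leave-one-out observer correlations, the
per-depth correlation between task accuracy and human-likeness with its
quadratic trend and zero crossing, the composition of the most human-like
decile, the decomposition of triangular-field ratings into glossiness and
realness, rating accuracy, and the pooled-variance sensitivity index d'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.corrcoef(x, y)[0, 1])


def loo_human_correlations(table: pd.DataFrame) -> pd.Series:
    """Per-observer correlation with the mean of the remaining observers.

    ``table`` is a response table with numeric responses; repeats are
    averaged per (observer, image) first. Requires >= 3 observers rating a
    common image set.
    """
    wide = table.pivot_table(index="image_id", columns="observer_id", values="response", aggfunc="mean")
    wide = wide.dropna(axis=0)
    if wide.shape[1] < 3:
        raise ValueError("need at least 3 observers")
    out = {}
    total = wide.sum(axis=1)
    for obs in wide.columns:
        rest_mean = (total - wide[obs]) / (wide.shape[1] - 1)
        out[obs] = pearson_r(wide[obs].to_numpy(), rest_mean.to_numpy())
    return pd.Series(out, name="loo_r")


@dataclass
class DepthTrend:
    per_depth_rho: pd.Series  # depth -> Pearson(accuracy, human-likeness)
    quad_coeffs: np.ndarray  # highest power first
    zero_crossing: float | None


def depth_trend(records: pd.DataFrame, min_per_depth: int = 3) -> DepthTrend:
    """Accuracy-vs-human-likeness correlation per depth, with quadratic fit.

    ``records`` needs columns depth, val_accuracy, objective, dead. Depths
    with fewer than ``min_per_depth`` live networks or zero variance in
    either variable are excluded (with a warning). The fitted quadratic's
    smallest real root inside the observed depth range is reported as the
    crossover depth, or None when no root falls in range.
    """
    live = records[~records["dead"].astype(bool)]
    rhos = {}
    for d, grp in live.groupby("depth"):
        if len(grp) < min_per_depth:
            continue
        a = grp["val_accuracy"].to_numpy(dtype=float)
        r = grp["objective"].to_numpy(dtype=float)
        if np.std(a) < 1e-12 or np.std(r) < 1e-12:
            warnings.warn(f"depth {d}: zero variance, excluded from trend", RuntimeWarning)
            continue
        rhos[d] = pearson_r(a, r)
    per_depth = pd.Series(rhos).sort_index()
    if len(per_depth) < 3:
        return DepthTrend(per_depth, np.array([]), None)
    coeffs = np.polyfit(per_depth.index.to_numpy(dtype=float), per_depth.to_numpy(), deg=2)
    roots = np.roots(coeffs)
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-9)
    lo, hi = float(per_depth.index.min()), float(per_depth.index.max())
    in_range = [r for r in real if lo <= r <= hi]
    return DepthTrend(per_depth, coeffs, in_range[0] if in_range else None)


def top_decile_composition(records: pd.DataFrame, frac: float = 0.10) -> pd.Series:
    """Depth proportions among the most human-like ``frac`` of live networks.

    Selection size is ceil(frac * n); boundary ties break deterministically
    by trial id (lower id wins). Proportions sum to 1.
    """
    live = records[~records["dead"].astype(bool)]
    if len(live) < 10:
        raise ValueError("need at least 10 live records")
    k = int(np.ceil(frac * len(live)))
    ranked = live.sort_values(["objective", "trial"], ascending=[False, True], kind="mergesort")
    top = ranked.head(k)
    props = top["depth"].value_counts(normalize=True).sort_index()
    props.name = "proportion"
    return props


# -- triangular rating field ------------------------------------------------
TRIANGLE_LOW = (0.0, 0.0)
TRIANGLE_HIGH = (1.0, 0.0)
TRIANGLE_APEX = (0.5, 1.0)


def triangle_decompose(points: np.ndarray, canvas: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Split triangle points into (glossiness, realness).

    The rating triangle has corners low-gloss (0,0), high-gloss (1,0) and
    an "unreal" apex (0.5,1), all in units of ``canvas`` (the rating-field
    side length, so the result is invariant to uniform canvas scaling).
    Realness is the vertical coordinate; glossiness is the horizontal
    position rescaled by the width of the triangle row at that height,
    with the apex mapping to 0.5. Points outside the triangle raise
    ValueError.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2) / float(canvas)
    x, y = pts[:, 0], pts[:, 1]
    eps = 1e-9
    left = y / 2.0
    width = 1.0 - y
    if np.any(y < -eps) or np.any(y > 1 + eps) or np.any(x < left - eps) or np.any(x > left + width + eps):
        raise ValueError("point outside the rating triangle")
    gloss = np.where(width > eps, (x - left) / np.maximum(width, eps), 0.5)
    return np.clip(gloss, 0.0, 1.0), np.clip(y, 0.0, 1.0)


def rating_accuracy(glossiness: np.ndarray, labels: np.ndarray) -> float:
    """Fraction rated strictly on the correct half of the gloss scale.

    ``labels`` are 1 for high gloss, 0 for low. Ratings exactly at the
    midpoint count as incorrect.
    """
    g = np.asarray(glossiness, dtype=float)
    lab = np.asarray(labels)
    if g.size == 0:
        raise ValueError("empty group")
    correct = np.where(lab > 0.5, g > 0.5, g < 0.5)
    return float(correct.mean())


def dprime(glossiness_high: np.ndarray, glossiness_low: np.ndarray) -> float:
    """Sensitivity index: mean separation in pooled-SD units.

    d' = (mean_high - mean_low) / sqrt((var_high + var_low) / 2), using
    unbiased sample variances. Zero pooled variance yields a signed
    infinity sentinel rather than an exception.
    """
    h = np.asarray(glossiness_high, dtype=float)
    l = np.asarray(glossiness_low, dtype=float)
    if h.size == 0 or l.size == 0:
        raise ValueError("empty group")
    vh = h.var(ddof=1) if h.size > 1 else 0.0
    vl = l.var(ddof=1) if l.size > 1 else 0.0
    pooled = np.sqrt((vh + vl) / 2.0)
    diff = h.mean() - l.mean()
    if pooled < 1e-12:
        if diff == 0:
            return 0.0
        return float(np.sign(diff) * np.inf)
    return float(diff / pooled)
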