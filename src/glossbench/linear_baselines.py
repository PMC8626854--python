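"""Hand-engineered baseline classifiers for gloss categorisation.

Two linear model families:

* a max-margin (linear SVM) classifier on eight pixel summary statistics —
  mean, variance, skewness and kurtosis of the luminance and saturation
  histograms;
* a logistic regression on variance-thresholded principal components of a
  texture-statistic vector (marginal moments, wavelet-pyramid subband
  moments, local autocorrelations, cross-scale and cross-channel
  correlations) — a reduced stand-in for full Portilla–Simoncelli color
  texture statistics.

Both are evaluated by scene-level twofold cross-validation repeated 10
times, so every image receives exactly 10 held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats as sstats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .observer_sim import luminance


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Sample mean/variance/skew-g1/kurtosis (non-excess); degenerate -> 0."""
    x = np.asarray(x, dtype=float).ravel()
    m = float(x.mean())
    v = float(x.var())
    if v <= 1e-24:
        return (m, 0.0, 0.0, 0.0)
    sk = float(sstats.skew(x, bias=True))
    ku = float(sstats.kurtosis(x, fisher=False, bias=True))
    return (m, v, sk, ku)


def saturation(image: np.ndarray) -> np.ndarray:
    """HSV saturation, scale-invariant: (max - min) / max per pixel."""
    mx = image.max(axis=2)
    mn = image.min(axis=2)
    return np.where(mx > 1e-12, (mx - mn) / np.maximum(mx, 1e-12), 0.0)


def pixel_stats(image: np.ndarray) -> np.ndarray:
    """The eight pixel summary statistics of one RGB image."""
    lum = luminance(image)
    sat = saturation(image)
    return np.array([*_moments(lum), *_moments(sat)])


@dataclass(frozen=True)
class TextureConfig:
    """Wavelet-pyramid configuration determining the statistic vector length."""

    scales: int = 3
    wavelet: str = "db2"
    acorr_radius: int = 1  # neighborhood half-width for autocorrelation stats

    @property
    def n_orientations(self) -> int:
        return 3  # horizontal / vertical / diagonal detail bands

    def vector_length(self) -> int:
        n_ch = 3
        marginal = 6 * n_ch
        subband = 3 * self.n_orientations * self.scales * n_ch
        acorr = ((2 * self.acorr_radius + 1) ** 2 - 1) * self.scales * n_ch
        cross_scale = self.n_orientations * (self.scales - 1) * n_ch
        cross_channel = 3 * self.n_orientations * self.scales
        return marginal + subband + acorr + cross_scale + cross_channel


def texture_stat_labels(config: TextureConfig = TextureConfig()) -> list[str]:
    """Names aligned with :func:`texture_stats` output positions."""
    labels: list[str] = []
    r = config.acorr_radius
    for ch in range(3):
        labels += [f"ch{ch}_{m}" for m in ("mean", "var", "skew", "kurt", "min", "max")]
        for scale in range(config.scales):
            for orient in ("h", "v", "d"):
                labels += [f"ch{ch}_s{scale}_{orient}_{m}" for m in ("var", "skew", "kurt")]
        for scale in range(config.scales):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dy == 0 and dx == 0:
                        continue
                    labels.append(f"ch{ch}_low{scale}_acorr_{dy}_{dx}")
        for scale in range(config.scales - 1):
            for orient in ("h", "v", "d"):
                labels.append(f"ch{ch}_xscale{scale}_{orient}")
    for scale in range(config.scales):
        for orient in ("h", "v", "d"):
            for c1, c2 in ((0, 1), (0, 2), (1, 2)):
                labels.append(f"xchan{c1}{c2}_s{scale}_{orient}")
    assert len(labels) == config.vector_length()
    return labels


def _autocorr_patch(x: np.ndarray, radius: int) -> np.ndarray:
    """Normalized circular autocorrelation values in a (2r+1)^2 neighborhood."""
    x = x - x.mean()
    f = np.fft.rfft2(x)
    ac = np.fft.irfft2(f * np.conj(f), s=x.shape)
    ac = ac / max(ac.flat[0], 1e-24)
    vals = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy == 0 and dx == 0:
                continue
            vals.append(ac[dy % x.shape[0], dx % x.shape[1]])
    return np.array(vals)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / den) if den > 1e-24 else 0.0


def texture_stats(image: np.ndarray, config: TextureConfig = TextureConfig()) -> np.ndarray:
    """Reduced texture-statistic vector over a wavelet pyramid.

    Per channel: marginal moments (mean, var, skew, kurt, min, max),
    per-subband variance/skew/kurtosis at every scale and orientation,
    autocorrelation of the lowpass at every scale, and correlations of
    subband magnitudes across adjacent scales. Across channels:
    correlations of corresponding detail subbands for every channel pair.
    Length is constant for a fixed config.
    """
    h, w = image.shape[:2]
    side = min(h, w)
    if side < 2 ** (config.scales + 2) or (side & (side - 1)) != 0:
        raise ValueError(f"image side {side} too small or not a power of 2 for {config.scales} scales")
    feats: list[float] = []
    per_channel_bands = []
    for ch in range(3):
        x = image[..., ch].astype(float)
        m, v, sk, ku = _moments(x)
        feats += [m, v, sk, ku, float(x.min()), float(x.max())]
        coeffs = pywt.wavedec2(x, config.wavelet, level=config.scales, mode="periodization")
        lows = []
        bands = []  # bands[scale][orient]; scale 0 = finest
        low = x
        for lvl in range(config.scales):
            cA = pywt.wavedec2(low, config.wavelet, level=1, mode="periodization")[0]
            lows.append(cA)
            low = cA
        details = coeffs[1:][::-1]  # finest first
        for scale_bands in details:
            bands.append([np.asarray(b, dtype=float) for b in scale_bands])
        per_channel_bands.append(bands)
        for scale in range(config.scales):
            for b in bands[scale]:
                _, bv, bsk, bku = _moments(b)
                feats += [bv, bsk, bku]
        for cA in lows:
            feats += list(_autocorr_patch(cA, config.acorr_radius))
        for scale in range(config.scales - 1):
            for orient in range(3):
                fine = np.abs(bands[scale][orient])
                coarse = np.abs(bands[scale + 1][orient])
                up = np.kron(coarse, np.ones((2, 2)))[: fine.shape[0], : fine.shape[1]]
                feats.append(_corr(fine, up))
    for scale in range(config.scales):
        for orient in range(3):
            for c1, c2 in ((0, 1), (0, 2), (1, 2)):
                feats.append(_corr(per_channel_bands[c1][scale][orient], per_channel_bands[c2][scale][orient]))
    out = np.array(feats)
    assert out.size == config.vector_length(), (out.size, config.vector_length())
    return out


def pca_reduce(X: np.ndarray, var_threshold: float) -> tuple[PCA, np.ndarray]:
    """Project onto the smallest PC basis explaining >= ``var_threshold``.

    Returns the fitted projection (reusable on held-out data via
    ``proj.transform``) and the reduced matrix.
    """
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    full = PCA().fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, len(cum))
    proj = PCA(n_components=k).fit(X)
    return proj, proj.transform(X)


def _make_model(model: str, seed: int):
    if model == "max-margin":
        return LinearSVC(C=1.0, random_state=seed, max_iter=20000)
    if model == "logistic":
        return LogisticRegression(max_iter=5000, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def twofold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    scene_ids: np.ndarray,
    model: str = "max-margin",
    n_repeats: int = 10,
    seed: int = 0,
    pca_threshold: float | None = None,
) -> pd.DataFrame:
    """Scene-split twofold cross-validation repeated ``n_repeats`` times.

    Each repeat splits *scenes* (not images) into random halves, trains on
    one half and predicts the other, then swaps — so the two images of a
    scene never straddle a split and every image collects exactly
    ``n_repeats`` held-out predictions. With an odd scene count the last
    scene alternates sides across repeats. Returns a long table
    (image_index, repeat, prediction) plus a ``mean`` column merged per
    image; predictions are P(high) for logistic and {0,1} for max-margin.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    scene_ids = np.asarray(scene_ids)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts[0] != counts[1]:
        raise ValueError("labels must be binary and balanced")
    scenes = np.unique(scene_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(scenes)
        half = len(perm) // 2
        if len(perm) % 2 == 1:
            # odd scene count: alternate the leftover scene's side by repeat
            half += rep % 2
        first = set(perm[:half])
        in_first = np.isin(scene_ids, list(first))
        for train_mask in (in_first, ~in_first):
            test_mask = ~train_mask
            Xtr, Xte = features[train_mask], features[test_mask]
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            if pca_threshold is not None:
                proj, Xtr = pca_reduce(Xtr, pca_threshold)
                Xte = proj.transform(Xte)
            clf = _make_model(model, seed + rep)
            clf.fit(Xtr, labels[train_mask])
            if hasattr(clf, "predict_proba"):
                pred = clf.predict_proba(Xte)[:, list(clf.classes_).index(classes.max())]
            else:
                pred = (clf.predict(Xte) == classes.max()).astype(float)
            for idx, p in zip(np.flatnonzero(test_mask), pred):
                rows.append((int(idx), rep, float(p)))
    table = pd.DataFrame(rows, columns=["image_index", "repeat", "prediction"])
    table = table.merge(
        table.groupby("image_index")["prediction"].mean().rename("mean"),
        on="image_index",
    )
    return table


def cv_accuracy(table: pd.DataFrame, labels: np.ndarray) -> float:
    """Accuracy of per-image mean predictions thresholded at 0.5."""
    labels = np.asarray(labels)
    hi = labels.max()
    means = table.drop_duplicates("image_index").set_index("image_index")["mean"]
    pred_hi = means > 0.5
    truth = pd.Series(labels == hi, index=np.arange(len(labels)))
    return float((pred_hi == truth.loc[means.index]).mean())
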