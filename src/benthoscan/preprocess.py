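"""Illumination correction and histogram normalization.

Towed-camera frames show a radial lightness falloff toward the corners
(vignetting) because the lamps illuminate the scene center most strongly.
The correction subtracts a heavily Gaussian-smoothed copy of each color
channel from the channel itself, removing the low-frequency illumination
field while preserving local structure.  The signed residual is then mapped
to a common intensity distribution by a piecewise-linear histogram stretch
anchored at the gray-histogram peak and two bracketing values, so all frames
of a transect share similar color statistics.

The smoothing kernel size ``M`` is the one tunable that matters; it can be
chosen data-driven by maximizing cluster-validity indices of taxon feature
clusters over candidate values of ``M``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

#: Index names in reporting order.
CLUSTER_INDEX_NAMES = (
    "calinski_harabasz",
    "index_i",
    "davies_bouldin",
    "intra_cluster_variance",
    "inter_cluster_variance",
)

#: Indices where smaller is better; inverted before curve normalization.
_INVERTED_INDICES = ("davies_bouldin", "intra_cluster_variance")


@dataclass(frozen=True)
class HistogramParams:
    """Peak and bracketing gray values of one image's histogram."""

    g_peak: float
    g_low: float
    g_high: float
    fraction: float

    def __post_init__(self) -> None:
        if not (self.g_low <= self.g_peak <= self.g_high):
            raise ValueError("require g_low <= g_peak <= g_high")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")


@dataclass
class KernelTuningResult:
    """Outcome of the data-driven kernel-size search."""

    candidates: list[int]
    raw_curves: dict[str, np.ndarray]
    normalized_curves: dict[str, np.ndarray]
    mean_curve: np.ndarray
    chosen_M: int


def grayscale(image: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Grayscale conversion: unweighted channel mean (default) or Rec.601."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if mode == "mean":
        return img.mean(axis=-1)
    if mode == "rec601":
        w = np.array([0.299, 0.587, 0.114])
        return img @ w
    raise ValueError(f"unknown grayscale mode {mode!r}")


def vignette_correct(image: np.ndarray, M: int = 701) -> np.ndarray:
    """Subtract the channel-wise Gaussian-smoothed image (kernel size ``M``).

    Returns a signed float64 array; the residual is carried at full
    precision until the histogram transform re-centers it.  ``M`` must be
    odd and at least 1; ``M = 1`` is the identity smoothing and yields a
    (near-)zero output.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if M < 1 or M % 2 == 0:
        raise ValueError("kernel size M must be odd and >= 1")
    if M > 2 * max(img.shape[0], img.shape[1]):
        raise ValueError(
            f"kernel size M={M} exceeds twice the image extent")
    if M == 1:
        return img - img
    # separable Gaussian, sigma = M/6, truncated so the kernel spans ~M pixels
    sigma = M / 6.0
    radius = (M - 1) // 2
    if img.ndim == 2:
        smooth = ndimage.gaussian_filter(img, sigma, mode="reflect",
                                         truncate=radius / sigma)
    else:
        smooth = np.empty_like(img)
        for c in range(img.shape[-1]):
            smooth[..., c] = ndimage.gaussian_filter(
                img[..., c], sigma, mode="reflect", truncate=radius / sigma)
    return img - smooth


def gray_peak_bounds(
    image: np.ndarray,
    fraction: float = 0.5,
    grayscale_mode: str = "mean",
) -> HistogramParams:
    """Locate the gray-histogram peak and its bracketing values.

    The histogram is taken over rounded integer gray values.  ``g_peak`` is
    the modal value (ties broken toward the lower gray value); ``g_low`` and
    ``g_high`` are the nearest values below/above the peak whose count drops
    to at most ``fraction`` times the peak count, searched within the
    occupied value range.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    gray = grayscale(image, grayscale_mode)
    if gray.size == 0:
        raise ValueError("empty image has no histogram")
    vals = np.rint(gray).astype(np.int64).ravel()
    offset = vals.min()
    counts = np.bincount(vals - offset)
    peak_idx = int(np.argmax(counts))  # argmax ties -> lower gray value
    peak_count = counts[peak_idx]
    limit = fraction * peak_count

    g_low = peak_idx
    for i in range(peak_idx - 1, -1, -1):
        if counts[i] <= limit:
            g_low = i
            break
    else:
        if peak_idx > 0:
            g_low = 0
    g_high = peak_idx
    for i in range(peak_idx + 1, len(counts)):
        if counts[i] <= limit:
            g_high = i
            break
    else:
        if peak_idx < len(counts) - 1:
            g_high = len(counts) - 1

    return HistogramParams(
        g_peak=float(peak_idx + offset),
        g_low=float(g_low + offset),
        g_high=float(g_high + offset),
        fraction=fraction,
    )


def histogram_transform(
    image: np.ndarray,
    params: HistogramParams,
    anchors: tuple[float, float, float] = (0.1, 0.5, 0.9),
    out_max: float = 255.0,
) -> np.ndarray:
    """Piecewise-linear remap onto fixed target anchors, per channel.

    Maps ``(g_low, g_peak, g_high)`` onto ``anchors * out_max`` (defaults:
    10% / 50% / 90% of the output range), extending the outer segments'
    slopes beyond the bracket and clipping to ``[0, out_max]``.  The same
    gray-derived parameters are applied to every color channel, which makes
    the map monotone non-decreasing in input intensity.  A degenerate
    bracket (``g_low == g_high``) yields an identity map with a warning.

    Output is uint8 for ``out_max = 255``.
    """
    img = np.asarray(image, dtype=np.float64)
    t_low, t_mid, t_high = (a * out_max for a in anchors)
    if not t_low < t_mid < t_high:
        raise ValueError("anchors must be strictly increasing")

    if params.g_low == params.g_high:
        warnings.warn("degenerate histogram bracket; applying identity map",
                      stacklevel=2)
        out = img.copy()
        if params.g_low == params.g_peak:
            # constant image: place it at the target peak value
            if np.all(img == params.g_peak):
                out = np.full_like(img, t_mid)
        return _finalize(out, out_max)

    xs, ys = [], []
    for x, y in ((params.g_low, t_low), (params.g_peak, t_mid),
                 (params.g_high, t_high)):
        if not xs or x > xs[-1]:
            xs.append(x)
            ys.append(y)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    out = np.interp(img, xs, ys)
    # extend the outer slopes instead of clamping at the anchor values
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    below = img < xs[0]
    above = img > xs[-1]
    out[below] = ys[0] + (img[below] - xs[0]) * lo_slope
    out[above] = ys[-1] + (img[above] - xs[-1]) * hi_slope
    return _finalize(out, out_max)


def _finalize(out: np.ndarray, out_max: float) -> np.ndarray:
    out = np.clip(out, 0.0, out_max)
    if out_max == 255.0:
        return np.rint(out).astype(np.uint8)
    return out


def preprocess_image(
    image: np.ndarray,
    M: int = 701,
    fraction: float = 0.5,
    anchors: tuple[float, float, float] = (0.1, 0.5, 0.9),
    grayscale_mode: str = "mean",
) -> np.ndarray:
    """Full pre-processing: vignette correction + histogram normalization.

    ``M = 0`` skips the illumination correction (the "unfiltered" setting);
    the histogram normalization is applied in either case.  Deterministic:
    identical inputs give bit-identical uint8 output.
    """
    if M == 0:
        corrected = np.asarray(image, dtype=np.float64)
    else:
        corrected = vignette_correct(image, M)
    params = gray_peak_bounds(corrected, fraction, grayscale_mode)
    return histogram_transform(corrected, params, anchors)


# ---------------------------------------------------------------------------
# cluster-validity indices and kernel-size tuning


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    singletons = classes[counts < 2]
    if len(singletons):
        warnings.warn(
            f"excluding singleton classes from cluster indices: "
            f"{list(singletons)}", stacklevel=3)
        keep = ~np.isin(y, singletons)
        X, y = X[keep], y[keep]
        classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with >= 2 members")
    return X, y, classes


def compute_cluster_indices(
    X: np.ndarray, y: Sequence
) -> dict[str, float]:
    """Five cluster-validity indices of a labeled feature cloud.

    Calinski-Harabasz and Davies-Bouldin follow their standard definitions;
    Index-I is the Bandyopadhyay formulation with power p = 2; the intra-
    (inter-) cluster variance is the mean squared distance of points to
    their class centroid (of class centroids to the global centroid).
    Singleton classes are excluded with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    X, y, classes = _class_stats(X, y)

    global_centroid = X.mean(axis=0)
    centroids = np.stack([X[y == c].mean(axis=0) for c in classes])

    # Index-I ingredients
    e1 = np.linalg.norm(X - global_centroid, axis=1).sum()
    ek = sum(
        np.linalg.norm(X[y == c] - centroids[i], axis=1).sum()
        for i, c in enumerate(classes)
    )
    d_max = max(
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(len(classes)) for j in range(i + 1, len(classes))
    )
    K = len(classes)
    index_i = ((1.0 / K) * (e1 / max(ek, 1e-300)) * d_max) ** 2

    intra = float(np.mean([
        ((X[y == c] - centroids[i]) ** 2).sum(axis=1).mean()
        for i, c in enumerate(classes)
    ]))
    inter = float(((centroids - global_centroid) ** 2).sum(axis=1).mean())

    return {
        "calinski_harabasz": float(calinski_harabasz_score(X, y)),
        "index_i": float(index_i),
        "davies_bouldin": float(davies_bouldin_score(X, y)),
        "intra_cluster_variance": intra,
        "inter_cluster_variance": inter,
    }


def normalize_curve(values: np.ndarray, invert: bool = False) -> np.ndarray:
    """Min-max normalize a raw index curve to [0, 1] (optionally inverted).

    Invariant to affine rescaling of the raw curve; a constant curve maps to
    all 0.5 (no preference among candidates).
    """
    v = np.asarray(values, dtype=np.float64)
    if invert:
        v = -v
    span = v.max() - v.min()
    if span == 0:
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def tune_kernel_size(
    images: Mapping[str, np.ndarray],
    label_positions: Iterable[tuple[str, str, float, float]],
    M_candidates: Sequence[int],
    feature_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    fraction: float = 0.5,
    anchors: tuple[float, float, float] = (0.1, 0.5, 0.9),
) -> KernelTuningResult:
    """Choose the Gaussian kernel size that best separates taxon clusters.

    For each candidate ``M``: pre-process all images, extract feature
    vectors at the labeled positions (``feature_fn(image, positions) ->
    (n, d)``), and compute the five cluster-validity indices with the taxon
    as the class.  Each index curve is normalized to [0, 1] (Davies-Bouldin
    and intra-cluster variance inverted so larger is better); the chosen
    ``M`` maximizes the mean normalized curve, ties toward smaller ``M``.

    ``label_positions`` yields ``(image_id, taxon, x, y)`` tuples.
    """
    M_candidates = list(M_candidates)
    if not M_candidates:
        raise ValueError("no kernel-size candidates")
    positions = list(label_positions)
    taxa = sorted({t for _, t, _, _ in positions})
    if len(taxa) < 2:
        raise ValueError("kernel tuning needs labels from >= 2 taxa")

    raw = {name: [] for name in CLUSTER_INDEX_NAMES}
    for M in M_candidates:
        feats, classes = [], []
        for image_id, img in images.items():
            pos = [(t, x, y) for iid, t, x, y in positions if iid == image_id]
            if not pos:
                continue
            processed = preprocess_image(img, M, fraction, anchors)
            xy = np.array([[x, y] for _, x, y in pos], dtype=int)
            feats.append(feature_fn(processed, xy))
            classes.extend(t for t, _, _ in pos)
        X = np.concatenate(feats, axis=0)
        idx = compute_cluster_indices(X, np.array(classes))
        for name in CLUSTER_INDEX_NAMES:
            raw[name].append(idx[name])

    raw_curves = {name: np.asarray(vals) for name, vals in raw.items()}
    normalized = {
        name: normalize_curve(vals, invert=name in _INVERTED_INDICES)
        for name, vals in raw_curves.items()
    }
    mean_curve = np.mean([normalized[name] for name in CLUSTER_INDEX_NAMES],
                         axis=0)
    best = int(np.argmax(mean_curve))  # argmax ties -> first, i.e. smaller M
    order = np.argsort(M_candidates, kind="stable")
    # evaluate in ascending-M order for the smaller-M tie rule
    ordered_mean = mean_curve[order]
    best = order[int(np.argmax(ordered_mean))]
    return KernelTuningResult(
        candidates=M_candidates,
        raw_curves=raw_curves,
        normalized_curves=normalized,
        mean_curve=mean_curve,
        chosen_M=int(M_candidates[best]),
    )
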