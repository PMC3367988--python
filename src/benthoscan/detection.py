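"""Pixel-wise cascade detection on full fields of view.

Trained per-taxon SVMs are arranged in an ordered cascade: pixels are
visited on a (stride) grid and each taxon model is evaluated in cascade
order until one exceeds its confidence threshold and claims the pixel —
avoiding the cost of evaluating every model everywhere.  A safety margin
around already-claimed pixels is excluded from further classification
(object occurrence is sparse, so nearby repeat detections are almost
always false).  Unclaimed pixels whose background confidence reaches the
background threshold are labeled background; the rest are rejected.

Per-taxon confidence maps are then binarized at taxon-specific thresholds,
8-connected components smaller than a taxon-specific minimum blob size are
discarded, and the surviving blob centroids are the detections.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .config import BACKGROUND, TaxonSet
from .features import FeatureExtractor
from .training import NormalizationModel, TaxonModel, se_ppv

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class CascadeEntry:
    model: TaxonModel
    theta: float = 0.5
    s_min: int = 10


@dataclass
class CascadeTree:
    """Ordered taxon classifiers plus the background model.

    Each taxon appears exactly once; ``entries`` order is the evaluation
    order.  ``theta_bg`` is the binarization threshold of the background
    confidence map (no blob detection is performed for background).
    """

    entries: list[CascadeEntry]
    background_model: TaxonModel | None = None
    theta_bg: float = 0.5

    def __post_init__(self):
        names = [e.model.taxon for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("each taxon may appear only once in the cascade")
        for e in self.entries:
            if not 0.0 <= e.theta <= 1.0:
                raise ValueError("cascade thresholds must lie in [0, 1]")

    @property
    def order(self) -> list[str]:
        return [e.model.taxon for e in self.entries]

    def entry(self, taxon: str) -> CascadeEntry:
        for e in self.entries:
            if e.model.taxon == taxon:
                return e
        raise KeyError(taxon)


@dataclass
class Blob:
    """A connected foreground region of a binarized confidence map."""

    taxon: str
    size: int
    centroid: tuple[float, float]  # (x, y)
    confidence: float = float("nan")
    pixels: np.ndarray | None = None  # (k, 2) array of (y, x), optional


@dataclass
class FieldClassification:
    """Pixel-wise cascade output for one field of view."""

    image_id: str
    confidence_maps: dict[str, np.ndarray]
    class_map: np.ndarray          # int codes; -1 rejected, -2 unvisited
    class_codes: dict[str, int]
    visited: np.ndarray            # bool mask of evaluated pixels


@dataclass
class DetectionResult:
    """Blob detections for one image."""

    image_id: str
    detections: list[Blob] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.detections:
            out[b.taxon] = out.get(b.taxon, 0) + 1
        return out

    def for_taxon(self, taxon: str) -> list[Blob]:
        return [b for b in self.detections if b.taxon == taxon]


# ---------------------------------------------------------------------------
# pixel-wise cascade classification


def _grid_features(image, extractor, normalizer, stride):
    feats, xs, ys = extractor.extract_grid(image, stride)
    if normalizer is not None:
        feats = normalizer.apply(feats)
    return feats, xs, ys


def classify_field_of_view(
    image: np.ndarray,
    cascade: CascadeTree,
    extractor: FeatureExtractor,
    normalizer: NormalizationModel | None = None,
    stride: int = 1,
    margin: int = 5,
    image_id: str = "image",
    grid_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FieldClassification:
    """Classify every grid pixel with the cascade of per-taxon SVMs.

    Models are evaluated in cascade order; the first model whose calibrated
    confidence reaches its threshold claims the pixel, and pixels within
    ``margin`` (Euclidean) of claimed pixels are skipped for the remaining
    stages.  Confidence values are recorded wherever a model was actually
    evaluated; maps are stored at full image resolution (stride cells are
    filled block-wise).
    """
    if not cascade.entries and cascade.background_model is None:
        raise ValueError("cascade has no models")
    h, w = image.shape[:2]
    feats, xs, ys = (grid_cache if grid_cache is not None
                     else _grid_features(image, extractor, normalizer, stride))
    gh = len(np.unique(ys))
    gw = len(np.unique(xs))

    taxa = cascade.order
    codes = {t: i for i, t in enumerate(taxa)}
    codes[BACKGROUND] = len(taxa)

    n = len(xs)
    assigned = np.full(n, -1, dtype=np.int32)   # cascade code or -1
    blocked = np.zeros(n, dtype=bool)
    conf_grid = {t: np.zeros(n, dtype=np.float32) for t in taxa}
    if cascade.background_model is not None:
        conf_grid[BACKGROUND] = np.zeros(n, dtype=np.float32)

    disk = _disk_offsets(margin, stride)
    for code, entry in enumerate(cascade.entries):
        active = (assigned < 0) & ~blocked
        if not active.any():
            break
        conf = entry.model.confidence(feats[active])
        conf_grid[entry.model.taxon][active] = conf
        hit_idx = np.flatnonzero(active)[conf >= entry.theta]
        assigned[hit_idx] = code
        if len(hit_idx) and margin > 0:
            blocked |= _dilate_hits(hit_idx, gh, gw, disk)

    # background decision for unclaimed, unblocked pixels
    class_grid = np.full(n, -1, dtype=np.int32)
    class_grid[assigned >= 0] = assigned[assigned >= 0]
    class_grid[blocked & (assigned < 0)] = -2
    if cascade.background_model is not None:
        active = (assigned < 0) & ~blocked
        if active.any():
            conf = cascade.background_model.confidence(feats[active])
            conf_grid[BACKGROUND][active] = conf
            bg_idx = np.flatnonzero(active)[conf >= cascade.theta_bg]
            class_grid[bg_idx] = codes[BACKGROUND]

    visited_grid = ~(blocked & (assigned < 0))

    def to_map(grid_vals, fill=0):
        m = grid_vals.reshape(gh, gw)
        full = np.kron(m, np.ones((stride, stride), dtype=m.dtype))
        return full[:h, :w]

    conf_maps = {t: to_map(v) for t, v in conf_grid.items()}
    class_map = to_map(class_grid)
    visited = to_map(visited_grid)
    return FieldClassification(
        image_id=image_id,
        confidence_maps=conf_maps,
        class_map=class_map,
        class_codes=codes,
        visited=visited.astype(bool),
    )


def _disk_offsets(margin: int, stride: int) -> np.ndarray:
    """Grid-cell offsets within Euclidean ``margin`` pixels."""
    r = int(np.ceil(margin / stride))
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1) for dx in range(-r, r + 1)
        if (dy * stride) ** 2 + (dx * stride) ** 2 <= margin ** 2
    ]
    return np.asarray(offs, dtype=np.int64)


def _dilate_hits(hit_idx: np.ndarray, gh: int, gw: int,
                 disk: np.ndarray) -> np.ndarray:
    hy, hx = np.divmod(hit_idx, gw)
    yy = hy[:, None] + disk[None, :, 0]
    xx = hx[:, None] + disk[None, :, 1]
    ok = (yy >= 0) & (yy < gh) & (xx >= 0) & (xx < gw)
    flat = (yy * gw + xx)[ok]
    out = np.zeros(gh * gw, dtype=bool)
    out[flat] = True
    return out


# ---------------------------------------------------------------------------
# blob extraction


def binarize_and_blob(
    conf_map: np.ndarray,
    theta: float,
    s_min: int,
    taxon: str = "",
    keep_pixels: bool = False,
) -> list[Blob]:
    """Threshold a confidence map and extract 8-connected blobs.

    Pixels with confidence >= ``theta`` are foreground; connected
    components smaller than ``s_min`` pixels are discarded; centroids are
    mean pixel coordinates.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    mask = np.asarray(conf_map) >= theta
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    sizes = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(sizes >= s_min) + 1
    blobs: list[Blob] = []
    if len(keep) == 0:
        return blobs
    centroids = ndimage.center_of_mass(mask, labeled, keep)
    maxima = ndimage.maximum(conf_map, labeled, keep)
    for lab, (cy, cx), cmax in zip(keep, centroids, maxima):
        pix = None
        if keep_pixels:
            yy, xx = np.nonzero(labeled == lab)
            pix = np.column_stack([yy, xx])
        blobs.append(Blob(taxon=taxon, size=int(sizes[lab - 1]),
                          centroid=(float(cx), float(cy)),
                          confidence=float(cmax), pixels=pix))
    return blobs


def detect(
    image: np.ndarray,
    cascade: CascadeTree,
    extractor: FeatureExtractor,
    normalizer: NormalizationModel | None = None,
    stride: int = 1,
    margin: int = 5,
    image_id: str = "image",
    grid_cache=None,
) -> DetectionResult:
    """End-to-end detection: cascade classification + blob extraction."""
    fc = classify_field_of_view(image, cascade, extractor, normalizer,
                                stride=stride, margin=margin,
                                image_id=image_id, grid_cache=grid_cache)
    # stride cells are expanded into blocks whose pixel center sits
    # (stride-1)/2 below/right of the window center the confidence belongs
    # to; re-align blob centroids onto the window-center lattice
    offset = (stride - 1) / 2.0
    detections: list[Blob] = []
    for entry in cascade.entries:
        taxon = entry.model.taxon
        blobs = binarize_and_blob(fc.confidence_maps[taxon], entry.theta,
                                  entry.s_min, taxon=taxon)
        for b in blobs:
            b.centroid = (max(b.centroid[0] - offset, 0.0),
                          max(b.centroid[1] - offset, 0.0))
        detections.extend(blobs)
    return DetectionResult(image_id=fc.image_id, detections=detections)


# ---------------------------------------------------------------------------
# automatic cascade tuning


def _match_counts(gold_xy: np.ndarray, det_xy: np.ndarray,
                  max_dist: float) -> tuple[int, int, int]:
    """Greedy nearest-first one-to-one matching; returns (tp, fp, fn)."""
    if len(gold_xy) == 0:
        return 0, len(det_xy), 0
    if len(det_xy) == 0:
        return 0, 0, len(gold_xy)
    d = np.hypot(gold_xy[:, 0, None] - det_xy[None, :, 0],
                 gold_xy[:, 1, None] - det_xy[None, :, 1])
    pairs = [(d[i, j], i, j) for i in range(d.shape[0])
             for j in range(d.shape[1]) if d[i, j] <= max_dist]
    pairs.sort()
    used_g, used_d = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_g or j in used_d:
            continue
        used_g.add(i)
        used_d.add(j)
        tp += 1
    return tp, len(det_xy) - tp, len(gold_xy) - tp


def _f_measure(tp: int, fp: int, fn: int) -> float:
    se, ppv = se_ppv(tp, fp, fn)
    if np.isnan(se) or np.isnan(ppv) or (se + ppv) == 0:
        return 0.0
    return 2 * se * ppv / (se + ppv)


def tune_cascade(
    models: Mapping[str, TaxonModel],
    images: Mapping[str, np.ndarray],
    gold: Sequence,
    taxa: TaxonSet,
    extractor: FeatureExtractor,
    normalizer: NormalizationModel | None = None,
    theta_grid: Sequence[float] = (0.3, 0.5, 0.7, 0.9),
    s_min_grid: Sequence[int] = (3, 8, 15, 30),
    theta_bg: float = 0.5,
    stride: int = 1,
    margin: int = 5,
    max_exhaustive: int = 5,
    conf_cache: Mapping[str, dict] | None = None,
) -> tuple[CascadeTree, dict]:
    """Search cascade order, thresholds and blob sizes on validation data.

    All models are first evaluated everywhere on each tuning image (no
    short-circuit), giving cached confidence grids.  Per-taxon (theta,
    s_min) are chosen to maximize that taxon's F-measure (harmonic mean of
    SE and PPV) against the gold standard; the cascade order is then
    searched (exhaustively up to ``max_exhaustive`` taxa, greedy insertion
    beyond) to maximize the mean per-taxon F-measure under full cascade
    semantics.  Deterministic throughout.

    ``conf_cache`` may supply pre-computed confidence grids per image
    (``{image_id: {"conf": {taxon: values}, "xs", "ys", "shape"}}``), e.g.
    out-of-fold confidences from models fitted on disjoint images; the
    ``images`` mapping is then ignored.
    """
    gold = list(gold)
    if not gold:
        raise ValueError("cascade tuning requires gold labels")
    taxa_names = [t for t in models if t != BACKGROUND]
    bg_model = models.get(BACKGROUND)

    # cache full confidence grids per image
    if conf_cache is not None:
        cache = dict(conf_cache)
    else:
        cache = {}
        for image_id, image in images.items():
            feats, xs, ys = _grid_features(image, extractor, normalizer,
                                           stride)
            conf = {t: models[t].confidence(feats) for t in taxa_names}
            cache[image_id] = {"conf": conf, "xs": xs, "ys": ys,
                               "shape": image.shape[:2]}

    gold_by = {}
    for g in gold:
        gold_by.setdefault((g.image_id, g.taxon), []).append((g.x, g.y))

    def taxon_counts(taxon, theta, s_min, conf_override=None):
        tp = fp = fn = 0
        for image_id, c in cache.items():
            conf = (conf_override[image_id] if conf_override is not None
                    else c["conf"][taxon])
            det_xy = _grid_blob_centroids(conf, c, stride, theta, s_min)
            gxy = np.asarray(gold_by.get((image_id, taxon), [])).reshape(-1, 2)
            t, f, n_ = _match_counts(gxy, det_xy, taxa[taxon].match_distance)
            tp, fp, fn = tp + t, fp + f, fn + n_
        return tp, fp, fn

    # stage 1: per-taxon threshold / blob-size selection on raw maps
    chosen: dict[str, tuple[float, int]] = {}
    for taxon in taxa_names:
        best_key, best_cfg = None, None
        for theta in theta_grid:
            for s_min in s_min_grid:
                f = _f_measure(*taxon_counts(taxon, theta, s_min))
                key = (-f, theta, s_min)
                if best_key is None or key < best_key:
                    best_key, best_cfg = key, (theta, int(s_min))
        chosen[taxon] = best_cfg

    # stage 2: order search under cascade semantics
    def score_order(order: Sequence[str]) -> float:
        per_taxon_f = []
        claim_conf = {
            iid: _simulate_cascade(cache[iid], order, chosen, stride, margin)
            for iid in cache
        }
        for taxon in order:
            theta, s_min = chosen[taxon]
            f = _f_measure(*taxon_counts(
                taxon, theta, s_min,
                conf_override={iid: claim_conf[iid][taxon] for iid in cache}))
            per_taxon_f.append(f)
        return float(np.mean(per_taxon_f)) if per_taxon_f else 0.0

    if len(taxa_names) <= max_exhaustive:
        candidates = [list(p) for p in itertools.permutations(sorted(taxa_names))]
        scores = [(score_order(o), o) for o in candidates]
        best_score, best_order = max(scores, key=lambda t: (t[0], t[1][::-1]))
    else:
        best_order = []
        for taxon in sorted(taxa_names):
            options = [
                best_order[:i] + [taxon] + best_order[i:]
                for i in range(len(best_order) + 1)
            ]
            scored = [(score_order(o), tuple(o)) for o in options]
            best_score, ord_t = max(scored, key=lambda t: (t[0], t[1]))
            best_order = list(ord_t)

    entries = [CascadeEntry(model=models[t], theta=chosen[t][0],
                            s_min=chosen[t][1]) for t in best_order]
    tree = CascadeTree(entries=entries, background_model=bg_model,
                       theta_bg=theta_bg)
    trace = {"per_taxon": chosen, "order": best_order, "score": best_score}
    return tree, trace


def _grid_to_map(conf: np.ndarray, c: dict, stride: int) -> np.ndarray:
    gh = len(np.unique(c["ys"]))
    gw = len(np.unique(c["xs"]))
    h, w = c["shape"]
    m = conf.reshape(gh, gw)
    return np.kron(m, np.ones((stride, stride), dtype=m.dtype))[:h, :w]


def _grid_blob_centroids(conf: np.ndarray, c: dict, stride: int,
                         theta: float, s_min: int) -> np.ndarray:
    """Blob centroids computed at stride-grid resolution (tuning fast path).

    Block upsampling preserves connectivity, scales component sizes by
    stride^2 and shifts centroids by (stride-1)/2, so grid-level labeling
    is equivalent to labeling the expanded map (up to border cropping).
    """
    gh = len(np.unique(c["ys"]))
    gw = len(np.unique(c["xs"]))
    mask = conf.reshape(gh, gw) >= theta
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.empty((0, 2))
    sizes = np.bincount(labeled.ravel())[1:] * stride * stride
    keep = np.flatnonzero(sizes >= s_min) + 1
    if not len(keep):
        return np.empty((0, 2))
    centroids = ndimage.center_of_mass(mask, labeled, keep)
    out = np.asarray([(cx, cy) for cy, cx in centroids])
    return out * stride  # grid cell (i, j) sits at pixel (stride*j, stride*i)


def _simulate_cascade(c: dict, order: Sequence[str],
                      chosen: Mapping[str, tuple[float, int]],
                      stride: int, margin: int) -> dict[str, np.ndarray]:
    """Replay cascade claiming on cached confidences.

    Returns per-taxon confidence grids as they would look after cascade
    evaluation (zero where an earlier stage claimed or blocked the pixel).
    """
    xs, ys = c["xs"], c["ys"]
    gh = len(np.unique(ys))
    gw = len(np.unique(xs))
    n = gh * gw
    available = np.ones(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)
    disk = _disk_offsets(margin, stride)
    out: dict[str, np.ndarray] = {}
    for taxon in order:
        theta, _ = chosen[taxon]
        conf = np.where(available & ~blocked, c["conf"][taxon], 0.0)
        out[taxon] = conf.astype(np.float32)
        hits = np.flatnonzero(conf >= theta)
        available[hits] = False
        if len(hits) and margin > 0:
            blocked |= _dilate_hits(hits, gh, gw, disk)
    return out


# ---------------------------------------------------------------------------
# persistence and export


def save_cascade(path, cascade: CascadeTree, config_hash: str = "") -> None:
    """Persist a tuned cascade (models, calibration, normalization) as one
    portable ``.npz`` archive."""
    from .features import group_map

    meta = {
        "config_hash": config_hash,
        "theta_bg": cascade.theta_bg,
        "group_map": {k: list(v) for k, v in group_map().items()},
        "entries": [],
        "has_background": cascade.background_model is not None,
    }
    arrays: dict[str, np.ndarray] = {}

    def pack(model: TaxonModel, key: str) -> dict:
        arrays[f"{key}__sv"] = model.support_vectors
        arrays[f"{key}__dual"] = model.dual_coef
        if model.normalizer is not None:
            arrays[f"{key}__norm_mean"] = model.normalizer.mean
            arrays[f"{key}__norm_std"] = model.normalizer.std
        return {
            "taxon": model.taxon, "C": model.C, "gamma": model.gamma,
            "intercept": model.intercept, "platt_a": model.platt_a,
            "platt_b": model.platt_b, "cv_se": model.cv_se,
            "cv_ppv": model.cv_ppv,
            "has_normalizer": model.normalizer is not None,
        }

    for entry in cascade.entries:
        spec = pack(entry.model, entry.model.taxon)
        spec["theta"] = entry.theta
        spec["s_min"] = entry.s_min
        meta["entries"].append(spec)
    if cascade.background_model is not None:
        meta["background"] = pack(cascade.background_model, BACKGROUND)

    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)


def load_cascade(path) -> tuple[CascadeTree, str]:
    """Load a cascade archive; returns (cascade, config hash)."""
    from .training import NormalizationModel

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))

        def unpack(spec: dict, key: str) -> TaxonModel:
            norm = None
            if spec["has_normalizer"]:
                norm = NormalizationModel(
                    mean=data[f"{key}__norm_mean"],
                    std=data[f"{key}__norm_std"],
                    groups={k: tuple(v)
                            for k, v in meta["group_map"].items()},
                )
            return TaxonModel(
                taxon=spec["taxon"], C=spec["C"], gamma=spec["gamma"],
                support_vectors=data[f"{key}__sv"],
                dual_coef=data[f"{key}__dual"],
                intercept=spec["intercept"], platt_a=spec["platt_a"],
                platt_b=spec["platt_b"], normalizer=norm,
                cv_se=spec["cv_se"], cv_ppv=spec["cv_ppv"],
            )

        entries = [
            CascadeEntry(model=unpack(spec, spec["taxon"]),
                         theta=spec["theta"], s_min=spec["s_min"])
            for spec in meta["entries"]
        ]
        bg = (unpack(meta["background"], BACKGROUND)
              if meta["has_background"] else None)
    tree = CascadeTree(entries=entries, background_model=bg,
                       theta_bg=meta["theta_bg"])
    return tree, meta["config_hash"]


#: Default color legend for classification maps (RGB); background is
#: rendered sand-gray, rejected pixels black, unvisited dark gray.
DEFAULT_PALETTE = (
    (230, 25, 75), (60, 180, 75), (0, 130, 200), (255, 225, 25),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (128, 128, 0), (250, 190, 190),
)


def classification_map_image(fc: FieldClassification,
                             palette: Sequence[tuple] = DEFAULT_PALETTE
                             ) -> np.ndarray:
    """Render a classification map as an RGB image with a fixed legend."""
    h, w = fc.class_map.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    out[fc.class_map == -2] = (40, 40, 40)       # unvisited (margin)
    for taxon, code in fc.class_codes.items():
        if taxon == BACKGROUND:
            color = (180, 165, 140)
        else:
            color = palette[code % len(palette)]
        out[fc.class_map == code] = color
    return out


def save_classification_map(fc: FieldClassification, path,
                            palette: Sequence[tuple] = DEFAULT_PALETTE
                            ) -> None:
    from skimage.io import imsave

    imsave(path, classification_map_image(fc, palette), check_contrast=False)
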