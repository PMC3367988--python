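"""Synthetic seafloor transect generator.

Produces the three ingredients the detection pipeline consumes, with exact
ground truth and no external data: (i) sediment-textured images with a
radial lightness falloff (vignette) and planted objects of eight visually
distinct morphotype classes at sparse densities, (ii) per-image ground-truth
object positions, and (iii) simulated multi-expert point labels with
positional jitter, per-class miss rates, class confusions and occasional
false alarms, so that conspicuous classes reach high inter-observer
agreement while cryptic classes stay low.

Class archetypes loosely follow common deep-sea morphotypes: discs
(anemones, small sponges, cryptic holothurians), stars (large holothurians,
crinoid crowns), stalks, and dark ring-like burrow openings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import PositionLabel
from .config import BACKGROUND

TRUTH_COLUMNS = ["image_id", "taxon", "x", "y", "size"]


@dataclass(frozen=True)
class ObjectClassSpec:
    """One planted object class.

    ``mean_count`` is the expected number of objects per image (the sparse
    regime spans roughly 0.5-16 per image across classes).  ``radius`` is
    the half-size range in pixels; for stalks it is half the stalk length.
    """

    name: str
    archetype: str  # disc | star | stalk | ring
    mean_count: float
    radius: tuple[float, float]
    color: tuple[float, float, float]
    arm_count: int = 0
    arm_amp: float = 0.0
    opacity: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Scene geometry, background texture, vignette, and object classes."""

    width: int = 600
    height: int = 500
    base_color: tuple[float, float, float] = (112.0, 101.0, 88.0)
    noise_scales: tuple[float, ...] = (40.0, 12.0, 2.0)
    noise_amps: tuple[float, ...] = (10.0, 6.0, 4.0)
    vignette_strength: float = 0.55
    vignette_power: float = 2.0
    classes: tuple[ObjectClassSpec, ...] = ()
    min_separation: float = 6.0
    placement_retries: int = 200

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]


@dataclass(frozen=True)
class AnnotatorSpec:
    """Behavior of one simulated expert.

    Each true object is labeled with probability ``1 - miss[class]``, at the
    true position plus isotropic Gaussian jitter, with the class possibly
    swapped according to ``confusion``.  ``false_alarm_rate`` is the expected
    number of spurious labels per image (class drawn uniformly).
    """

    annotator_id: str
    jitter_sigma: float = 2.0
    miss: Mapping[str, float] = field(default_factory=dict)
    confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    false_alarm_rate: float = 0.3


# Conspicuousness tiers used for the default annotator behavior: easily
# spotted classes are missed almost never; cryptic ones about half the time.
CONSPICUOUS_CLASSES = ("holothurian_white", "anemone_purple", "anemone_white")
MIDRANGE_CLASSES = ("crinoid_crown", "crinoid_stalk", "burrow")
CRYPTIC_CLASSES = ("sponge_small", "holothurian_cryptic")

_DEFAULT_MISS = {
    "holothurian_white": 0.02,
    "anemone_purple": 0.04,
    "anemone_white": 0.03,
    "crinoid_crown": 0.18,
    "crinoid_stalk": 0.30,
    "burrow": 0.15,
    "sponge_small": 0.50,
    "holothurian_cryptic": 0.52,
}

_DEFAULT_CONFUSION = {
    "sponge_small": {"holothurian_cryptic": 0.08},
    "holothurian_cryptic": {"sponge_small": 0.08},
    "crinoid_crown": {"crinoid_stalk": 0.03},
}

#: False alarms are drawn from the ambiguous classes only: experts mistake
#: sediment features for cryptic or mid-range morphotypes, not for large
#: conspicuous animals.
_FALSE_ALARM_CLASSES = MIDRANGE_CLASSES + CRYPTIC_CLASSES

#: Default per-class linear density profiles (factor at transect start, end);
#: expected counts vary smoothly along the image sequence.
DEFAULT_GRADIENTS = {
    "holothurian_white": (1.6, 0.4),
    "anemone_purple": (0.6, 1.4),
    "anemone_white": (0.3, 1.7),
    "crinoid_crown": (1.0, 1.0),
    "crinoid_stalk": (0.7, 1.3),
    "burrow": (1.3, 0.7),
    "sponge_small": (1.0, 1.0),
    "holothurian_cryptic": (1.2, 0.8),
}


def default_scene_spec(width: int = 600, height: int = 500) -> SceneSpec:
    """The default eight-class scene emulating a deep-sea photo transect."""
    classes = (
        ObjectClassSpec("holothurian_white", "star", 1.5, (10.0, 14.0),
                        (236.0, 226.0, 218.0), arm_count=10, arm_amp=0.12),
        ObjectClassSpec("anemone_purple", "disc", 2.5, (6.0, 9.0),
                        (158.0, 84.0, 168.0)),
        ObjectClassSpec("anemone_white", "disc", 6.0, (5.0, 7.0),
                        (238.0, 238.0, 234.0)),
        ObjectClassSpec("crinoid_crown", "star", 3.0, (8.0, 11.0),
                        (196.0, 188.0, 172.0), arm_count=5, arm_amp=0.45),
        ObjectClassSpec("crinoid_stalk", "stalk", 4.0, (12.0, 17.0),
                        (208.0, 200.0, 186.0)),
        ObjectClassSpec("burrow", "ring", 12.0, (6.0, 9.0),
                        (42.0, 38.0, 34.0)),
        ObjectClassSpec("sponge_small", "disc", 2.5, (3.0, 4.5),
                        (168.0, 158.0, 138.0), opacity=0.8),
        ObjectClassSpec("holothurian_cryptic", "disc", 3.0, (3.5, 5.0),
                        (134.0, 120.0, 102.0), opacity=0.85),
    )
    return SceneSpec(width=width, height=height, classes=classes)


def default_annotators(n: int = 5) -> list[AnnotatorSpec]:
    """Five simulated experts with mildly heterogeneous behavior."""
    sigmas = [1.8, 2.0, 2.2, 2.0, 2.6]
    miss_shift = [0.0, 0.0, 0.02, -0.01, 0.04]
    out = []
    for i in range(n):
        miss = {c: float(np.clip(m + miss_shift[i % 5], 0.0, 0.95))
                for c, m in _DEFAULT_MISS.items()}
        out.append(AnnotatorSpec(
            annotator_id=f"expert{i + 1}",
            jitter_sigma=sigmas[i % 5],
            miss=miss,
            confusion=_DEFAULT_CONFUSION,
            false_alarm_rate=0.3,
        ))
    return out


# ---------------------------------------------------------------------------
# image synthesis


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Correlated-noise sediment texture (float, pre-vignette)."""
    h, w = spec.height, spec.width
    canvas = np.empty((h, w, 3), dtype=np.float64)
    base = np.asarray(spec.base_color)
    lum = np.zeros((h, w))
    for scale, amp in zip(spec.noise_scales, spec.noise_amps):
        raw = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(raw, scale, mode="reflect")
        std = smooth.std()
        if std > 0:
            lum += amp * smooth / std
    # mild independent per-channel grain so channels decorrelate slightly
    for c in range(3):
        grain = rng.standard_normal((h, w)) * 1.5
        canvas[..., c] = base[c] + lum + grain
    return canvas


def _vignette_profile(spec: SceneSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_max = np.hypot(cy, cx)
    return 1.0 - spec.vignette_strength * (r / r_max) ** spec.vignette_power


def _object_alpha(cls: ObjectClassSpec, radius: float, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Soft opacity mask for one object on a (size x size) local canvas."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    edge = 1.5

    if cls.archetype == "disc":
        alpha = np.clip((radius - r) / edge + 0.5, 0.0, 1.0)
    elif cls.archetype == "star":
        phase = rng.uniform(0, 2 * np.pi)
        r0 = radius * (1.0 + cls.arm_amp * np.cos(cls.arm_count * theta + phase))
        alpha = np.clip((r0 - r) / edge + 0.5, 0.0, 1.0)
    elif cls.archetype == "stalk":
        phi = rng.uniform(0, np.pi)
        ux, uy = np.cos(phi), np.sin(phi)
        along = dx * ux + dy * uy
        across = -dx * uy + dy * ux
        half_len = radius
        width = rng.uniform(1.2, 2.0)
        d_along = np.maximum(np.abs(along) - half_len, 0.0)
        d = np.hypot(d_along, across)
        alpha = np.clip((width - d) / 1.0 + 0.5, 0.0, 1.0)
    elif cls.archetype == "ring":
        # dark opening with a soft, slightly raised rim
        hole = np.clip((0.65 * radius - r) / edge + 0.5, 0.0, 1.0)
        alpha = hole
    else:  # pragma: no cover - guarded by spec construction
        raise ValueError(f"unknown archetype {cls.archetype!r}")

    # low-amplitude interior texture so objects are not flat
    speckle = ndimage.gaussian_filter(rng.standard_normal((size, size)), 1.0)
    alpha = alpha * np.clip(1.0 + 0.08 * speckle, 0.0, None)
    return np.clip(alpha, 0.0, 1.0) * cls.opacity


def _paint_object(canvas: np.ndarray, cls: ObjectClassSpec, x: int, y: int,
                  radius: float, rng: np.random.Generator) -> None:
    size = int(np.ceil(2 * radius + 8)) | 1
    alpha = _object_alpha(cls, radius, size, rng)
    color = np.asarray(cls.color) * rng.uniform(0.9, 1.1)
    if cls.archetype == "ring":
        # lightened rim around the dark opening
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(yy - c, xx - c)
        rim = np.clip(1.0 - np.abs(r - 0.85 * radius) / (0.35 * radius), 0, 1)
        rim_color = np.asarray([150.0, 138.0, 120.0])
    half = (size - 1) // 2
    h, w = canvas.shape[:2]
    y0, y1 = y - half, y + half + 1
    x0, x1 = x - half, x + half + 1
    sy0, sx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(h, y1), min(w, x1)
    a = alpha[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0), None]
    region = canvas[y0:y1, x0:x1]
    region[:] = (1 - a) * region + a * color
    if cls.archetype == "ring":
        rm = rim[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0), None] * 0.5
        region[:] = (1 - rm) * region + rm * rim_color


def generate_image(
    spec: SceneSpec,
    seed: int | np.random.SeedSequence,
    image_id: str = "img000",
    count_factors: Mapping[str, float] | None = None,
    counts: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one synthetic seafloor frame and its ground truth.

    Object counts are Poisson around each class's ``mean_count`` (scaled by
    ``count_factors``) unless fixed explicitly via ``counts``.  Objects are
    placed without overlap by rejection sampling; if placement fails after
    the retry budget, fewer objects are planted (with a warning).

    Returns the uint8 RGB image and a truth table with columns
    ``image_id, taxon, x, y, size``.
    """
    rng = np.random.default_rng(seed)
    canvas = _background(spec, rng)

    placed: list[tuple[float, float, float]] = []  # x, y, radius
    truth_rows: list[tuple] = []
    h, w = spec.height, spec.width

    for cls in spec.classes:
        if counts is not None and cls.name in counts:
            n = int(counts[cls.name])
        else:
            factor = 1.0 if count_factors is None else count_factors.get(cls.name, 1.0)
            n = int(rng.poisson(cls.mean_count * max(factor, 0.0)))
        for _ in range(n):
            radius = rng.uniform(*cls.radius)
            margin = radius + 6
            ok = False
            for _attempt in range(spec.placement_retries):
                x = rng.uniform(margin, w - 1 - margin)
                y = rng.uniform(margin, h - 1 - margin)
                if all(np.hypot(x - px, y - py) >= radius + pr + spec.min_separation
                       for px, py, pr in placed):
                    ok = True
                    break
            if not ok:
                warnings.warn(
                    f"{image_id}: could not place all {cls.name} objects "
                    "without overlap; planting fewer", stacklevel=2)
                continue
            xi, yi = int(round(x)), int(round(y))
            _paint_object(canvas, cls, xi, yi, radius, rng)
            placed.append((xi, yi, radius))
            truth_rows.append((image_id, cls.name, xi, yi, radius))

    canvas *= _vignette_profile(spec)[..., None]
    image = np.clip(canvas, 0, 255).round().astype(np.uint8)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return image, truth


# ---------------------------------------------------------------------------
# transect and annotator simulation


@dataclass
class TransectDataset:
    """A generated image sequence with ground truth."""

    spec: SceneSpec
    images: dict[str, np.ndarray]
    truth: pd.DataFrame

    @property
    def image_ids(self) -> list[str]:
        return list(self.images)


def generate_transect(
    n_images: int = 70,
    spec: SceneSpec | None = None,
    gradients: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> TransectDataset:
    """Generate an ordered image sequence with smoothly varying densities.

    Per-class expected counts follow linear profiles along the sequence
    (``gradients`` maps class name to (start factor, end factor)), which
    exercises the per-image count-correlation evaluation downstream.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec = spec or default_scene_spec()
    if gradients is None:
        gradients = {c: DEFAULT_GRADIENTS.get(c, (1.0, 1.0))
                     for c in spec.class_names()}
    root = np.random.SeedSequence(entropy=seed)
    child_seeds = root.spawn(n_images)

    images: dict[str, np.ndarray] = {}
    truth_parts = []
    for i in range(n_images):
        t = i / max(n_images - 1, 1)
        factors = {
            c: g[0] + (g[1] - g[0]) * t
            for c, g in gradients.items()
        }
        image_id = f"img{i:03d}"
        img, truth = generate_image(spec, child_seeds[i], image_id=image_id,
                                    count_factors=factors)
        images[image_id] = img
        truth_parts.append(truth)
    truth = pd.concat(truth_parts, ignore_index=True)
    return TransectDataset(spec=spec, images=images, truth=truth)


def simulate_annotators(
    truth: pd.DataFrame,
    annotators: Sequence[AnnotatorSpec],
    spec: SceneSpec,
    sessions: int = 2,
    seed: int = 0,
    session_image_fraction: float = 0.5,
) -> list[PositionLabel]:
    """Simulate expert point labeling of the ground truth.

    Session 1 covers every image; later sessions (re-labeling after a break)
    cover the first ``session_image_fraction`` of the images.  Class names
    double as taxon names.  Returns labels for all annotators and sessions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 910)))
    class_names = spec.class_names()
    image_ids = sorted(truth["image_id"].unique())
    n_relabel = max(1, int(round(session_image_fraction * len(image_ids))))
    labels: list[PositionLabel] = []

    for ann in annotators:
        for s in range(1, sessions + 1):
            session_id = f"s{s}"
            covered = image_ids if s == 1 else image_ids[:n_relabel]
            covered_set = set(covered)
            for row in truth.itertuples(index=False):
                if row.image_id not in covered_set:
                    continue
                if rng.random() < ann.miss.get(row.taxon, 0.0):
                    continue
                taxon = row.taxon
                conf = ann.confusion.get(taxon, {})
                u = rng.random()
                acc = 0.0
                for other, p in conf.items():
                    acc += p
                    if u < acc:
                        taxon = other
                        break
                x = row.x + rng.normal(0, ann.jitter_sigma)
                y = row.y + rng.normal(0, ann.jitter_sigma)
                x = float(np.clip(x, 0, spec.width - 1))
                y = float(np.clip(y, 0, spec.height - 1))
                labels.append(PositionLabel(row.image_id, ann.annotator_id,
                                            session_id, taxon, x, y))
            # false alarms, uniformly placed, drawn from ambiguous classes
            fa_classes = [c for c in class_names
                          if c in _FALSE_ALARM_CLASSES] or class_names
            for image_id in covered:
                n_fa = rng.poisson(ann.false_alarm_rate)
                for _ in range(n_fa):
                    labels.append(PositionLabel(
                        image_id, ann.annotator_id, session_id,
                        fa_classes[int(rng.integers(len(fa_classes)))],
                        float(rng.uniform(0, spec.width - 1)),
                        float(rng.uniform(0, spec.height - 1)),
                    ))
    return labels


def sample_background_truth(
    truth: pd.DataFrame,
    spec: SceneSpec,
    n_per_image: int,
    min_distance: float,
    seed: int = 0,
) -> list[PositionLabel]:
    """Uniform background reference positions away from all true objects.

    Convenience for experiments that need labeled background points with
    guaranteed clearance from planted objects (ground truth, not simulated
    expert behavior).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 911)))
    labels: list[PositionLabel] = []
    for image_id, group in truth.groupby("image_id"):
        pos = group[["x", "y"]].to_numpy(dtype=float)
        placed = 0
        attempts = 0
        cap = 200 * n_per_image
        while placed < n_per_image and attempts < cap:
            attempts += 1
            x = rng.uniform(16, spec.width - 17)
            y = rng.uniform(16, spec.height - 17)
            if pos.size and np.min(np.hypot(pos[:, 0] - x, pos[:, 1] - y)) < min_distance:
                continue
            labels.append(PositionLabel(str(image_id), "truth", "s1",
                                        BACKGROUND, float(x), float(y)))
            placed += 1
    return labels
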