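"""Per-taxon SVM training: set composition, normalization, tuning.

For every taxon (and for the background class) a binary RBF-SVM is trained
on a balanced feature set: 50% positive samples and 50% negatives, the
negatives split half background / half equal shares of the other taxa.
Positive positions are boosted five-fold by adding the four 4-connected
neighbors at two-pixel offset.  Hyperparameters (C, gamma) are tuned by
logarithmically sampled grid search under 4-fold cross-validation,
selecting the pair with the best test-fold PPV (ties: SE, then smaller C);
a Platt-style sigmoid maps decision values to [0, 1] confidences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.svm import SVC

from .annotations import GoldLabel, PositionLabel
from .config import BACKGROUND
from .features import group_map


# ---------------------------------------------------------------------------
# performance measures


def se_ppv(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and positive predictive value TP/(TP+FP).

    A measure with zero denominator is undefined and reported as NaN.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    se = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return se, ppv


# ---------------------------------------------------------------------------
# training positions


def boost_positions(
    gold: Sequence[GoldLabel],
    offset: int = 2,
    image_shapes: Mapping[str, tuple[int, int]] | None = None,
) -> list[tuple[str, str, int, int, int]]:
    """Five positions per gold label: the label and its offset neighbors.

    For a label at (x, y) emits (x, y), (x±offset, y), (x, y±offset).
    Offsets falling outside the image (when ``image_shapes`` maps image_id
    to (height, width)) are clipped out with a warning.  Returns tuples
    ``(image_id, taxon, x, y, origin_index)`` where ``origin_index``
    identifies the source label (used to keep all five variants of one
    label in the same cross-validation fold).
    """
    out = []
    clipped = 0
    for idx, g in enumerate(gold):
        x, y = int(round(g.x)), int(round(g.y))
        candidates = [(x, y), (x + offset, y), (x - offset, y),
                      (x, y + offset), (x, y - offset)]
        for cx, cy in candidates:
            if image_shapes is not None and g.image_id in image_shapes:
                h, w = image_shapes[g.image_id]
                if not (0 <= cx < w and 0 <= cy < h):
                    clipped += 1
                    continue
            out.append((g.image_id, g.taxon, cx, cy, idx))
    if clipped:
        warnings.warn(f"clipped {clipped} boosted positions at the border",
                      stacklevel=2)
    return out


def sample_background(
    image_ids: Sequence[str],
    labels: Sequence[PositionLabel],
    image_shape: tuple[int, int],
    n_per_image: int = 68,
    min_distance: float = 40.0,
    seed: int = 0,
    retry_factor: int = 200,
) -> list[tuple[str, int, int]]:
    """Random background positions away from every human label.

    Uniform rejection sampling within each image; every returned position
    is at Euclidean distance >= ``min_distance`` from all human labels of
    that image.  If the retry cap is hit, fewer samples are returned with a
    warning.  Deterministic under ``seed``.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    h, w = image_shape
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 407)))
    by_image: dict[str, list[tuple[float, float]]] = {i: [] for i in image_ids}
    for lab in labels:
        if lab.image_id in by_image:
            by_image[lab.image_id].append((lab.x, lab.y))

    out: list[tuple[str, int, int]] = []
    for image_id in image_ids:
        pts = np.asarray(by_image[image_id], dtype=float).reshape(-1, 2)
        placed = 0
        attempts = 0
        cap = retry_factor * n_per_image
        while placed < n_per_image and attempts < cap:
            attempts += 1
            x = int(rng.integers(0, w))
            y = int(rng.integers(0, h))
            if pts.size and np.min(np.hypot(pts[:, 0] - x, pts[:, 1] - y)) < min_distance:
                continue
            out.append((image_id, x, y))
            placed += 1
        if placed < n_per_image:
            warnings.warn(
                f"{image_id}: placed only {placed}/{n_per_image} background "
                "samples within the retry cap", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationModel:
    """Per-feature standardization fitted on training data.

    Features are organized in domain groups; the group map is retained so
    persisted models document which span belongs to which descriptor
    family.  Zero-variance features map to 0.
    """

    mean: np.ndarray
    std: np.ndarray
    groups: dict[str, tuple[int, int]] = field(default_factory=group_map)

    def apply(self, features: np.ndarray) -> np.ndarray:
        safe = np.where(self.std > 0, self.std, 1.0)
        out = (features - self.mean) / safe
        out[:, self.std == 0] = 0.0
        return out.astype(np.float32)


def fit_normalizer(features: np.ndarray,
                   groups: dict[str, tuple[int, int]] | None = None
                   ) -> NormalizationModel:
    """Fit per-feature mean/std (grouped bookkeeping; see methods note)."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the normalizer")
    return NormalizationModel(
        mean=features.mean(axis=0),
        std=features.std(axis=0),
        groups=groups or group_map(),
    )


def apply_normalizer(model: NormalizationModel,
                     features: np.ndarray) -> np.ndarray:
    return model.apply(np.asarray(features, dtype=np.float64))


# ---------------------------------------------------------------------------
# training-set composition


@dataclass
class TrainingSet:
    """Balanced binary training set for one taxon.

    ``provenance`` records each row's origin (``taxon:<name>``,
    ``background`` or ``other:<name>``); ``fold_groups`` ties boosted
    variants of one source label together for leakage-free folding.
    """

    taxon: str
    X: np.ndarray
    y: np.ndarray
    provenance: list[str]
    fold_groups: np.ndarray

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.y == 1))


@dataclass
class FeaturePool:
    """Feature rows for one class with per-row fold-group ids."""

    features: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features)
        if self.groups is None:
            self.groups = np.arange(len(self.features))
        self.groups = np.asarray(self.groups)

    def __len__(self) -> int:
        return len(self.features)


def _draw(pool: FeaturePool, n: int, rng: np.random.Generator,
          what: str) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=int)
    if len(pool) >= n:
        return rng.choice(len(pool), size=n, replace=False)
    warnings.warn(f"{what}: pool of {len(pool)} sampled with replacement "
                  f"to reach {n} rows", stacklevel=3)
    return rng.choice(len(pool), size=n, replace=True)


def compose_training_set(
    taxon: str,
    pools: Mapping[str, FeaturePool],
    seed: int = 0,
) -> TrainingSet:
    """Assemble the balanced 50/50 feature set for one taxon.

    Positives are all rows of ``pools[taxon]``.  Negatives match the
    positive count: half drawn from the background pool, half split in
    equal shares (±1 row) over the other taxa.  For the background class
    itself the negatives are an equal mix of all taxa.  Sampling is
    without replacement where pools allow, seeded and deterministic.
    """
    if taxon not in pools or len(pools[taxon]) == 0:
        raise ValueError(f"no positive samples for {taxon!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 701)))
    pos_pool = pools[taxon]
    n_pos = len(pos_pool)

    others = sorted(t for t in pools
                    if t not in (taxon, BACKGROUND) and len(pools[t]) > 0)
    if taxon == BACKGROUND:
        n_bg = 0
    else:
        if BACKGROUND not in pools or len(pools[BACKGROUND]) == 0:
            raise ValueError("background pool is empty")
        n_bg = n_pos // 2
    if not others:
        raise ValueError("need at least one other-taxon pool")

    n_other_total = n_pos - (n_bg if taxon != BACKGROUND else 0)
    base, rem = divmod(n_other_total, len(others))
    # deterministic assignment of the remainder
    extras = rng.permutation(len(others))[:rem]
    shares = {t: base + int(i in extras) for i, t in enumerate(others)}

    X_parts = [pos_pool.features]
    prov = [f"taxon:{taxon}"] * n_pos
    group_parts = [np.char.add("pos_", pos_pool.groups.astype(str))]

    if taxon != BACKGROUND and n_bg:
        idx = _draw(pools[BACKGROUND], n_bg, rng, f"{taxon}/background")
        X_parts.append(pools[BACKGROUND].features[idx])
        prov += [BACKGROUND] * n_bg
        group_parts.append(
            np.char.add("bg_", pools[BACKGROUND].groups[idx].astype(str)))
    for t in others:
        idx = _draw(pools[t], shares[t], rng, f"{taxon}/{t}")
        X_parts.append(pools[t].features[idx])
        prov += [f"other:{t}"] * shares[t]
        group_parts.append(
            np.char.add(f"{t}_", pools[t].groups[idx].astype(str)))

    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate([np.ones(n_pos, dtype=int),
                        np.zeros(len(X) - n_pos, dtype=int)])
    fold_groups = np.concatenate(group_parts)
    return TrainingSet(taxon=taxon, X=X.astype(np.float32), y=y,
                       provenance=prov, fold_groups=fold_groups)


# ---------------------------------------------------------------------------
# SVM tuning, training, calibration


@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    cv_se: float
    cv_ppv: float
    table: list[dict]


def _cv_counts(X, y, groups, C, gamma, folds, seed):
    tp = fp = fn = 0
    skf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y, groups):
        if len(np.unique(y[train_idx])) < 2:  # pragma: no cover - guarded
            continue
        clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=200)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, fn


def tune_svm(
    training_set: TrainingSet,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    folds: int = 4,
    seed: int = 0,
) -> GridSearchResult:
    """Grid search (C, gamma) under stratified group 4-fold CV.

    Selection maximizes the precision-weighted F-score (F_0.5) of the
    pooled test folds — PPV carries double weight, reflecting that false
    positives on unseen data are the primary concern — with ties broken by
    higher PPV, then smaller C, then smaller gamma.  (A strictly
    lexicographic PPV-first rule degenerates: it prefers an overfit corner
    of the grid with near-zero sensitivity whenever that corner gains the
    last fraction of a PPV percent.)  Boosted variants of a label share a
    fold (group-aware folding).
    """
    C_grid = list(C_grid if C_grid is not None
                  else [10.0 ** e for e in range(-3, 4)])
    gamma_grid = list(gamma_grid if gamma_grid is not None
                      else [10.0 ** e for e in range(-4, 3)])
    if not C_grid or not gamma_grid:
        raise ValueError("parameter grids must be non-empty")

    X, y, groups = training_set.X, training_set.y, training_set.fold_groups
    table = []
    best = None
    best_key = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            tp, fp, fn = _cv_counts(X, y, groups, C, gamma, folds, seed)
            se, ppv = se_ppv(tp, fp, fn)
            se_c = 0.0 if np.isnan(se) else se
            ppv_c = 0.0 if np.isnan(ppv) else ppv
            f05 = (1.25 * ppv_c * se_c / (0.25 * ppv_c + se_c)
                   if (ppv_c + se_c) > 0 else 0.0)
            table.append({"C": C, "gamma": gamma, "se": se, "ppv": ppv,
                          "f05": f05})
            key = (-f05, -ppv_c, C, gamma)
            if best_key is None or key < best_key:
                best_key = key
                best = (C, gamma, se, ppv)
    C, gamma, se, ppv = best
    return GridSearchResult(best_C=C, best_gamma=gamma, cv_se=se,
                            cv_ppv=ppv, table=table)


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid P(y=1|f) = 1/(1+exp(A f + B)) with Platt's targets."""
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0),
                 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        # p = 1/(1+exp(z)); NLL = sum lse(z) - (1-t) z, stable via logaddexp
        lse = np.logaddexp(0.0, z)
        return float(np.sum(lse - (1.0 - t) * z))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="L-BFGS-B")
    a, b = res.x
    return float(a), float(b)


@dataclass
class TaxonModel:
    """A trained per-taxon classifier with calibration and normalization."""

    taxon: str
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    normalizer: NormalizationModel | None = None
    cv_se: float = float("nan")
    cv_ppv: float = float("nan")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """RBF decision function evaluated with BLAS-backed kernels."""
        X = np.asarray(X, dtype=np.float32)
        sv = np.asarray(self.support_vectors, dtype=np.float32)
        d2 = ((X ** 2).sum(axis=1)[:, None] + (sv ** 2).sum(axis=1)[None, :]
              - 2.0 * (X @ sv.T)).astype(np.float64)
        np.maximum(d2, 0.0, out=d2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Calibrated confidence in [0, 1] (Platt sigmoid)."""
        f = self.decision_values(X)
        return 1.0 / (1.0 + np.exp(np.clip(self.platt_a * f + self.platt_b,
                                           -500, 500)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) > 0).astype(int)


def cv_decision_values(
    training_set: TrainingSet, C: float, gamma: float,
    folds: int = 4, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold decision values at fixed (C, gamma).

    The preferred input for Platt calibration: unlike decision values on
    the fit data itself (saturated for separable sets), out-of-fold values
    reflect how decisions look on unseen samples.
    """
    X, y, groups = training_set.X, training_set.y, training_set.fold_groups
    decision = np.empty(len(y))
    filled = np.zeros(len(y), dtype=bool)
    skf = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                               random_state=seed)
    for train_idx, test_idx in skf.split(X, y, groups):
        if len(np.unique(y[train_idx])) < 2:
            continue  # degenerate fold on a tiny set; filled below
        clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=200)
        clf.fit(X[train_idx], y[train_idx])
        decision[test_idx] = clf.decision_function(X[test_idx])
        filled[test_idx] = True
    if not filled.all():
        clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=200)
        clf.fit(X, y)
        decision[~filled] = clf.decision_function(X[~filled])
    return decision, y.copy()


def train_taxon_model(
    training_set: TrainingSet,
    C: float,
    gamma: float,
    normalizer: NormalizationModel | None = None,
    cv_se: float = float("nan"),
    cv_ppv: float = float("nan"),
    calibration: tuple[np.ndarray, np.ndarray] | None = None,
) -> TaxonModel:
    """Final SVM fit on the full set, plus Platt calibration.

    ``calibration`` optionally supplies (decision values, targets) to fit
    the sigmoid on (e.g. from :func:`cv_decision_values`); by default the
    sigmoid is fitted on the training decisions.
    """
    X, y = training_set.X.astype(np.float64), training_set.y
    clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=200)
    clf.fit(X, y)
    if clf.fit_status_ != 0:  # pragma: no cover - libsvm rarely fails
        raise RuntimeError(
            f"SVM training failed for {training_set.taxon!r} "
            f"(C={C}, gamma={gamma}, status={clf.fit_status_})")
    if calibration is not None:
        a, b = _platt_fit(np.asarray(calibration[0]),
                          np.asarray(calibration[1]))
    else:
        a, b = _platt_fit(clf.decision_function(X), y)
    return TaxonModel(
        taxon=training_set.taxon,
        C=C, gamma=gamma,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        platt_a=a, platt_b=b,
        normalizer=normalizer,
        cv_se=cv_se, cv_ppv=cv_ppv,
    )
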