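"""Evaluation against the gold standard.

Detections are matched one-to-one to gold-standard positions per taxon
(greedy nearest-first within a taxon-specific distance); matched pairs are
true positives, unmatched detections false positives, unmatched gold
labels false negatives.  From the counts: per-taxon SE/PPV, micro-averaged
totals, per-image count correlations, supporter-threshold sweeps, and a
false-positive review-queue export whose returned verdicts update SE/PPV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GoldLabel, build_gold_standard
from .config import BACKGROUND, TaxonSet
from .detection import DetectionResult
from .training import se_ppv

#: Review verdict categories; only "true_positive" flips an FP to a TP.
VERDICT_CATEGORIES = (
    "true_positive", "rejected", "misclassification",
    "untrained_taxon", "background", "unknown",
)


@dataclass
class MatchOutcome:
    """Matching result between gold labels and detections."""

    counts: dict[str, dict[str, int]]            # taxon -> {tp, fp, fn}
    detection_status: pd.DataFrame               # one row per detection
    gold_status: pd.DataFrame                    # one row per gold label

    def taxon_counts(self, taxon: str) -> tuple[int, int, int]:
        c = self.counts.get(taxon, {"tp": 0, "fp": 0, "fn": 0})
        return c["tp"], c["fp"], c["fn"]

    def pooled(self, exclude: Sequence[str] = ()) -> tuple[int, int, int]:
        tp = fp = fn = 0
        for taxon, c in self.counts.items():
            if taxon in exclude:
                continue
            tp, fp, fn = tp + c["tp"], fp + c["fp"], fn + c["fn"]
        return tp, fp, fn


def match_detections(
    gold: Sequence[GoldLabel],
    detections: Sequence[DetectionResult],
    taxa: TaxonSet,
) -> MatchOutcome:
    """Greedy nearest-first one-to-one matching within taxon and distance.

    Background gold labels are not detection targets and are ignored.
    """
    gold = [g for g in gold if g.taxon != BACKGROUND]
    det_rows = []
    for res in detections:
        for b in res.detections:
            det_rows.append((res.image_id, b.taxon, b.centroid[0],
                             b.centroid[1], b.size, b.confidence))
    det = pd.DataFrame(
        det_rows,
        columns=["image_id", "taxon", "x", "y", "size", "confidence"],
    )
    det["status"] = "FP"
    gold_df = pd.DataFrame(
        [(g.image_id, g.taxon, g.x, g.y, g.k) for g in gold],
        columns=["image_id", "taxon", "x", "y", "k"],
    )
    gold_df["status"] = "FN"

    taxa_seen = sorted(
        set(gold_df["taxon"]) | set(det["taxon"]) if len(det) or len(gold_df)
        else set()
    )
    counts = {t: {"tp": 0, "fp": 0, "fn": 0} for t in taxa_seen}

    for (image_id, taxon), gidx in gold_df.groupby(
            ["image_id", "taxon"]).groups.items():
        didx = det.index[(det["image_id"] == image_id)
                         & (det["taxon"] == taxon)]
        gxy = gold_df.loc[gidx, ["x", "y"]].to_numpy(float)
        dxy = det.loc[didx, ["x", "y"]].to_numpy(float)
        if not len(didx):
            continue
        dmat = np.hypot(gxy[:, 0, None] - dxy[None, :, 0],
                        gxy[:, 1, None] - dxy[None, :, 1])
        pairs = [(dmat[i, j], i, j)
                 for i in range(dmat.shape[0]) for j in range(dmat.shape[1])
                 if dmat[i, j] <= taxa[taxon].match_distance]
        pairs.sort()
        used_g, used_d = set(), set()
        for _, i, j in pairs:
            if i in used_g or j in used_d:
                continue
            used_g.add(i)
            used_d.add(j)
            gold_df.loc[gidx[i], "status"] = "TP"
            det.loc[didx[j], "status"] = "TP"

    for t in taxa_seen:
        counts[t]["tp"] = int(((det["taxon"] == t)
                               & (det["status"] == "TP")).sum())
        counts[t]["fp"] = int(((det["taxon"] == t)
                               & (det["status"] == "FP")).sum())
        counts[t]["fn"] = int(((gold_df["taxon"] == t)
                               & (gold_df["status"] == "FN")).sum())

    return MatchOutcome(counts=counts, detection_status=det,
                        gold_status=gold_df)


def count_correlation(
    gold_counts: Mapping[str, int] | Sequence[float],
    machine_counts: Mapping[str, int] | Sequence[float],
    method: str = "pearson",
) -> float:
    """Correlation between per-image gold and machine object counts.

    Returns NaN for degenerate (zero-variance) series.
    """
    g = np.asarray(list(gold_counts.values())
                   if isinstance(gold_counts, Mapping) else gold_counts,
                   dtype=float)
    m = np.asarray(list(machine_counts.values())
                   if isinstance(machine_counts, Mapping) else machine_counts,
                   dtype=float)
    if len(g) != len(m) or len(g) < 2:
        raise ValueError("need two aligned series of length >= 2")
    if g.std() == 0 or m.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(g, m).statistic)
    if method == "spearman":
        return float(stats.spearmanr(g, m).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def per_image_counts(
    gold: Sequence[GoldLabel],
    detections: Sequence[DetectionResult],
    taxon: str,
    image_ids: Sequence[str],
) -> tuple[list[int], list[int]]:
    """Aligned per-image gold and machine counts for one taxon."""
    gold_c = {i: 0 for i in image_ids}
    mach_c = {i: 0 for i in image_ids}
    for g in gold:
        if g.taxon == taxon and g.image_id in gold_c:
            gold_c[g.image_id] += 1
    for res in detections:
        if res.image_id in mach_c:
            mach_c[res.image_id] += res.counts.get(taxon, 0)
    return ([gold_c[i] for i in image_ids], [mach_c[i] for i in image_ids])


def performance_table(
    outcome: MatchOutcome,
    gold: Sequence[GoldLabel],
    detections: Sequence[DetectionResult],
    image_ids: Sequence[str],
    exclude_from_total: Sequence[str] = (),
    correlation: str = "pearson",
) -> pd.DataFrame:
    """Per-taxon SE/PPV plus count correlation and micro-averaged totals.

    The totals row pools TP/FP/FN over taxa; a second totals row excludes
    the taxa in ``exclude_from_total`` (e.g. a cryptic taxon dominating the
    false positives).
    """
    if len(image_ids) < 2:
        raise ValueError("count correlation needs >= 2 images")
    rows = []
    for taxon in sorted(outcome.counts):
        tp, fp, fn = outcome.taxon_counts(taxon)
        se, ppv = se_ppv(tp, fp, fn)
        gc, mc = per_image_counts(gold, detections, taxon, image_ids)
        try:
            r = count_correlation(gc, mc, correlation)
        except ValueError:
            r = float("nan")
        rows.append({"taxon": taxon, "tp": tp, "fp": fp, "fn": fn,
                     "se": se, "ppv": ppv, "correlation": r})

    tp, fp, fn = outcome.pooled()
    se, ppv = se_ppv(tp, fp, fn)
    rows.append({"taxon": "total", "tp": tp, "fp": fp, "fn": fn,
                 "se": se, "ppv": ppv, "correlation": float("nan")})
    if exclude_from_total:
        tp, fp, fn = outcome.pooled(exclude=exclude_from_total)
        se, ppv = se_ppv(tp, fp, fn)
        rows.append({
            "taxon": "total_excluding_" + "_".join(exclude_from_total),
            "tp": tp, "fp": fp, "fn": fn, "se": se, "ppv": ppv,
            "correlation": float("nan"),
        })
    return pd.DataFrame(rows)


def supporter_sweep(
    labels,
    detections: Sequence[DetectionResult],
    taxa: TaxonSet,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    session_id: str | None = None,
) -> pd.DataFrame:
    """SE/PPV against gold standards of increasing supporter threshold.

    Detections are held fixed (no retraining); only the gold standard is
    rebuilt for each ``k_min``.  Because the gold sets are nested, PPV is
    monotone non-increasing in ``k_min``.
    """
    rows = []
    for k_min in k_values:
        gold_k = build_gold_standard(labels, taxa, k_min=k_min,
                                     session_id=session_id)
        outcome = match_detections(gold_k, detections, taxa)
        for taxon in sorted(outcome.counts):
            tp, fp, fn = outcome.taxon_counts(taxon)
            se, ppv = se_ppv(tp, fp, fn)
            rows.append({"k_min": k_min, "taxon": taxon, "tp": tp, "fp": fp,
                         "fn": fn, "se": se, "ppv": ppv})
        tp, fp, fn = outcome.pooled()
        se, ppv = se_ppv(tp, fp, fn)
        rows.append({"k_min": k_min, "taxon": "total", "tp": tp, "fp": fp,
                     "fn": fn, "se": se, "ppv": ppv})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# false-positive review queue


def export_review_queue(outcome: MatchOutcome,
                        path=None) -> pd.DataFrame:
    """Export all false-positive detections for manual review.

    Each row carries a stable ``detection_id``, position, taxon and
    confidence, plus a ``crop`` reference naming the image region a
    reviewer should inspect.  The verdict column is left empty and is to
    be filled with one of :data:`VERDICT_CATEGORIES`.
    """
    fps = outcome.detection_status[
        outcome.detection_status["status"] == "FP"].copy()
    fps = fps.reset_index().rename(columns={"index": "detection_id"})
    fps["crop"] = [
        f"{r.image_id}:x{int(r.x)}y{int(r.y)}"
        for r in fps.itertuples(index=False)
    ]
    fps["verdict"] = ""
    cols = ["detection_id", "image_id", "taxon", "x", "y", "confidence",
            "crop", "verdict"]
    out = fps[cols]
    if path is not None:
        out.to_csv(path, index=False)
    return out


def apply_review_verdicts(
    outcome: MatchOutcome,
    verdicts: pd.DataFrame,
) -> dict[str, dict[str, float]]:
    """Recompute SE/PPV treating accepted false positives as true positives.

    ``verdicts`` must carry ``detection_id`` and ``verdict`` columns; only
    the ``true_positive`` verdict flips an FP to a TP.  Unknown detection
    ids or verdict categories raise an error.
    """
    det = outcome.detection_status
    accepted_by_taxon: dict[str, int] = {}
    for row in verdicts.itertuples(index=False):
        did = int(row.detection_id)
        if did not in det.index:
            raise ValueError(f"verdict for unknown detection id {did}")
        if det.loc[did, "status"] != "FP":
            raise ValueError(f"detection {did} is not a false positive")
        if row.verdict not in VERDICT_CATEGORIES:
            raise ValueError(f"unknown verdict category {row.verdict!r}")
        if row.verdict == "true_positive":
            t = det.loc[did, "taxon"]
            accepted_by_taxon[t] = accepted_by_taxon.get(t, 0) + 1

    result: dict[str, dict[str, float]] = {}
    pooled_tp = pooled_fp = pooled_fn = 0
    for taxon, c in outcome.counts.items():
        a = accepted_by_taxon.get(taxon, 0)
        tp, fp, fn = c["tp"] + a, c["fp"] - a, c["fn"]
        se, ppv = se_ppv(tp, fp, fn)
        result[taxon] = {"tp": tp, "fp": fp, "fn": fn, "se": se, "ppv": ppv}
        pooled_tp, pooled_fp, pooled_fn = (pooled_tp + tp, pooled_fp + fp,
                                           pooled_fn + fn)
    se, ppv = se_ppv(pooled_tp, pooled_fp, pooled_fn)
    result["total"] = {"tp": pooled_tp, "fp": pooled_fp, "fn": pooled_fn,
                       "se": se, "ppv": ppv}
    return result
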