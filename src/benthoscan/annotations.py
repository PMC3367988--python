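"""Point annotations: label I/O, multi-expert fusion, observer agreement.

Several independent experts mark each organism with a single point label.  To
compare observers and to derive a consensus ("gold standard"), same-taxon
labels lying mutually closer than a taxon-specific distance are fused into a
clique whose centroid becomes the gold position and whose cardinality ``k``
(the supporter count) records how many labels back it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import BACKGROUND, ConfigurationError, TaxonSet

LABEL_COLUMNS = ["image_id", "annotator_id", "session_id", "taxon", "x", "y"]
GOLD_COLUMNS = ["image_id", "taxon", "x", "y", "k"]


@dataclass(frozen=True)
class PositionLabel:
    """A single expert point label."""

    image_id: str
    annotator_id: str
    session_id: str
    taxon: str
    x: float
    y: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class GoldLabel:
    """A fused consensus position with its supporter count."""

    image_id: str
    taxon: str
    x: float
    y: float
    k: int
    members: tuple[PositionLabel, ...] = field(default=(), compare=False)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class AgreementReport:
    """Observer-agreement value for one annotator pair (or session pair)."""

    taxon: str
    pair: tuple[str, str]
    value: float
    n_matched: int = 0
    n_only_u: int = 0
    n_only_v: int = 0


# ---------------------------------------------------------------------------
# label table I/O


def labels_to_frame(labels: Iterable[PositionLabel]) -> pd.DataFrame:
    rows = [(l.image_id, l.annotator_id, l.session_id, l.taxon, l.x, l.y)
            for l in labels]
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


def frame_to_labels(frame: pd.DataFrame) -> list[PositionLabel]:
    missing = set(LABEL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return [
        PositionLabel(str(r.image_id), str(r.annotator_id), str(r.session_id),
                      str(r.taxon), float(r.x), float(r.y))
        for r in frame.itertuples(index=False)
    ]


def read_labels_csv(path) -> list[PositionLabel]:
    return frame_to_labels(pd.read_csv(path, comment="#"))


def write_labels_csv(labels: Iterable[PositionLabel], path,
                     config_hash: str | None = None) -> None:
    frame = labels_to_frame(labels)
    # pixel coordinates are written as integers per the file contract
    frame["x"] = frame["x"].round().astype(int)
    frame["y"] = frame["y"].round().astype(int)
    _write_csv(frame, path, config_hash)


def gold_to_frame(gold: Iterable[GoldLabel]) -> pd.DataFrame:
    rows = [(g.image_id, g.taxon, g.x, g.y, g.k) for g in gold]
    return pd.DataFrame(rows, columns=GOLD_COLUMNS)


def read_gold_csv(path) -> list[GoldLabel]:
    frame = pd.read_csv(path, comment="#")
    return [
        GoldLabel(str(r.image_id), str(r.taxon), float(r.x), float(r.y), int(r.k))
        for r in frame.itertuples(index=False)
    ]


def write_gold_csv(gold: Iterable[GoldLabel], path,
                   config_hash: str | None = None) -> None:
    _write_csv(gold_to_frame(gold), path, config_hash)


def _write_csv(frame: pd.DataFrame, path, config_hash: str | None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# label-set matching and observer agreement


def _check_taxa(labels: Iterable[PositionLabel], taxa: TaxonSet) -> None:
    for lab in labels:
        if lab.taxon not in taxa:
            raise ConfigurationError(f"unknown taxon {lab.taxon!r} in label set")


def match_label_sets(
    U: Sequence[PositionLabel],
    V: Sequence[PositionLabel],
    taxa: TaxonSet,
) -> tuple[list[tuple[PositionLabel, PositionLabel]],
           list[PositionLabel], list[PositionLabel]]:
    """Partition two label sets into matched pairs and one-sided leftovers.

    A label in ``U`` matches a label in ``V`` iff both carry the same taxon
    and their Euclidean distance is at most that taxon's ``match_distance``.
    Assignment is greedy nearest-pair-first and one-to-one; the returned
    partition is exhaustive and disjoint.
    """
    _check_taxa(U, taxa)
    _check_taxa(V, taxa)

    candidates = []
    for i, u in enumerate(U):
        for j, v in enumerate(V):
            if u.taxon != v.taxon or u.image_id != v.image_id:
                continue
            d = float(np.hypot(u.x - v.x, u.y - v.y))
            if d <= taxa[u.taxon].match_distance:
                candidates.append((d, i, j))
    candidates.sort()

    used_u: set[int] = set()
    used_v: set[int] = set()
    pairs: list[tuple[PositionLabel, PositionLabel]] = []
    for _, i, j in candidates:
        if i in used_u or j in used_v:
            continue
        used_u.add(i)
        used_v.add(j)
        pairs.append((U[i], V[j]))

    only_u = [u for i, u in enumerate(U) if i not in used_u]
    only_v = [v for j, v in enumerate(V) if j not in used_v]
    return pairs, only_u, only_v


def observer_agreement(
    U: Sequence[PositionLabel],
    V: Sequence[PositionLabel],
    taxa: TaxonSet,
) -> float:
    """Observer agreement between two label sets.

    OA = #matched / (#matched + #only-U + #only-V).  Two empty sets agree
    perfectly by convention (no disagreement was observed).
    """
    if len(U) == 0 and len(V) == 0:
        return 1.0
    pairs, only_u, only_v = match_label_sets(U, V, taxa)
    return len(pairs) / (len(pairs) + len(only_u) + len(only_v))


def intra_observer_agreement(
    before: Sequence[PositionLabel],
    after: Sequence[PositionLabel],
    taxa: TaxonSet,
) -> float:
    """Agreement of one annotator with themselves across two sessions.

    Both sets are restricted to the images present in *both* sessions before
    applying the observer-agreement formula.
    """
    imgs_before = {l.image_id for l in before}
    imgs_after = {l.image_id for l in after}
    common = imgs_before & imgs_after
    if not common and (imgs_before or imgs_after):
        raise ValueError("sessions share no image ids; cannot compare")
    before_c = [l for l in before if l.image_id in common]
    after_c = [l for l in after if l.image_id in common]
    return observer_agreement(before_c, after_c, taxa)


def pairwise_agreements(
    labels: Sequence[PositionLabel],
    taxa: TaxonSet,
    session_id: str | None = None,
    per_taxon: bool = True,
) -> list[AgreementReport]:
    """All pairwise inter-observer agreements, optionally split per taxon."""
    pool = [l for l in labels
            if session_id is None or l.session_id == session_id]
    annotators = sorted({l.annotator_id for l in pool})
    taxon_groups = sorted({l.taxon for l in pool}) if per_taxon else [None]
    reports = []
    for t in taxon_groups:
        if t == BACKGROUND:
            continue
        sub = [l for l in pool if t is None or l.taxon == t]
        for a, b in itertools.combinations(annotators, 2):
            U = [l for l in sub if l.annotator_id == a]
            V = [l for l in sub if l.annotator_id == b]
            if not U and not V:
                continue
            value = observer_agreement(U, V, taxa)
            p, ou, ov = match_label_sets(U, V, taxa)
            reports.append(AgreementReport(t or "all", (a, b), value,
                                           len(p), len(ou), len(ov)))
    return reports


# ---------------------------------------------------------------------------
# gold standard construction


def _extract_cliques(
    positions: np.ndarray, d_max: float
) -> list[list[int]]:
    """Greedy decomposition of a proximity graph into disjoint cliques.

    Builds the graph with edges between labels closer than ``d_max``,
    enumerates maximal cliques, and accepts them greedily by descending size
    (ties: smaller mean pairwise distance, then lexicographic member order),
    removing used labels after each acceptance.
    """
    n = len(positions)
    if n == 0:
        return []
    diffs = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diffs ** 2).sum(-1))
    adj = dist < d_max

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(
        (i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]
    )

    accepted: list[list[int]] = []
    while graph.number_of_nodes():
        best = None
        best_key = None
        for clique in nx.find_cliques(graph):
            clique = sorted(clique)
            if len(clique) > 1:
                sub = dist[np.ix_(clique, clique)]
                mean_d = sub.sum() / (len(clique) * (len(clique) - 1))
            else:
                mean_d = 0.0
            key = (-len(clique), mean_d, tuple(clique))
            if best_key is None or key < best_key:
                best_key = key
                best = clique
        accepted.append(best)
        graph.remove_nodes_from(best)
    return accepted


def build_gold_standard(
    labels: Sequence[PositionLabel],
    taxa: TaxonSet,
    k_min: int = 3,
    session_id: str | None = None,
) -> list[GoldLabel]:
    """Fuse all experts' labels into gold-standard positions.

    Per (image, taxon), same-taxon labels with all pairwise distances below
    ``d_taxon`` form a clique; each clique with at least ``k_min`` members
    yields one gold label at the member centroid with supporter count
    ``k`` = member count.  Background labels pass through unfused (k = 1),
    regardless of ``k_min``.
    """
    pool = [l for l in labels
            if session_id is None or l.session_id == session_id]
    _check_taxa(pool, taxa)
    gold: list[GoldLabel] = []

    background = [l for l in pool if l.taxon == BACKGROUND]
    for lab in background:
        gold.append(GoldLabel(lab.image_id, BACKGROUND, lab.x, lab.y, 1, (lab,)))

    rest = [l for l in pool if l.taxon != BACKGROUND]
    keyfn = lambda l: (l.image_id, l.taxon)
    for (image_id, taxon), group in itertools.groupby(
            sorted(rest, key=keyfn), key=keyfn):
        members = list(group)
        positions = np.array([[l.x, l.y] for l in members], dtype=float)
        for clique in _extract_cliques(positions, taxa[taxon].d_taxon):
            if len(clique) < k_min:
                continue
            sel = [members[i] for i in clique]
            cx = float(np.mean([l.x for l in sel]))
            cy = float(np.mean([l.y for l in sel]))
            gold.append(GoldLabel(image_id, taxon, cx, cy, len(sel), tuple(sel)))
    return gold


def filter_rare_taxa(
    counts: Mapping[str, int] | pd.DataFrame | Sequence[PositionLabel],
    min_count: int = 150,
) -> list[str]:
    """Taxa with enough human labels to support training.

    Accepts a ``{taxon: count}`` mapping, a label table, or a label list.
    Returns taxa whose total human label count is at least ``min_count``
    (inclusive).  Background, when present, is always retained.
    """
    if isinstance(counts, pd.DataFrame):
        tally = counts["taxon"].value_counts().to_dict()
    elif isinstance(counts, Mapping):
        tally = dict(counts)
    else:
        tally = pd.Series([l.taxon for l in counts]).value_counts().to_dict()

    kept = [t for t, c in tally.items() if c >= min_count or t == BACKGROUND]
    # stable, deterministic order: descending count, then name
    kept.sort(key=lambda t: (-tally[t], t))
    return kept


def label_counts(labels: Sequence[PositionLabel]) -> dict[str, int]:
    """Total number of human labels per taxon."""
    out: dict[str, int] = {}
    for l in labels:
        out[l.taxon] = out.get(l.taxon, 0) + 1
    return out
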