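"""Label matching, observer agreement, and gold-standard fusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscan.annotations import (PositionLabel,
                                    build_gold_standard, filter_rare_taxa,
                                    frame_to_labels, intra_observer_agreement,
                                    label_counts, labels_to_frame,
                                    match_label_sets, observer_agreement,
                                    read_labels_csv, write_labels_csv)
from benthoscan.config import BACKGROUND, ConfigurationError, TaxonSet


def L(taxon, x, y, annotator="u", image="img0", session="s1"):
    return PositionLabel(image, annotator, session, taxon, x, y)


# ---------------------------------------------------------------------------
# matching


class TestMatchLabelSets:
    def test_identical_sets_fully_match(self, taxa):
        U = [L("A", 0, 0), L("A", 10, 0), L("B", 3, 4)]
        pairs, only_u, only_v = match_label_sets(U, list(U), taxa)
        assert len(pairs) == 3 and not only_u and not only_v

    def test_same_positions_different_taxa_never_match(self, taxa):
        U = [L("A", 0, 0), L("A", 1, 1)]
        V = [L("B", 0, 0), L("B", 1, 1)]
        pairs, only_u, only_v = match_label_sets(U, V, taxa)
        assert pairs == [] and len(only_u) == 2 and len(only_v) == 2

    def test_greedy_nearest_first_assignment(self, taxa):
        # U = {(0,0),(10,0)}, V = {(1,0)}: only (0,0) matches
        U = [L("A", 0, 0), L("A", 10, 0)]
        V = [L("A", 1, 0)]
        pairs, only_u, only_v = match_label_sets(U, V, taxa)
        assert len(pairs) == 1
        assert pairs[0][0].x == 0 and pairs[0][1].x == 1
        assert [u.x for u in only_u] == [10] and not only_v

    def test_one_to_one_and_partition_exhaustive(self, taxa, rng):
        U = [L("A", rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(12)]
        V = [L("A", rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(9)]
        pairs, only_u, only_v = match_label_sets(U, V, taxa)
        assert len(pairs) + len(only_u) == len(U)
        assert len(pairs) + len(only_v) == len(V)
        matched_u = [id(p[0]) for p in pairs]
        assert len(set(matched_u)) == len(matched_u)
        for u, v in pairs:
            assert u.taxon == v.taxon
            assert np.hypot(u.x - v.x, u.y - v.y) <= 5.0

    def test_unknown_taxon_is_configuration_error(self, taxa):
        with pytest.raises(ConfigurationError):
            match_label_sets([L("unknown", 0, 0)], [], taxa)


# ---------------------------------------------------------------------------
# observer agreement


class TestObserverAgreement:
    def test_identical_nonempty_sets_agree_fully(self, taxa):
        U = [L("A", 0, 0), L("B", 9, 9)]
        assert observer_agreement(U, list(U), taxa) == 1.0

    def test_disjoint_sets_agree_zero(self, taxa):
        U = [L("A", 0, 0), L("A", 20, 20)]
        V = [L("A", 40, 40)]
        assert observer_agreement(U, V, taxa) == 0.0

    def test_partial_overlap_formula(self, taxa):
        # 2 matched + 1 only-U -> 2/3
        U = [L("A", 0, 0), L("A", 20, 0), L("A", 40, 0)]
        V = [L("A", 1, 0), L("A", 21, 0)]
        assert observer_agreement(U, V, taxa) == pytest.approx(2 / 3)

    def test_both_empty_is_perfect_agreement(self, taxa):
        assert observer_agreement([], [], taxa) == 1.0

    @given(st.lists(st.tuples(st.sampled_from(["A", "B"]),
                              st.integers(0, 40), st.integers(0, 40)),
                    max_size=12),
           st.lists(st.tuples(st.sampled_from(["A", "B"]),
                              st.integers(0, 40), st.integers(0, 40)),
                    max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, u_spec, v_spec):
        taxa = TaxonSet.uniform(["A", "B"], d_taxon=5, match_distance=5)
        U = [L(t, x, y) for t, x, y in u_spec]
        V = [L(t, x, y) for t, x, y in v_spec]
        oa_uv = observer_agreement(U, V, taxa)
        oa_vu = observer_agreement(V, U, taxa)
        assert oa_uv == pytest.approx(oa_vu)
        assert 0.0 <= oa_uv <= 1.0
        if U:
            assert observer_agreement(U, list(U), taxa) == 1.0


class TestIntraObserverAgreement:
    def test_identical_sessions(self, taxa):
        before = [L("A", 0, 0), L("B", 5, 5)]
        assert intra_observer_agreement(before, list(before), taxa) == 1.0

    def test_empty_after_session(self, taxa):
        before = [L("A", 0, 0)]
        after = [L("B", 30, 30)]  # same image, nothing matching
        assert intra_observer_agreement(before, after, taxa) == 0.0

    def test_three_matched_three_unmatched(self, taxa):
        before = [L("A", 0, 0), L("A", 20, 0), L("A", 40, 0), L("A", 60, 0)]
        after = [L("A", 0, 1), L("A", 20, 1), L("A", 40, 1),
                 L("A", 90, 0), L("A", 120, 0)]
        # 3 matched, 1 only-before, 2 only-after -> 0.5
        assert intra_observer_agreement(before, after, taxa) == 0.5

    def test_disjoint_image_sets_error(self, taxa):
        before = [L("A", 0, 0, image="img0")]
        after = [L("A", 0, 0, image="img1")]
        with pytest.raises(ValueError, match="image"):
            intra_observer_agreement(before, after, taxa)

    def test_restricted_to_common_images(self, taxa):
        before = [L("A", 0, 0, image="img0"), L("A", 5, 5, image="img9")]
        after = [L("A", 0, 1, image="img0")]
        # img9 only in session 1, excluded from the comparison
        assert intra_observer_agreement(before, after, taxa) == 1.0


# ---------------------------------------------------------------------------
# gold standard


def brute_force_max_cliques(positions, d_max):
    """Oracle: greedy clique cover via exhaustive subset enumeration."""
    n = len(positions)
    remaining = set(range(n))
    dist = np.sqrt(((positions[:, None] - positions[None, :]) ** 2).sum(-1))

    def is_clique(sub):
        return all(dist[i, j] < d_max
                   for i, j in itertools.combinations(sub, 2))

    cliques = []
    while remaining:
        best = None
        for size in range(len(remaining), 0, -1):
            candidates = []
            for sub in itertools.combinations(sorted(remaining), size):
                if is_clique(sub):
                    # maximality within remaining
                    if not any(is_clique(sub + (o,))
                               for o in remaining if o not in sub):
                        candidates.append(sub)
            if candidates:
                def key(sub):
                    if len(sub) > 1:
                        pairs = list(itertools.combinations(sub, 2))
                        md = np.mean([dist[i, j] for i, j in pairs])
                    else:
                        md = 0.0
                    return (md, sub)
                best = min(candidates, key=key)
                break
        cliques.append(sorted(best))
        remaining -= set(best)
    return cliques


class TestGoldStandard:
    def test_five_coincident_labels_fuse(self, taxa):
        labels = [L("A", 10, 10, annotator=f"a{i}") for i in range(5)]
        gold = build_gold_standard(labels, taxa, k_min=3)
        assert len(gold) == 1
        g = gold[0]
        assert g.k == 5 and g.x == 10 and g.y == 10

    def test_two_supporters_below_k_min(self, taxa):
        labels = [L("A", 10, 10), L("A", 11, 10, annotator="v")]
        assert build_gold_standard(labels, taxa, k_min=3) == []

    def test_centroid_is_member_mean(self, taxa):
        labels = [L("A", 0, 0), L("A", 2, 0, annotator="v"),
                  L("A", 1, 2, annotator="w")]
        gold = build_gold_standard(labels, taxa, k_min=3)
        assert len(gold) == 1
        assert gold[0].x == pytest.approx(1.0)
        assert gold[0].y == pytest.approx(2 / 3)

    def test_background_passes_through_unfused(self, taxa):
        labels = [L(BACKGROUND, 5, 5, annotator=f"a{i}") for i in range(4)]
        gold = build_gold_standard(labels, taxa, k_min=3)
        assert len(gold) == 4
        assert all(g.k == 1 for g in gold)

    def test_empty_input(self, taxa):
        assert build_gold_standard([], taxa, k_min=3) == []

    def test_nested_in_k_min(self, taxa, rng):
        labels = [
            L("A", rng.uniform(0, 60), rng.uniform(0, 60),
              annotator=f"a{i % 5}")
            for i in range(40)
        ]
        sizes = []
        positions = {}
        for k_min in (1, 2, 3, 4, 5):
            gold = build_gold_standard(labels, taxa, k_min=k_min)
            sizes.append(len(gold))
            positions[k_min] = {(g.x, g.y, g.k) for g in gold}
        assert sizes == sorted(sizes, reverse=True)
        for a, b in zip((1, 2, 3, 4), (2, 3, 4, 5)):
            assert positions[b] <= positions[a]

    def test_centroid_inside_convex_hull(self, taxa, rng):
        for _ in range(20):
            pts = rng.uniform(0, 4, size=(rng.integers(3, 6), 2))
            labels = [L("A", x, y, annotator=f"a{i}")
                      for i, (x, y) in enumerate(pts)]
            for g in build_gold_standard(labels, taxa, k_min=1):
                mx = [m.x for m in g.members]
                my = [m.y for m in g.members]
                assert min(mx) <= g.x <= max(mx)
                assert min(my) <= g.y <= max(my)

    def test_matches_brute_force_clique_oracle(self, rng):
        taxa = TaxonSet.uniform(["A"], d_taxon=6.0)
        for trial in range(100):
            n = int(rng.integers(1, 11))
            pts = rng.uniform(0, 25, size=(n, 2))
            labels = [L("A", x, y, annotator=f"a{i}")
                      for i, (x, y) in enumerate(pts)]
            gold = build_gold_standard(labels, taxa, k_min=1)
            oracle = brute_force_max_cliques(pts, 6.0)
            got = sorted(
                (round(g.x, 6), round(g.y, 6), g.k) for g in gold)
            want = sorted(
                (round(float(pts[list(c), 0].mean()), 6),
                 round(float(pts[list(c), 1].mean()), 6), len(c))
                for c in oracle)
            assert got == want, f"trial {trial}"


# ---------------------------------------------------------------------------
# rare-taxon filter and I/O


class TestFilterRareTaxa:
    def test_study_counts_retain_eight_taxa(self):
        # the study's printed per-taxon human label counts
        import importlib.resources as res

        with res.files("benthoscan.data").joinpath(
                "reference_label_counts.csv").open() as fh:
            table = pd.read_csv(fh)
        counts = dict(zip(table["taxon"], table["human_labels"]))
        kept = filter_rare_taxa(counts, min_count=150)
        non_background = [t for t in kept if t != BACKGROUND]
        assert len(non_background) == 8
        assert BACKGROUND in kept

    def test_all_below_threshold(self):
        assert filter_rare_taxa({"A": 10, "B": 3}, min_count=150) == []

    def test_threshold_is_inclusive(self):
        assert filter_rare_taxa({"A": 150, "B": 149}, min_count=150) == ["A"]

    def test_accepts_label_list(self):
        labels = [L("A", 0, 0)] * 3 + [L("B", 1, 1)]
        assert filter_rare_taxa(labels, min_count=2) == ["A"]


def test_labels_csv_roundtrip(tmp_path, taxa):
    labels = [L("A", 3, 4), L("B", 10, 20, annotator="v", session="s2")]
    path = tmp_path / "labels.csv"
    write_labels_csv(labels, path, config_hash="abc123")
    assert "config_hash=abc123" in path.read_text().splitlines()[0]
    back = read_labels_csv(path)
    assert [(l.taxon, l.x, l.y) for l in back] == [("A", 3, 4), ("B", 10, 20)]
    frame = labels_to_frame(back)
    assert frame_to_labels(frame) == back


def test_label_counts():
    labels = [L("A", 0, 0), L("A", 1, 1), L("B", 2, 2)]
    assert label_counts(labels) == {"A": 2, "B": 1}
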