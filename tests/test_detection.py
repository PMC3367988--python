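"""Cascade classification, blob extraction, and cascade tuning."""

import numpy as np
import pytest

from benthoscan.config import BACKGROUND, TaxonSet
from benthoscan.detection import (Blob, CascadeEntry, CascadeTree,
                                  binarize_and_blob, classify_field_of_view,
                                  detect, tune_cascade)
from benthoscan.training import TaxonModel


def flood_fill_components(mask):
    """Oracle: 8-connected components by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or visited[sy, sx]:
                continue
            stack = [(sy, sx)]
            visited[sy, sx] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and not visited[ny, nx]):
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(comp)
    return comps


class TestBinarizeAndBlob:
    def test_small_blob_discarded(self):
        conf = np.zeros((30, 30))
        conf[5:7, 5:10] = 0.9  # 10 px
        assert binarize_and_blob(conf, 0.5, s_min=20) == []

    def test_theta_zero_single_region(self):
        conf = np.random.default_rng(0).uniform(size=(20, 20))
        blobs = binarize_and_blob(conf, 0.0, s_min=1)
        assert len(blobs) == 1
        assert blobs[0].size == 400

    def test_diagonal_touch_merges_under_8_connectivity(self):
        conf = np.zeros((30, 30))
        conf[5:10, 5:10] = 1.0
        conf[10:15, 10:15] = 1.0  # touches only diagonally at (9,9)-(10,10)
        blobs = binarize_and_blob(conf, 0.5, s_min=1)
        assert len(blobs) == 1

    def test_centroid_is_pixel_mean(self):
        conf = np.zeros((20, 20))
        conf[4:6, 10:14] = 1.0
        blobs = binarize_and_blob(conf, 0.5, s_min=1)
        assert blobs[0].centroid == pytest.approx((11.5, 4.5))

    def test_matches_flood_fill_oracle(self, rng):
        for trial in range(100):
            mask = rng.random((30, 30)) < 0.35
            conf = mask.astype(float)
            blobs = binarize_and_blob(conf, 0.5, s_min=1, keep_pixels=True)
            oracle = flood_fill_components(mask)
            assert len(blobs) == len(oracle), f"trial {trial}"
            got = sorted(
                (b.size, round(b.centroid[0], 6), round(b.centroid[1], 6))
                for b in blobs)
            want = sorted(
                (len(c),
                 round(float(np.mean([x for _, x in c])), 6),
                 round(float(np.mean([y for y, _ in c])), 6))
                for c in oracle)
            assert got == want

    def test_foreground_monotone_in_theta(self, rng):
        conf = rng.random((40, 40))
        areas = [sum(b.size for b in binarize_and_blob(conf, t, 1))
                 for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert areas == sorted(areas, reverse=True)

    def test_count_monotone_in_s_min(self, rng):
        conf = (rng.random((40, 40)) < 0.3).astype(float)
        counts = [len(binarize_and_blob(conf, 0.5, s))
                  for s in (1, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_parameters(self):
        conf = np.zeros((5, 5))
        with pytest.raises(ValueError):
            binarize_and_blob(conf, 1.5, 1)
        with pytest.raises(ValueError):
            binarize_and_blob(conf, 0.5, 0)


def _synthetic_model(taxon, center, sharpness=4.0):
    """A tiny RBF model whose confidence peaks near ``center`` in a 2-dim
    toy feature space (features: x/width, y/height)."""
    sv = np.asarray([center], dtype=float)
    return TaxonModel(
        taxon=taxon, C=1.0, gamma=sharpness,
        support_vectors=sv, dual_coef=np.array([4.0]), intercept=-2.0,
        platt_a=-3.0, platt_b=0.0,
    )


class _ToyExtractor:
    """Feature extractor stub: features are normalized coordinates."""

    patch_size = 32

    def extract(self, image, positions, chunk=4096):
        h, w = image.shape[:2]
        pos = np.asarray(positions, dtype=float).reshape(-1, 2)
        return np.column_stack([pos[:, 0] / w, pos[:, 1] / h]).astype(
            np.float32)

    def extract_grid(self, image, stride=1):
        h, w = image.shape[:2]
        gx = np.arange(0, w, stride)
        gy = np.arange(0, h, stride)
        xx, yy = np.meshgrid(gx, gy)
        pos = np.column_stack([xx.ravel(), yy.ravel()])
        return self.extract(image, pos), pos[:, 0], pos[:, 1]


class TestClassifyFieldOfView:
    def _setup(self):
        image = np.zeros((40, 40, 3), dtype=np.uint8)
        model_a = _synthetic_model("A", (0.25, 0.25))
        model_b = _synthetic_model("B", (0.75, 0.75))
        bg = _synthetic_model(BACKGROUND, (0.5, 0.5), sharpness=0.01)
        return image, _ToyExtractor(), model_a, model_b, bg

    def test_empty_cascade_errors(self):
        image, ex, *_ = self._setup()
        with pytest.raises(ValueError):
            classify_field_of_view(image, CascadeTree(entries=[]), ex)

    def test_theta_zero_first_taxon_claims_everything(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.0),
                                       CascadeEntry(b, theta=0.5)])
        fc = classify_field_of_view(image, cascade, ex, margin=0)
        assert np.all(fc.class_map == fc.class_codes["A"])

    def test_confidences_bounded(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a), CascadeEntry(b)],
                              background_model=bg)
        fc = classify_field_of_view(image, cascade, ex, margin=0)
        for m in fc.confidence_maps.values():
            assert np.all((m >= 0) & (m <= 1))

    def test_first_above_threshold_claims_pixel(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.5),
                                       CascadeEntry(b, theta=0.5)])
        fc = classify_field_of_view(image, cascade, ex, margin=0)
        # near (10, 10) model A fires; near (30, 30) model B
        assert fc.class_map[10, 10] == fc.class_codes["A"]
        assert fc.class_map[30, 30] == fc.class_codes["B"]

    def test_margin_blocks_neighborhood(self):
        image, ex, a, b, bg = self._setup()
        # B's peak is inside A's margin ring only if margin is very large
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.5),
                                       CascadeEntry(b, theta=0.5)])
        fc = classify_field_of_view(image, cascade, ex, margin=30)
        # everything within 30 px of an A-claimed pixel is unvisited for B
        b_area = (fc.class_map == fc.class_codes["B"]).sum()
        fc0 = classify_field_of_view(image, cascade, ex, margin=0)
        b_area0 = (fc0.class_map == fc0.class_codes["B"]).sum()
        assert b_area < b_area0

    def test_stride_counts_consistent(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.5, s_min=1),
                                       CascadeEntry(b, theta=0.5, s_min=1)])
        d1 = detect(image, cascade, ex, stride=1, margin=0)
        d2 = detect(image, cascade, ex, stride=2, margin=0)
        for taxon in ("A", "B"):
            c1 = d1.counts.get(taxon, 0)
            c2 = d2.counts.get(taxon, 0)
            assert abs(c1 - c2) <= max(1, 0.2 * max(c1, c2))

    def test_detect_counts_match_detections(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.5, s_min=1),
                                       CascadeEntry(b, theta=0.5, s_min=1)],
                              background_model=bg, theta_bg=0.0)
        result = detect(image, cascade, ex, margin=0)
        for taxon, count in result.counts.items():
            assert count == len(result.for_taxon(taxon))

    def test_end_to_end_deterministic(self):
        image, ex, a, b, bg = self._setup()
        cascade = CascadeTree(entries=[CascadeEntry(a, theta=0.5, s_min=1),
                                       CascadeEntry(b, theta=0.5, s_min=1)])
        r1 = detect(image, cascade, ex, margin=5)
        r2 = detect(image, cascade, ex, margin=5)
        assert [(b.taxon, b.centroid, b.size) for b in r1.detections] == \
               [(b.taxon, b.centroid, b.size) for b in r2.detections]

    def test_duplicate_taxon_rejected(self):
        _, _, a, _, _ = self._setup()
        with pytest.raises(ValueError):
            CascadeTree(entries=[CascadeEntry(a), CascadeEntry(a)])


class TestTuneCascade:
    def _setup(self):
        from benthoscan.annotations import GoldLabel

        image = np.zeros((40, 40, 3), dtype=np.uint8)
        models = {
            "A": _synthetic_model("A", (0.25, 0.25)),
            "B": _synthetic_model("B", (0.75, 0.75)),
        }
        gold = [GoldLabel("img0", "A", 10.0, 10.0, 3),
                GoldLabel("img0", "B", 30.0, 30.0, 3)]
        taxa = TaxonSet.uniform(["A", "B", BACKGROUND], match_distance=8.0)
        return image, models, gold, taxa

    def test_single_configuration_returned(self):
        image, models, gold, taxa = self._setup()
        tree, trace = tune_cascade(models, {"img0": image}, gold, taxa,
                                   _ToyExtractor(), theta_grid=[0.5],
                                   s_min_grid=[1], margin=0)
        assert trace["per_taxon"] == {"A": (0.5, 1), "B": (0.5, 1)}

    def test_tuning_beats_default_configuration(self):
        image, models, gold, taxa = self._setup()
        ex = _ToyExtractor()
        tree, trace = tune_cascade(models, {"img0": image}, gold, taxa, ex,
                                   theta_grid=[0.1, 0.5, 0.9],
                                   s_min_grid=[1, 4, 1000], margin=0)
        # a degenerate default (s_min covering the whole image) scores 0
        assert trace["score"] > 0.0
        for taxon, (theta, s_min) in trace["per_taxon"].items():
            assert s_min < 1000

    def test_deterministic(self):
        image, models, gold, taxa = self._setup()
        ex = _ToyExtractor()
        kw = dict(theta_grid=[0.3, 0.7], s_min_grid=[1, 4], margin=0)
        _, t1 = tune_cascade(models, {"img0": image}, gold, taxa, ex, **kw)
        _, t2 = tune_cascade(models, {"img0": image}, gold, taxa, ex, **kw)
        assert t1 == t2

    def test_no_gold_errors(self):
        image, models, _, taxa = self._setup()
        with pytest.raises(ValueError):
            tune_cascade(models, {"img0": image}, [], taxa, _ToyExtractor())


class TestPersistence:
    def _cascade(self, rng):
        from benthoscan.training import (TrainingSet, fit_normalizer,
                                         train_taxon_model)

        def model(taxon, shift):
            pos = rng.normal(shift, 0.5, size=(30, 6)).astype(np.float32)
            neg = rng.normal(-shift, 0.5, size=(30, 6)).astype(np.float32)
            X = np.vstack([pos, neg])
            y = np.array([1] * 30 + [0] * 30)
            ts = TrainingSet(taxon, X, y, ["x"] * 60, np.arange(60))
            norm = fit_normalizer(np.vstack([X, X]),
                                  groups={"all": (0, 6)})
            return train_taxon_model(ts, 1.0, 0.1, normalizer=norm)

        entries = [CascadeEntry(model("A", 2.0), theta=0.6, s_min=4),
                   CascadeEntry(model("B", 3.0), theta=0.7, s_min=9)]
        bg = model("background", 1.0)
        return CascadeTree(entries=entries, background_model=bg,
                           theta_bg=0.4)

    def test_cascade_roundtrip(self, tmp_path, rng):
        from benthoscan.detection import load_cascade, save_cascade

        cascade = self._cascade(rng)
        path = tmp_path / "bundle.npz"
        save_cascade(path, cascade, config_hash="deadbeef")
        loaded, chash = load_cascade(path)
        assert chash == "deadbeef"
        assert loaded.order == cascade.order
        assert loaded.theta_bg == cascade.theta_bg
        probe = rng.normal(size=(20, 6))
        for orig, back in zip(cascade.entries, loaded.entries):
            assert back.theta == orig.theta and back.s_min == orig.s_min
            assert np.allclose(orig.model.confidence(probe),
                               back.model.confidence(probe))
            assert np.allclose(orig.model.normalizer.mean,
                               back.model.normalizer.mean)
        assert np.allclose(cascade.background_model.confidence(probe),
                           loaded.background_model.confidence(probe))

    def test_classification_map_image(self):
        from benthoscan.detection import (FieldClassification,
                                          classification_map_image)

        cm = np.array([[-1, 0], [1, -2]])
        fc = FieldClassification(
            image_id="img0",
            confidence_maps={},
            class_map=cm,
            class_codes={"A": 0, "B": 1, "background": 2},
            visited=np.ones((2, 2), dtype=bool),
        )
        img = classification_map_image(fc)
        assert img.shape == (2, 2, 3)
        assert tuple(img[0, 0]) == (0, 0, 0)        # rejected -> black
        assert tuple(img[1, 1]) == (40, 40, 40)     # unvisited -> gray
        assert tuple(img[0, 1]) != tuple(img[1, 0])  # distinct taxa colors
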