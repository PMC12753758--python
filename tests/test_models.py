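"""Training roles: splits, class weights, backend contract, expert pool,
tumor-locator remapping and slide-mask assembly."""

import numpy as np
import pytest

from somseg import (
    LabelMask, ModelHandle, SlideRecord, TrainConfig, class_weights,
    predict_slide_mask, split_case_patches, train_expert_pool,
    train_segmentation, train_supervised, train_tumor_locator,
)
from somseg.models import LOCATOR_SCHEME, remap_to_locator
from conftest import make_patch


def colour_patches(scheme, n=10, code=1, colour=(200, 60, 60), slide_id="s0"):
    """n identical single-class patches (trivially separable toy data)."""
    return [
        make_patch(
            np.full((8, 8, 3), colour, dtype=np.uint8),
            np.full((8, 8), code, dtype=np.int64),
            scheme, slide_id=slide_id, origin=(i, 0),
        )
        for i in range(n)
    ]


def two_class_patches(scheme, n=10, slide_id="s0"):
    """Left half tumor (red), right half background (white) — separable."""
    out = []
    for i in range(n):
        px = np.empty((8, 8, 3), dtype=np.uint8)
        px[:, :4] = (200, 60, 60)
        px[:, 4:] = (245, 245, 245)
        codes = np.zeros((8, 8), dtype=np.int64)
        codes[:, :4] = 1
        out.append(make_patch(px, codes, scheme, slide_id=slide_id, origin=(i, 0)))
    return out


class TestSplitCasePatches:
    def test_ninety_ten(self, scheme):
        patches = colour_patches(scheme, 10)
        train, val = split_case_patches(patches, TrainConfig(split_seed=3))
        assert (len(train), len(val)) == (9, 1)
        assert {p.origin for p in train} | {p.origin for p in val} == {
            p.origin for p in patches
        }

    def test_minimum_val_of_one(self, scheme):
        train, val = split_case_patches(colour_patches(scheme, 2), TrainConfig())
        assert (len(train), len(val)) == (1, 1)

    def test_deterministic(self, scheme):
        patches = colour_patches(scheme, 20)
        cfg = TrainConfig(split_seed=11)
        t1, v1 = split_case_patches(patches, cfg)
        t2, v2 = split_case_patches(patches, cfg)
        assert [p.origin for p in t1] == [p.origin for p in t2]
        assert [p.origin for p in v1] == [p.origin for p in v2]

    def test_too_few_errors(self, scheme):
        with pytest.raises(ValueError):
            split_case_patches(colour_patches(scheme, 1), TrainConfig())


class TestClassWeights:
    def test_uniform_histogram_gives_unit_weights(self):
        w = class_weights({0: 50, 1: 50, 2: 50})
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_inverse_frequency_example(self):
        w = class_weights({1: 900, 2: 100})
        assert w[1] == pytest.approx(0.5556, abs=1e-3)
        assert w[2] == pytest.approx(5.0, abs=1e-3)

    def test_scale_invariance(self):
        w1 = class_weights({0: 10, 1: 30, 2: 60})
        w2 = class_weights({0: 20, 1: 60, 2: 120})
        for c in w1:
            assert w1[c] == pytest.approx(w2[c])

    def test_unobserved_class_gets_max_weight(self):
        w = class_weights({1: 900, 2: 100}, all_codes=[0, 1, 2, 3])
        assert w[0] == w[3] == max(w[1], w[2])

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError):
            class_weights({1: 0})


class TestTrainSegmentation:
    @pytest.mark.parametrize("backend_id", ["centroid", "softmax"])
    def test_separable_patches_reach_val_dice_one(self, scheme, backend_id):
        cfg = TrainConfig(backend_id=backend_id, epochs=8)
        patches = two_class_patches(scheme, 10)
        train, val = split_case_patches(patches, cfg)
        handle = train_segmentation(train, val, scheme, cfg)
        assert handle.best_val_score == pytest.approx(1.0)
        assert handle.best_val_score == max(handle.backend.val_scores_)

    def test_deterministic_given_seeds(self, scheme):
        cfg = TrainConfig(backend_id="softmax", epochs=3)
        patches = two_class_patches(scheme, 10)
        train, val = split_case_patches(patches, cfg)
        h1 = train_segmentation(train, val, scheme, cfg)
        h2 = train_segmentation(train, val, scheme, cfg)
        px = np.random.default_rng(0).integers(0, 256, (8, 8, 3)).astype(np.uint8)
        np.testing.assert_array_equal(
            h1.backend.predict_mask(px), h2.backend.predict_mask(px)
        )

    def test_ignore_pixels_contribute_nothing(self, scheme):
        # poisoning ignore pixels with a wrong colour must not move centroids
        cfg = TrainConfig(backend_id="centroid")
        base = two_class_patches(scheme, 6)
        poisoned = []
        for p in two_class_patches(scheme, 6):
            p.mask.codes[0, :] = scheme.ignore_code
            p.pixels[0, :] = (7, 200, 7)
            poisoned.append(p)
        t1, v1 = split_case_patches(base, cfg)
        t2, v2 = split_case_patches(poisoned, cfg)
        h1 = train_segmentation(t1, v1, scheme, cfg)
        h2 = train_segmentation(t2, v2, scheme, cfg)
        np.testing.assert_allclose(
            h1.backend.centroids_, h2.backend.centroids_, atol=1.5
        )

    def test_unknown_backend_surfaces_id(self, scheme):
        cfg = TrainConfig(backend_id="nonesuch")
        patches = two_class_patches(scheme, 4)
        train, val = split_case_patches(patches, cfg)
        with pytest.raises((KeyError, RuntimeError), match="nonesuch"):
            train_segmentation(train, val, scheme, cfg)


def synthetic_annotated(scheme, n=3, size=64):
    from somseg.synthetic import SyntheticCohortConfig, generate_slide, separable_styles

    cfg = SyntheticCohortConfig(
        slide_size=64, border=4, tumor_extent=32, stroma_width=4, benign_extent=12,
    )
    styles = separable_styles()
    return [
        generate_slide(styles[i % 4], cfg, seed=100 + i, slide_id=f"a{i}")
        for i in range(n)
    ]


class TestPoolRoles:
    def test_expert_pool_one_model_per_slide(self, scheme):
        slides = synthetic_annotated(scheme, 3)
        pool = train_expert_pool(slides, TrainConfig(), patch_size=16, stride=16)
        assert set(pool.experts) == {s.slide_id for s in slides}
        for sid, handle in pool.experts.items():
            assert handle.role == "expert"
            assert handle.source_slides == [sid]

    def test_expert_role_requires_single_source(self, scheme):
        with pytest.raises(ValueError):
            ModelHandle("m", "expert", ["a", "b"], 0.0, object(), scheme)

    def test_supervised_with_one_slide_equals_its_expert(self, scheme):
        slides = synthetic_annotated(scheme, 1)
        cfg = TrainConfig()
        pool = train_expert_pool(slides, cfg, patch_size=16, stride=16)
        sup = train_supervised(slides, cfg, patch_size=16, stride=16)
        expert = pool.experts[slides[0].slide_id]
        np.testing.assert_array_equal(
            sup.backend.predict_mask(slides[0].image),
            expert.backend.predict_mask(slides[0].image),
        )
        assert sup.source_slides == [slides[0].slide_id]

    def test_supervised_lists_all_sources(self, scheme):
        slides = synthetic_annotated(scheme, 3)
        sup = train_supervised(slides, TrainConfig(), patch_size=16, stride=16)
        assert sup.source_slides == sorted(s.slide_id for s in slides)

    def test_handle_roundtrip(self, scheme, tmp_path):
        slides = synthetic_annotated(scheme, 1)
        sup = train_supervised(slides, TrainConfig(), patch_size=16, stride=16)
        sup.save(tmp_path / "model")
        back = ModelHandle.load(tmp_path / "model", scheme)
        np.testing.assert_array_equal(
            back.backend.predict_mask(slides[0].image),
            sup.backend.predict_mask(slides[0].image),
        )
        assert back.role == "supervised"


class TestTumorLocator:
    def test_remap_strictly_tumor(self, scheme):
        codes = np.array([[1, 2], [3, 0]])
        out = remap_to_locator(LabelMask(codes, scheme))
        # only the tumor class maps to "tumor"; stroma is non-tumor
        np.testing.assert_array_equal(out.codes, [[1, 2], [2, 0]])

    def test_remap_with_stroma_as_tumor(self, scheme):
        codes = np.array([[1, 2], [3, scheme.ignore_code]])
        out = remap_to_locator(LabelMask(codes, scheme), stroma_as_tumor=True)
        np.testing.assert_array_equal(
            out.codes, [[1, 1], [2, LOCATOR_SCHEME.ignore_code]]
        )

    def test_locator_recovers_tumor_region(self, scheme):
        slides = synthetic_annotated(scheme, 4)
        cfg = TrainConfig(backend_id="centroid")
        locator = train_tumor_locator(slides, cfg, patch_size=16)
        slide = slides[0]
        pred = predict_slide_mask(locator, slide, 16)
        ref = remap_to_locator(slide.label_mask)
        p, r = pred.codes == 1, ref.codes == 1
        dice = 2 * np.logical_and(p, r).sum() / (p.sum() + r.sum())
        assert dice >= 0.95
        assert set(np.unique(pred.codes)) <= {0, 1, 2}


class _ScriptedBackend:
    """Predicts a constant code per call, from a script list."""

    backend_id = "scripted"

    def __init__(self, script):
        self.script = list(script)
        self.calls = 0

    def predict_mask(self, pixels):
        code = self.script[min(self.calls, len(self.script) - 1)]
        self.calls += 1
        return np.full(pixels.shape[:2], code, dtype=np.int64)


class TestPredictSlideMask:
    def _slide(self, scheme, size=32):
        img = np.zeros((size, size, 3), dtype=np.uint8)
        return SlideRecord("s", img, 1.0)

    def test_mosaic_no_overlap(self, scheme):
        slide = self._slide(scheme)
        handle = ModelHandle("m", "supervised", ["s"], 1.0, _ScriptedBackend([3]), scheme)
        mask = predict_slide_mask(handle, slide, 16)
        assert (mask.codes == 3).all()

    def test_tumor_persists_under_overlap(self, scheme):
        # stride < patch: first tile writes tumor, later overlapping tiles
        # write benign; shared pixels must stay tumor
        slide = self._slide(scheme, size=24)
        handle = ModelHandle(
            "m", "supervised", ["s"], 1.0,
            _ScriptedBackend([1, 3, 3, 3]), scheme,
        )
        mask = predict_slide_mask(handle, slide, 16, stride=8)
        assert (mask.codes[:16, :16] == 1).all()
        assert (mask.codes[16:, 16:] == 3).all()

    def test_benign_overwritten_by_later_tile(self, scheme):
        slide = self._slide(scheme, size=24)
        handle = ModelHandle(
            "m", "supervised", ["s"], 1.0,
            _ScriptedBackend([3, 4, 4, 4]), scheme,
        )
        mask = predict_slide_mask(handle, slide, 16, stride=8)
        # non-tumor codes are overwritten where tiles overlap
        assert (mask.codes[:8, 8:16] == 4).all()
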