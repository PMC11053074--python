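"""Scene generator: determinism, ground-truth consistency, degradations."""

import numpy as np
import pytest
from scipy import ndimage

from verdure.io_formats import (labelme_read, mask_read, rasterize_polygon,
                                voc_read)
from verdure.synthetic import (SceneConfig, degrade_image, generate_dataset,
                               generate_scene)


def laplacian_variance(image: np.ndarray) -> float:
    grey = np.asarray(image, float).mean(axis=-1)
    return float(ndimage.laplace(grey).var())


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SceneConfig(image_size=64), seed=7)


class TestGenerateScene:
    def test_deterministic_given_seed(self, scene):
        again = generate_scene(SceneConfig(image_size=64), seed=7)
        np.testing.assert_array_equal(scene.image, again.image)
        np.testing.assert_array_equal(scene.mask, again.mask)
        assert scene.boxes == again.boxes

    def test_mask_is_rasterization_of_stored_polygon(self, scene):
        rendered = rasterize_polygon(scene.polygons[0][1], 64, 64)
        np.testing.assert_array_equal(rendered, scene.mask)

    def test_coverage_close_to_requested(self):
        sc = generate_scene(
            SceneConfig(image_size=64, greenery_coverage=(0.6, 0.6)), seed=3)
        assert abs(sc.mask.mean() - 0.6) <= 0.05

    def test_boxes_inside_image_and_on_greenery(self, scene):
        for _, (x0, y0, x1, y1) in scene.boxes:
            assert 0 <= x0 < x1 <= 64 and 0 <= y0 < y1 <= 64
            box_mask = scene.mask[int(y0):int(y1), int(x0):int(x1)]
            assert box_mask.mean() >= 0.9

    def test_clear_label_without_degradation(self, scene):
        assert scene.label == "clear"
        assert scene.meta["degradation"] == "none"


class TestDegradeImage:
    def test_zero_strength_is_identity(self, scene):
        for kind in ("gaussian_blur", "motion_blur", "low_light", "noise"):
            np.testing.assert_array_equal(
                degrade_image(scene.image, kind, 0.0), scene.image)

    def test_low_light_strength_one_halves_mean(self, scene):
        dark = degrade_image(scene.image, "low_light", 1.0)
        assert dark.astype(float).mean() == pytest.approx(
            scene.image.astype(float).mean() / 2, rel=0.02)

    def test_blur_reduces_sharpness_monotonically(self, scene):
        variances = [laplacian_variance(
            degrade_image(scene.image, "gaussian_blur", s)) for s in (1, 2, 4)]
        assert variances[0] > variances[1] > variances[2]
        assert variances[0] < laplacian_variance(scene.image)

    def test_smoothing_kinds_lower_sharpness(self):
        for kind in ("gaussian_blur", "motion_blur", "low_light"):
            sc = generate_scene(
                SceneConfig(image_size=64, degradation=kind), seed=11)
            assert sc.label == "blurry"
            clear = generate_scene(SceneConfig(image_size=64), seed=11)
            assert laplacian_variance(sc.image) < laplacian_variance(clear.image)

    def test_unknown_kind_rejected(self, scene):
        with pytest.raises(ValueError):
            degrade_image(scene.image, "fog", 1.0)


class TestGenerateDataset:
    def test_layout_counts_and_determinism(self, tmp_path):
        cfg = SceneConfig(image_size=64)
        out1 = generate_dataset(8, 2, cfg, seed=5, out_dir=tmp_path / "a")
        out2 = generate_dataset(8, 2, cfg, seed=5, out_dir=tmp_path / "b")
        rows = out1["rows"]
        assert len(rows) == 10
        assert sum(r["label"] == "clear" for r in rows) == 8
        # per-image completeness: mask + labelme + voc all exist and agree
        for r in rows:
            mask = mask_read(tmp_path / "a" / r["mask"])
            rec = labelme_read(tmp_path / "a" / r["labelme"])
            rendered = rasterize_polygon(rec.polygons[0][1], 64, 64)
            np.testing.assert_array_equal(rendered, mask)
            voc = voc_read(tmp_path / "a" / r["voc"])
            assert all(label in ("water_deficient", "dead")
                       for label, _ in voc.boxes)
        # same seed -> byte-identical artifacts
        for r in rows:
            a = (tmp_path / "a" / r["image"]).read_bytes()
            b = (tmp_path / "b" / r["image"]).read_bytes()
            assert a == b
        assert (tmp_path / "a" / "splits.json").exists()

    def test_split_partitions_dataset(self, tmp_path):
        out = generate_dataset(4, 2, SceneConfig(image_size=64), seed=1,
                               out_dir=tmp_path / "d")
        split = out["split"]
        union = sorted(split.train + split.val + split.test)
        assert union == list(range(6))
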