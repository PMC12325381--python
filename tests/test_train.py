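"""Training harness: schedule, metrics, heatmaps, determinism."""

import numpy as np
import pytest

from keyfg.coco import Annotation, Category, DetectionDataset, ImageInfo
from keyfg.model import KeyFgDetector, ModelConfig
from keyfg.synthetic import SceneSpec, generate_dataset
from keyfg.train import (
    TrainConfig,
    cosine_lr,
    evaluate,
    export_heatmap,
    predict_dataset,
    train,
)

DESK_SPEC = SceneSpec(height=64, width=64, n_objects=1, alpha=0.8,
                      min_radius=8, max_radius=12)


class TestCosineSchedule:
    def test_endpoints(self):
        assert cosine_lr(0, 50, 0.001) == pytest.approx(0.001)
        assert cosine_lr(49, 50, 0.001) <= 1e-5

    def test_monotone_decay(self):
        lrs = [cosine_lr(e, 30, 0.001) for e in range(30)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


def _fixture_dataset():
    """3 GT boxes across 2 images with hand-computable metrics."""
    ds = DetectionDataset(categories=[Category(1, "pest")])
    ds.images = [ImageInfo(id=1, width=100, height=100),
                 ImageInfo(id=2, width=100, height=100)]
    ds.annotations = [
        Annotation(id=1, image_id=1, bbox=(10, 10, 20, 20), category_id=1),
        Annotation(id=2, image_id=1, bbox=(60, 60, 20, 20), category_id=1),
        Annotation(id=3, image_id=2, bbox=(40, 40, 20, 20), category_id=1),
    ]
    return ds


def _det(box, score=1.0):
    return {"score": score, "label": 0, "box_xyxy": np.array(box) / 100.0}


class TestEvaluate:
    def test_perfect_predictions(self):
        ds = _fixture_dataset()
        preds = {
            1: [_det([10, 10, 30, 30]), _det([60, 60, 80, 80])],
            2: [_det([40, 40, 60, 60])],
        }
        m = evaluate(preds, ds)
        assert m.ap == pytest.approx(1.0)
        assert m.ap50 == pytest.approx(1.0)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(1.0)

    def test_no_predictions(self):
        m = evaluate({}, _fixture_dataset())
        assert m.ap == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_one_tp_one_fp_one_fn(self):
        # one exact hit, one far miss, one GT undetected
        preds = {
            1: [_det([10, 10, 30, 30], 0.9), _det([0, 0, 5, 5], 0.8)],
            2: [],
        }
        m = evaluate(preds, _fixture_dataset())
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1 / 3)
        f1 = 2 * 0.5 * (1 / 3) / (0.5 + 1 / 3)
        assert m.f1 == pytest.approx(f1)

    def test_ap_never_exceeds_ap50(self, rng):
        preds = {
            1: [_det([10 + rng.integers(0, 6), 10, 32, 31], 0.7)],
            2: [_det([41, 40, 61, 59], 0.6)],
        }
        m = evaluate(preds, _fixture_dataset())
        assert m.ap <= m.ap50 + 1e-12

    def test_empty_ground_truth_rejected(self):
        ds = _fixture_dataset()
        ds.annotations = []
        with pytest.raises(ValueError):
            evaluate({}, ds)


class TestTrainLoop:
    def test_same_seed_identical_first_epoch(self):
        ds = generate_dataset(4, DESK_SPEC, seed=2)
        tc = TrainConfig(epochs=1, seed=11)
        _, log1 = train(tc, ds)
        _, log2 = train(tc, ds)
        assert log1[0]["total"] == log2[0]["total"]

    def test_ablation_flags_reach_model_config(self):
        tc = TrainConfig(maskmlp=False, dn=False, dropkey=False, fgsp=False)
        cfg = tc.apply_flags(ModelConfig())
        assert not (cfg.use_maskmlp or cfg.use_dn or cfg.use_dropkey or cfg.use_fgsp)

    def test_empty_dataset_rejected(self):
        ds = DetectionDataset(categories=[Category(1, "c")],
                              images=[ImageInfo(id=1, width=64, height=64)])
        with pytest.raises(ValueError):
            train(TrainConfig(epochs=1), ds)


class TestHeatmap:
    def test_output_geometry_and_range(self, rng):
        model = KeyFgDetector(ModelConfig(), seed=0)
        img = rng.integers(0, 256, size=(64, 64, 3))
        maps = export_heatmap(model, img, ("res3", "res4", "res5"))
        for hm in maps.values():
            assert hm.shape == (64, 64)
            assert hm.min() >= 0.0 and hm.max() <= 1.0

    def test_constant_image_constant_heatmap_biasfree(self):
        from keyfg.model.backbone import TinyBackbone

        model = KeyFgDetector(ModelConfig(), seed=0)
        model.backbone = TinyBackbone(np.random.default_rng(0), bias=False)
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        maps = export_heatmap(model, img, ("res4",))
        hm = maps["res4"]
        assert np.allclose(hm, hm.flat[0])

    def test_unknown_layer_rejected(self, rng):
        model = KeyFgDetector(ModelConfig(), seed=0)
        with pytest.raises(KeyError):
            export_heatmap(model, rng.integers(0, 256, size=(64, 64, 3)),
                           ("res9",))

    def test_overlay_files_written(self, rng, tmp_path):
        model = KeyFgDetector(ModelConfig(), seed=0)
        img = rng.integers(0, 256, size=(64, 64, 3))
        export_heatmap(model, img, ("res3",), out_dir=tmp_path)
        assert (tmp_path / "heatmap_res3.png").exists()


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        from keyfg.model.detector import load_checkpoint, save_checkpoint

        cfg = ModelConfig()
        model = KeyFgDetector(cfg, seed=4)
        save_checkpoint(model, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt", cfg)
        img = rng.integers(0, 256, size=(64, 64, 3))
        a = model.forward(img)["pred_boxes"]
        b = back.forward(img)["pred_boxes"]
        assert np.allclose(a, b)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(n_heads=4, keep_ratio=0.5, dn_groups=7)
        cfg.to_yaml(tmp_path / "m.yaml")
        back = ModelConfig.from_yaml(tmp_path / "m.yaml")
        assert back == cfg
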