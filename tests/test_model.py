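"""Dual-view model: loss closed forms, gating, contracts, overfit training."""

import numpy as np
import pytest

from petbrainx import boxes, model, phantom
from petbrainx.model import ModelConfig, TrainConfig, loss_total


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        vec = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        # up to the 1e-7 clamp on log arguments
        assert loss_total(1.0, vec, 1.0, vec) == pytest.approx(0.0, abs=1e-5)
        assert loss_total(0.0, vec, 0.0, vec) == pytest.approx(0.0, abs=1e-5)

    def test_uncertain_existence_closed_form(self):
        # Y=1, p=0.5, exact box: alpha * ln 2 = 6.9315
        vec = np.zeros(6)
        assert loss_total(0.5, vec, 1.0, vec, alpha=10, beta=1) == pytest.approx(
            10 * np.log(2), rel=1e-6
        )

    def test_absent_brain_gates_box_term(self):
        # Y=0, p=0.1: 10 * (-ln 0.9); the box error must contribute nothing
        wild = np.full(6, 123.0)
        expected = 10 * -np.log(0.9)
        assert loss_total(0.1, wild, 0.0, np.zeros(6)) == pytest.approx(expected, rel=1e-6)
        assert loss_total(0.1, wild, 0.0, np.zeros(6)) == pytest.approx(
            loss_total(0.1, np.zeros(6), 0.0, np.zeros(6))
        )

    def test_alpha_zero_ignores_existence_errors(self):
        vec = np.zeros(6)
        assert loss_total(0.01, vec, 1.0, vec, alpha=0.0, beta=1.0) == pytest.approx(0.0)

    def test_extreme_probability_clamped(self):
        v = loss_total(0.0, np.zeros(6), 1.0, np.zeros(6))
        assert np.isfinite(v) and v > 0

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, 4)
            y = rng.integers(0, 2, 4).astype(float)
            bp, bt = rng.uniform(0, 1, (4, 6)), rng.uniform(0, 1, (4, 6))
            assert loss_total(p, bp, y, bt) >= 0.0


class TestForwardContract:
    def test_output_shapes_range_and_determinism(self, rng):
        m = model.build_model(ModelConfig(fc_dim=32, channels=(4, 8)), seed=0)
        ant = rng.uniform(0, 255, (3, 224, 224)).astype(np.float32)
        lat = rng.uniform(0, 255, (3, 224, 224)).astype(np.float32)
        p, b = m.forward(ant, lat)
        assert p.shape == (3,) and b.shape == (3, 6)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all((b >= 0) & (b <= 1))
        p2, b2 = m.forward(ant, lat)
        assert np.array_equal(p, p2) and np.array_equal(b, b2)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(backbone="resnet151")

    def test_save_load_roundtrip(self, tmp_path, rng):
        m = model.build_model(ModelConfig(fc_dim=32, channels=(4,)), seed=1)
        path = tmp_path / "ckpt.npz"
        m.save(path)
        m2 = model.DualViewModel.load(path)
        ant = rng.uniform(0, 255, (2, 224, 224)).astype(np.float32)
        lat = rng.uniform(0, 255, (2, 224, 224)).astype(np.float32)
        assert np.array_equal(m.forward(ant, lat)[1], m2.forward(ant, lat)[1])


class TestTraining:
    def test_overfit_decreases_loss_and_nails_existence(self, tiny_trained_model):
        m, ds, hist = tiny_trained_model
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        ev = model.evaluate(m, ds)
        assert ev["accuracy"] == 1.0

    def test_overfit_boxes_localize_brain(self, tiny_trained_model):
        m, ds, _ = tiny_trained_model
        ev = model.evaluate(m, ds)
        assert ev["iou_mean"] > 0.5

    def test_training_is_seed_deterministic(self):
        cohort = phantom.generate_cohort(6, phantom.CohortSpec(truncated_fraction=0.5),
                                         seed=3)
        ds = model.make_dataset(cohort)
        cfg = TrainConfig.desk_scale(seed=4, epochs=5)
        _, h1 = model.train(ds, ModelConfig(fc_dim=32, channels=(4, 8)), cfg)
        _, h2 = model.train(ds, ModelConfig(fc_dim=32, channels=(4, 8)), cfg)
        assert h1["train_loss"].iloc[-1] == pytest.approx(
            h2["train_loss"].iloc[-1], rel=1e-6
        )

    def test_empty_dataset_rejected_and_single_class_warns(self, caplog):
        with pytest.raises(ValueError):
            model.train([], ModelConfig(fc_dim=32, channels=(4,)))
        cohort = phantom.generate_cohort(3, phantom.CohortSpec(truncated_fraction=0.0),
                                         seed=3)
        ds = model.make_dataset(cohort)
        import logging

        with caplog.at_level(logging.WARNING):
            model.train(ds, ModelConfig(fc_dim=32, channels=(4,)),
                        TrainConfig.desk_scale(epochs=1))
        assert any("single existence class" in r.message for r in caplog.records)


class TestPredictEvaluate:
    def test_truncated_phantom_predicts_absent(self, tiny_trained_model):
        m, _, _ = tiny_trained_model
        vol, truth = phantom.generate_phantom(
            phantom.PhantomSpec(brain_truncation_fraction=0.5, seed=123)
        )
        out, box = model.predict(m, vol)
        assert not truth.whole_brain_present
        assert box is None or out.p_exist >= 0.5  # box emitted only with p >= 0.5
        assert out.p_exist < 0.5

    def test_full_phantom_box_decodes_within_grid(self, tiny_trained_model):
        m, ds, _ = tiny_trained_model
        vol, truth = phantom.generate_phantom(phantom.PhantomSpec(seed=0))
        out, box = model.predict(m, vol)
        if box is not None:
            assert all(mc >= 0 for mc in box.min_corner)
            assert all(M <= g for M, g in zip(box.max_corner, vol.shape))

    def test_evaluate_matches_hand_computation(self, rng):
        m = model.build_model(ModelConfig(fc_dim=32, channels=(4, 8)), seed=5)
        cohort = phantom.generate_cohort(5, phantom.CohortSpec(truncated_fraction=0.4),
                                         seed=9)
        ds = model.make_dataset(cohort)
        ev = model.evaluate(m, ds)
        ants = np.stack([s.anterior.pixels for s in ds])
        lats = np.stack([s.lateral.pixels for s in ds])
        p, b = m.forward(ants, lats)
        acc = np.mean([(p[i] >= 0.5) == ds[i].exists for i in range(5)])
        ious = [
            boxes.iou3d(boxes.decode(b[i], ds[i].grid_shape), ds[i].truth_box)
            for i in range(5)
            if ds[i].exists and p[i] >= 0.5
        ]
        assert ev["accuracy"] == pytest.approx(acc)
        if ious:
            assert ev["iou_mean"] == pytest.approx(np.mean(ious))
            if len(ious) > 1:
                assert ev["iou_sd"] == pytest.approx(np.std(ious, ddof=1))


class TestBoxVectorAugmentation:
    def test_identity_geometry_preserves_vector(self):
        vol, truth = phantom.generate_phantom(phantom.PhantomSpec(seed=2))
        s = model.make_sample(vol, truth)
        out = model.transform_box_vector(s.anterior, s.lateral, s.box_vector,
                                         1.0, 0.0, 0.0, 0.0)
        assert np.allclose(out, s.box_vector, atol=1e-9)

    def test_row_translation_moves_z_only(self):
        vol, truth = phantom.generate_phantom(phantom.PhantomSpec(seed=2))
        s = model.make_sample(vol, truth)
        out = model.transform_box_vector(s.anterior, s.lateral, s.box_vector,
                                         1.0, 5.0, 0.0, 0.0)
        # +5 px down the image is toward inferior: z min decreases
        assert out[2] < s.box_vector[2]
        assert np.allclose(out[[0, 1, 3, 4]], s.box_vector[[0, 1, 3, 4]], atol=1e-9)
        assert out[5] == pytest.approx(s.box_vector[5], abs=1e-9)
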