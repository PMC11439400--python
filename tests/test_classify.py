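import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seston import classify
from seston.classify import ConfidenceVector, TrainConfig, top5_truncate


class TestTop5Truncate:
    def test_six_nonzero_entries_sixth_zeroed(self):
        d = np.array([0.5, 0.2, 0.1, 0.08, 0.07, 0.05, 0, 0, 0, 0, 0])
        expected = np.array([0.5, 0.2, 0.1, 0.08, 0.07, 0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(top5_truncate(d), expected)

    def test_one_hot_unchanged(self):
        d = np.zeros(11)
        d[4] = 1.0
        np.testing.assert_array_equal(top5_truncate(d), d)

    def test_uniform_ties_break_to_lowest_class_index(self):
        d = np.full(11, 1 / 11)
        out = top5_truncate(d)
        np.testing.assert_allclose(out[:5], 1 / 11)
        np.testing.assert_array_equal(out[5:], 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            top5_truncate(np.zeros(10))

    def test_no_renormalization(self):
        d = np.array([0.3, 0.2, 0.1, 0.08, 0.07, 0.05, 0.05, 0.05, 0.05, 0.03, 0.02])
        out = top5_truncate(d)
        assert out.sum() == pytest.approx(0.75)  # kept entries keep raw values

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=11, max_size=11))
    def test_idempotent_and_never_increases(self, dist):
        d = np.asarray(dist)
        once = top5_truncate(d)
        np.testing.assert_array_equal(top5_truncate(once), once)
        assert np.all(once <= d)
        assert np.count_nonzero(once) <= 5
        # the 5 largest entries survive exactly
        top5_idx = np.argsort(-d, kind="stable")[:5]
        np.testing.assert_array_equal(once[top5_idx], d[top5_idx])


class TestTrainConfig:
    def test_defaults(self):
        cfg = TrainConfig()
        assert (cfg.image_side_px, cfg.epochs, cfg.batch_size) == (320, 15, 16)

    @pytest.mark.parametrize("kwargs", [dict(epochs=0), dict(batch_size=-1),
                                        dict(image_side_px=0), dict(backbone="resnet")])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestClassifier:
    def test_validation_accuracy_beats_chance(self, trained_model):
        assert trained_model.training_log
        assert trained_model.training_log[-1]["val_accuracy"] > 1 / 11

    def test_training_deterministic_under_seed(self, small_dataset, small_splits):
        records, _ = small_dataset
        by_id = {r.image_id: r for r in records}
        train = [by_id[i] for i in small_splits["train"]["image_id"]]
        sigs = []
        for _ in range(2):
            m = classify.train_classifier(
                train, small_splits["train"], config=TrainConfig(seed=99)
            )
            sigs.append(m.coef_signature())
        np.testing.assert_array_equal(sigs[0], sigs[1])

    def test_missing_class_error_lists_absent_labels(self, small_dataset, small_splits):
        records, _ = small_dataset
        manifest = small_splits["train"]
        subset = manifest[manifest["class_index"] != 4]
        by_id = {r.image_id: r for r in records}
        recs = [by_id[i] for i in subset["image_id"]]
        with pytest.raises(ValueError, match="5-9.99"):
            classify.TurbidityClassifier(recs, subset)

    def test_infer_returns_valid_truncated_vectors(self, trained_model, small_dataset):
        records, _ = small_dataset
        vecs = trained_model.infer(records[:10])
        assert len(vecs) == 10
        for v in vecs:
            v.validate()
            assert np.count_nonzero(v.x) <= 5
            assert v.x.sum() <= 1.0 + 1e-9

    def test_unreadable_image_skipped_batch_continues(self, trained_model, small_dataset):
        records, _ = small_dataset
        bad = classify.ImageRecord(image_id="bad", pixels=np.full((8, 8, 3), 2.0),
                                   fnu_true=1.0)
        vecs = trained_model.infer([records[0], bad, records[1]])
        assert [v.image_id for v in vecs] == [records[0].image_id, records[1].image_id]

    def test_single_image_wrapper(self, trained_model, small_dataset):
        records, _ = small_dataset
        v = classify.infer_confidences(trained_model, records[0])
        assert isinstance(v, ConfidenceVector)
        assert v.image_id == records[0].image_id

    def test_save_load_round_trip(self, trained_model, small_dataset, tmp_path):
        records, _ = small_dataset
        path = tmp_path / "model.joblib"
        trained_model.save(path)
        loaded = classify.TurbidityClassifier.load(path)
        a = trained_model.predict_proba(records[:5])
        b = loaded.predict_proba(records[:5])
        np.testing.assert_array_equal(a, b)
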