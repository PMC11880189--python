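"""Dataset balancing/splitting, training contracts, rounding and metrics."""

import dataclasses
import warnings

import numpy as np
import pytest

import mnquant as m
from mnquant import model as M


def _labels(histogram: dict[int, int]) -> np.ndarray:
    return np.concatenate([np.full(n, k) for k, n in histogram.items()])


class TestBalancing:
    def test_downsampling_and_outlier_removal(self):
        y = _labels({0: 100, 1: 50, 2: 10, 4: 2})
        idx = M.balance_indices(y, seed=0)
        out = y[idx]
        assert out.size == 120
        hist = dict(zip(*np.unique(out, return_counts=True)))
        assert hist == {0: 60, 1: 50, 2: 10}
        assert np.mean(out == 0) == 0.5

    def test_already_balanced_set_is_unchanged_up_to_shuffle(self):
        y = _labels({0: 5, 1: 5})
        idx = M.balance_indices(y, seed=1)
        assert sorted(idx) == list(range(10))

    def test_small_set_with_high_counts(self):
        y = _labels({0: 10, 3: 1, 5: 1})
        out = y[M.balance_indices(y, seed=2)]
        assert sorted(out.tolist()) == [0, 3]

    def test_no_nonzero_labels_is_an_error(self):
        with pytest.raises(ValueError, match="non-zero"):
            M.balance_indices(np.zeros(10, dtype=int))

    def test_zero_deficit_keeps_all_zeros_with_warning(self):
        y = _labels({0: 3, 1: 8})
        with pytest.warns(UserWarning, match="keeping all zeros"):
            out = y[M.balance_indices(y, seed=0)]
        assert sorted(out.tolist()) == [0, 0, 0] + [1] * 8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_fifty_percent_zeros_whenever_zeros_in_excess(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice(6, size=500, p=[0.7, 0.15, 0.08, 0.04, 0.02, 0.01])
        out = y[M.balance_indices(y, seed=seed)]
        assert np.mean(out == 0) == 0.5
        assert out.max() <= 3


class TestSplitting:
    def test_ninety_ten_split_arithmetic(self):
        y = np.tile([0, 1], 6000)  # 12,000 patches
        train_idx, val_idx = M.split_dataset(y, val_fraction=0.10, seed=0)
        assert len(train_idx) == 10800 and len(val_idx) == 1200
        assert np.intersect1d(train_idx, val_idx).size == 0

    def test_kfold_partitions_every_sample_once(self):
        y = np.repeat([0, 1, 2, 3], [200, 120, 60, 20])
        folds = M.split_dataset(y, k_folds=10, seed=0)
        seen = np.concatenate([val for _, val in folds])
        assert sorted(seen.tolist()) == list(range(y.size))

    def test_kfold_stratification_within_two_patches(self):
        y = np.repeat([0, 1, 2, 3], [200, 120, 60, 20])
        folds = M.split_dataset(y, k_folds=10, seed=0)
        for _, val in folds:
            for cls, total in zip(*np.unique(y, return_counts=True)):
                expected = total / 10
                got = np.sum(y[val] == cls)
                assert abs(got - expected) <= 2

    def test_too_many_folds_for_class_size_is_an_error(self):
        y = np.repeat([0, 1], [50, 3])
        with pytest.raises(ValueError):
            M.split_dataset(y, k_folds=10, seed=0)


class TestRounding:
    @pytest.mark.parametrize("raw,expected", [
        (1.4, 1), (1.5, 2), (2.5, 3), (0.49, 0), (-0.2, 0), (-1.7, 0), (3.6, 4),
    ])
    def test_round_half_away_then_clamp(self, raw, expected):
        count = max(0, int(M.round_half_away_from_zero(np.asarray(raw))))
        assert count == expected

    def test_rounding_is_idempotent(self):
        raw = np.array([-0.6, 0.2, 0.5, 1.49, 1.5, 2.7])
        once = M.round_half_away_from_zero(raw)
        np.testing.assert_array_equal(M.round_half_away_from_zero(once.astype(float)), once)


@pytest.fixture(scope="module")
def tiny_patches():
    rng = np.random.default_rng(9)
    x = rng.random((60, 32, 32)).astype(np.float32)
    y = rng.integers(0, 4, size=60)
    return x, y


@pytest.fixture(scope="module")
def tiny_spec():
    return M.ModelSpec(conv_channels=(4, 8), n_pools=2)


class TestTrainingContracts:
    def test_predict_counts_agree_with_external_rounding(self, tiny_patches, tiny_spec):
        x, _ = tiny_patches
        model = M.CountingCNN(tiny_spec, dropout=0.0, seed=0)
        trained = M.TrainedModel(model=model, spec=tiny_spec,
                                 config=M.TrainingConfig(), input_size=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = M.predict_counts(trained, x)
        raw = trained.predict_raw(x)
        for r, v in zip(recs, raw):
            assert r.raw_count == pytest.approx(float(v))
            assert r.count == max(0, int(np.sign(v) * np.floor(abs(v) + 0.5)))

    def test_identical_seeds_give_identical_validation_loss(self, tiny_patches, tiny_spec):
        x, y = tiny_patches
        cfg = M.TrainingConfig(max_epochs=3, seed=123)
        _, h1 = M.train(x[:40], y[:40], x[40:], y[40:], tiny_spec, cfg)
        _, h2 = M.train(x[:40], y[:40], x[40:], y[40:], tiny_spec, cfg)
        assert h1["val_loss"].tolist() == h2["val_loss"].tolist()

    def test_small_set_is_memorized(self, tiny_spec):
        """Capacity check: a memorizable 50-patch set (label = number of
        bright disks) used as both train and val overfits to a training MSE
        below 0.05 within 100 epochs (no augmentation)."""
        rng = np.random.default_rng(4)
        x = np.zeros((50, 32, 32), dtype=np.float32)
        y = rng.integers(0, 4, size=50)
        yy, xx = np.mgrid[0:32, 0:32]
        for i, k in enumerate(y):
            for _ in range(k):
                cy, cx = rng.integers(4, 28, size=2)
                x[i][(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = 1.0
        cfg = M.TrainingConfig(max_epochs=100, augment=False, dropout=0.0,
                               seed=4, batch_size=8)
        _, hist = M.train(x, y, x, y, tiny_spec, cfg)
        # val here IS the training set, evaluated in inference mode (fixed
        # batch-norm statistics), i.e. the deterministic training MSE
        assert hist["val_loss"].iloc[-1] < 0.05

    def test_mismatched_patch_size_rejected(self, tiny_patches, tiny_spec):
        x, y = tiny_patches
        cfg = M.TrainingConfig(max_epochs=1, seed=0)
        trained, _ = M.train(x[:40], y[:40], x[40:], y[40:], tiny_spec, cfg)
        with pytest.raises(ValueError, match="trained on"):
            trained.predict_raw(np.zeros((2, 64, 64), dtype=np.float32))

    def test_save_load_round_trip(self, tiny_patches, tiny_spec, tmp_path):
        x, y = tiny_patches
        cfg = M.TrainingConfig(max_epochs=1, seed=0)
        trained, _ = M.train(x[:40], y[:40], x[40:], y[40:], tiny_spec, cfg)
        trained.save(tmp_path / "model")
        loaded = M.TrainedModel.load(tmp_path / "model")
        np.testing.assert_array_equal(trained.predict_raw(x), loaded.predict_raw(x))

    def test_efficientnet_backbone_is_unsupported(self):
        with pytest.raises(NotImplementedError, match="small_cnn"):
            M.ModelSpec(backbone="efficientnet_family").validate()


def _hand_metrics(y_true, y_pred):
    """Textbook per-class precision/recall/F1 and weighted F1."""
    classes = sorted(set(y_true) | set(y_pred))
    f1s, weights = [], []
    per_class = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = (prec, rec)
        f1s.append(f1)
        weights.append(sum(1 for t in y_true if t == c))
    wf1 = sum(f * w for f, w in zip(f1s, weights)) / sum(weights)
    return wf1, per_class


class TestEvaluation:
    def test_perfect_predictions(self):
        ev = M.evaluate_classification([0, 1, 2, 3], [0, 1, 2, 3])
        assert ev["f1_weighted"] == 1.0 and ev["mcc"] == 1.0

    def test_binary_chance_level_mcc_is_zero(self):
        # contingency table TP=1, FP=1, FN=1, TN=1 -> MCC 0 in closed form
        ev = M.evaluate_classification([0, 0, 1, 1], [0, 1, 0, 1])
        assert ev["mcc"] == pytest.approx(0.0)

    def test_single_class_convention(self):
        with pytest.warns(UserWarning, match="single-class"):
            ev = M.evaluate_classification([1, 1, 1], [1, 1, 1])
        assert ev["mcc"] == 0.0 and ev["f1_weighted"] == 1.0

    def test_weighted_f1_and_per_class_match_hand_computation(self):
        y_true = [0, 1, 2, 1, 0, 2, 1, 3, 0, 1]
        y_pred = [0, 2, 2, 1, 0, 1, 1, 3, 1, 0]
        ev = M.evaluate_classification(y_true, y_pred)
        wf1, per_class = _hand_metrics(y_true, y_pred)
        assert ev["f1_weighted"] == pytest.approx(wf1)
        for i, c in enumerate(ev["classes"]):
            prec, rec = per_class[int(c)]
            assert ev["precision_per_class"][i] == pytest.approx(prec)
            assert ev["recall_per_class"][i] == pytest.approx(rec)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            M.evaluate_classification([], [])

    def test_average_precision_from_raw_scores(self):
        # perfect ranking of positives -> AP 1.0
        ev = M.evaluate_classification([0, 0, 1, 1], [0, 0, 1, 1],
                                       raw_scores=[0.1, 0.2, 0.9, 1.4])
        assert ev["average_precision_binary"] == 1.0


class TestSaliency:
    def test_contract_shape_range_and_peak(self, tiny_spec):
        model = M.CountingCNN(tiny_spec, dropout=0.0, seed=1)
        trained = M.TrainedModel(model=model, spec=tiny_spec,
                                 config=M.TrainingConfig(), input_size=32)
        rng = np.random.default_rng(2)
        patch = rng.random((32, 32)).astype(np.float32)
        cam = M.saliency_map(trained, patch)
        assert cam.shape == patch.shape
        assert cam.min() >= 0.0 and cam.max() <= 1.0
        assert cam.max() == pytest.approx(1.0) or cam.max() == 0.0

    def test_constant_zero_patch_gives_defined_output(self, tiny_spec):
        model = M.CountingCNN(tiny_spec, dropout=0.0, seed=1)
        trained = M.TrainedModel(model=model, spec=tiny_spec,
                                 config=M.TrainingConfig(), input_size=32)
        cam = M.saliency_map(trained, np.zeros((32, 32), dtype=np.float32))
        assert cam.shape == (32, 32)
        assert np.all(np.isfinite(cam))


def test_training_config_validation():
    with pytest.raises(ValueError):
        M.TrainingConfig(max_epochs=0).validate()
    with pytest.raises(ValueError):
        M.TrainingConfig(lr_factor=1.5).validate()
    with pytest.raises(ValueError):
        dataclasses.replace(M.TrainingConfig(), dropout=1.0).validate()
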