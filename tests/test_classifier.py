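"""CNN construction, training behaviour, metrics and majority voting."""

import warnings

import numpy as np
import pytest

from bandrep import nn
from bandrep.classifier import (
    build_model,
    count_parameters,
    evaluate,
    load_model,
    majority_vote,
    predict_labels,
    save_model,
    train,
)
from bandrep.datamodel_io import EXERCISES
from bandrep.synthetic import SimulationConfig, simulate_classification_corpus


@pytest.fixture(scope="module")
def small_corpus():
    return simulate_classification_corpus(
        30, SimulationConfig(seed=5, noise_sd=2.0), variant="imu")


@pytest.fixture(scope="module")
def trained(small_corpus):
    model = build_model("imu", seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = train(model, small_corpus, seed=5, epochs=8)
    return model, result


class TestArchitecture:
    def test_kernel_sizes_uniquely_solve_conv_param_counts(self):
        # brute force over square kernels: which k gives the published counts?
        conv1 = [k for k in range(1, 11) if k * k * 1 * 32 + 32 == 832]
        conv2 = [k for k in range(1, 11) if k * k * 32 * 64 + 64 == 8256]
        assert conv1 == [5] and conv2 == [2]

    @pytest.mark.parametrize("variant,dense1", [
        ("imu", 1_921_000), ("joints", 11_521_000),
        ("upper_joints", 3_841_000), ("imu_joints", 14_401_000)])
    def test_dense1_parameter_counts(self, variant, dense1):
        table = dict((name, params) for name, _, params
                     in count_parameters(build_model(variant)))
        assert table["dense_1"] == dense1
        assert table["dense_2"] == 6006
        assert table["conv2d_1"] == 832
        assert table["conv2d_2"] == 8256

    def test_pool_and_dropout_layers_have_no_parameters(self):
        for name, _, params in count_parameters(build_model("imu")):
            if "pool" in name or "dropout" in name or name == "flatten":
                assert params == 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_model("audio")


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end gradient of a tiny conv/pool/dense net."""
        rng = np.random.default_rng(0)
        layers = [
            nn.Conv2DSame(1, 2, 3, rng=rng, name="c"),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Flatten(),
            nn.Dense(2 * 3 * 2, 3, rng=rng, name="d"),
        ]
        model = nn.Sequential(layers, input_shape=(4, 6, 1))
        x = rng.normal(size=(2, 4, 6, 1)).astype(np.float64)
        onehot = np.eye(3)[[0, 2]]

        logits = model.forward(x, training=False)
        _, dlogits = nn.softmax_cross_entropy(logits, onehot)
        model.backward(dlogits)

        eps = 1e-3
        for p, g in zip(model.parameters, model.gradients):
            flat = p.ravel()
            idx = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = nn.softmax_cross_entropy(
                    model.forward(x, training=False), onehot)
                flat[i] = orig - eps
                lm, _ = nn.softmax_cross_entropy(
                    model.forward(x, training=False), onehot)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(numeric, abs=2e-3)


class TestTraining:
    def test_heldout_metrics_deterministic_given_seed(self, small_corpus):
        accs = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = train(build_model("imu", seed=3), small_corpus,
                          seed=3, epochs=2)
            accs.append(r.metrics.accuracy)
        assert accs[0] == accs[1]

    def test_single_class_batch_rejected(self, small_corpus):
        batch = small_corpus
        from bandrep.preprocess import WindowBatch
        one = WindowBatch(windows=batch.windows[:30],
                          channel_layout=batch.channel_layout,
                          labels=np.array(["Ex1"] * 30))
        with pytest.raises(ValueError, match="class"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train(build_model("imu"), one, seed=0, epochs=1)

    def test_loss_trend_non_increasing(self, trained):
        _, result = trained
        losses = np.asarray(result.loss_history)
        half = len(losses) // 2
        assert losses[half:].mean() <= losses[:half].mean()

    def test_separable_classes_learned(self, trained):
        _, result = trained
        assert result.metrics.accuracy >= 0.95

    def test_softmax_outputs_sum_to_one(self, trained, small_corpus):
        model, _ = trained
        x = small_corpus.windows[:8][..., None]
        proba = model.predict_proba(x.astype(np.float32))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


def loop_confusion(y_true, y_pred, n_classes=6):
    """Independent brute-force confusion builder."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


class TestMetrics:
    def _fake_batch_and_preds(self, y_true, y_pred):
        """Run the metric kernel via evaluate on a stub model."""
        from bandrep.classifier import _metrics_from_indices
        return _metrics_from_indices(np.asarray(y_true), np.asarray(y_pred))

    def test_two_class_kernel_hand_computed(self):
        # confusion [[5,0],[1,4]] on Ex1/Ex2
        y_true = [0] * 5 + [1] * 5
        y_pred = [0] * 5 + [0] + [1] * 4
        m = self._fake_batch_and_preds(y_true, y_pred)
        assert m.precision["Ex1"] == pytest.approx(5 / 6)
        assert m.recall["Ex1"] == pytest.approx(1.0)
        assert m.f1["Ex1"] == pytest.approx(10 / 11)

    def test_perfect_predictions(self):
        y = list(range(6))
        m = self._fake_batch_and_preds(y, y)
        assert m.accuracy == 1.0
        assert all(v == 1.0 for v in m.precision.values())

    def test_zero_support_class_reported_missing(self):
        m = self._fake_batch_and_preds([0, 0, 1], [0, 0, 1])
        assert m.recall["Ex6"] is None  # undefined, not 0

    def test_matches_loop_based_recomputation(self, rng):
        y_true = rng.integers(0, 6, 200)
        y_pred = rng.integers(0, 6, 200)
        m = self._fake_batch_and_preds(y_true, y_pred)
        cm = loop_confusion(y_true, y_pred)
        np.testing.assert_array_equal(m.confusion, cm)
        for c, label in enumerate(EXERCISES):
            tp = cm[c, c]
            if cm[:, c].sum():
                assert m.precision[label] == pytest.approx(tp / cm[:, c].sum())
            if cm[c, :].sum():
                assert m.recall[label] == pytest.approx(tp / cm[c, :].sum())
        assert m.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_confusion_row_sums_are_class_support(self, rng):
        y_true = rng.integers(0, 6, 300)
        y_pred = rng.integers(0, 6, 300)
        m = self._fake_batch_and_preds(y_true, y_pred)
        np.testing.assert_array_equal(m.confusion.sum(axis=1),
                                      np.bincount(y_true, minlength=6))


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote(["Ex1", "Ex1", "Ex3"]) == "Ex1"

    def test_singleton(self):
        assert majority_vote(["Ex2"]) == "Ex2"

    def test_tie_broken_by_first_occurrence(self):
        assert majority_vote(["Ex1", "Ex3", "Ex3", "Ex1"]) == "Ex1"
        assert majority_vote(["Ex3", "Ex1", "Ex1", "Ex3"]) == "Ex3"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, trained, small_corpus):
        model, _ = trained
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert predict_labels(back, small_corpus) == \
            predict_labels(model, small_corpus)
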