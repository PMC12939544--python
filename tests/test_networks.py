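"""Attention-network contracts: architecture arithmetic, softmax
normalization, gradient correctness, training determinism, ablation
variants, cross-validation hygiene."""

from __future__ import annotations

import numpy as np
import pytest

from eegaffect.networks import (
    MultiHeadAttentionClassifier,
    RecurrentBaselineClassifier,
    ablation_variant,
)
from eegaffect.report import cross_validate_model


def grad_check(model, params, X, y, eps=1e-6):
    """Max norm-relative difference between analytic and central
    finite-difference gradients, per parameter tensor."""
    _, grads, _ = model._loss_and_grads(params, X, y, None)
    worst = 0.0
    for key, g in grads.items():
        num = np.zeros_like(g)
        it = np.nditer(params[key], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = params[key][idx]
            params[key][idx] = orig + eps
            lp, _, _ = model._loss_and_grads(params, X, y, None)
            params[key][idx] = orig - eps
            lm, _, _ = model._loss_and_grads(params, X, y, None)
            params[key][idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        denom = max(np.linalg.norm(num), np.linalg.norm(g), 1e-12)
        worst = max(worst, np.linalg.norm(num - g) / denom)
    return worst


@pytest.fixture()
def toy_batch(rng):
    X = rng.normal(size=(5, 24))
    y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
    return X, y


class TestArchitecture:
    def test_attention_parameter_count_full_vector(self):
        counts = MultiHeadAttentionClassifier().parameter_counts(24)
        assert counts["attention"] == 1800  # 3 * (24*24 + 24)
        assert counts["hidden"] == 72 * 16 + 16
        assert counts["output"] == 17

    def test_subspace_mode_counts_and_fused_dim(self, rng):
        clf = MultiHeadAttentionClassifier(head_input_mode="subspace")
        assert clf.parameter_counts(24)["attention"] == 3 * (8 * 8 + 8)
        X = rng.normal(size=(20, 24))
        y = np.array([0, 1] * 10)
        clf.fit(X, y)
        fused, alphas = clf.attention_state(X)
        assert fused.shape == (20, 24)
        assert all(a.shape == (20, 8) for a in alphas)

    def test_incompatible_layout_rejected(self, rng):
        clf = MultiHeadAttentionClassifier(
            head_input_mode="subspace", subspace_layout=(8, 8, 7)
        )
        with pytest.raises(ValueError):
            clf.fit(rng.normal(size=(10, 24)), np.array([0, 1] * 5))

    def test_fused_dimension_72_and_alpha_sums(self, rng):
        X = rng.normal(size=(30, 24))
        y = np.array([0, 1] * 15)
        clf = MultiHeadAttentionClassifier(random_state=0).fit(X, y)
        fused, alphas = clf.attention_state(rng.normal(size=(50, 24)))
        assert fused.shape == (50, 72)
        assert len(alphas) == 3
        for a in alphas:
            assert np.all(a >= 0)
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_attention_and_half_output(self, toy_batch):
        X, y = toy_batch
        clf = MultiHeadAttentionClassifier(random_state=0)
        params = clf._init_params(24, np.random.default_rng(0))
        for key in params:
            params[key] = np.zeros_like(params[key])
        fused, alphas = clf._attention_apply(params, X)
        for a in alphas:
            assert np.allclose(a, 1.0 / 24)
        p, _ = clf._forward(params, X)
        assert np.allclose(p, 0.5)

    def test_zero_input_gives_zero_fusion(self, toy_batch):
        X, y = toy_batch
        clf = MultiHeadAttentionClassifier(random_state=0)
        params = clf._init_params(24, np.random.default_rng(1))
        fused, _ = clf._attention_apply(params, np.zeros((3, 24)))
        assert np.all(fused == 0.0)

    def test_output_in_unit_interval_and_eval_deterministic(self, rng):
        X = rng.normal(size=(40, 24))
        y = np.array([0, 1] * 20)
        clf = MultiHeadAttentionClassifier(random_state=3).fit(X, y)
        p1 = clf.predict_proba(X)[:, 1]
        p2 = clf.predict_proba(X)[:, 1]
        assert np.array_equal(p1, p2)  # dropout off at inference
        assert np.all((p1 > 0) & (p1 < 1))


class TestGradients:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"attention": "single_head"},
            {"attention": "none"},
            {"head_input_mode": "subspace"},
        ],
        ids=["multi_full", "single", "none", "multi_subspace"],
    )
    def test_analytic_matches_finite_differences(self, toy_batch, kwargs):
        """Backprop through softmax attention, ReLU head and sigmoid output
        agrees with central finite differences on a 5-sample batch."""
        X, y = toy_batch
        clf = MultiHeadAttentionClassifier(**kwargs)
        params = clf._init_params(24, np.random.default_rng(7))
        assert grad_check(clf, params, X, y) < 1e-4

    def test_rnn_bptt_matches_finite_differences(self, toy_batch):
        X, y = toy_batch
        clf = RecurrentBaselineClassifier(random_state=0)
        clf.fit(X, np.array([0, 1, 0, 1, 1]))
        S = clf._to_sequence(X)
        _, grads, _ = clf._loss_and_grads(clf.params_, S, y)
        worst = 0.0
        for key, g in grads.items():
            num = np.zeros_like(g)
            it = np.nditer(clf.params_[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = clf.params_[key][idx]
                clf.params_[key][idx] = orig + 1e-6
                lp, _, _ = clf._loss_and_grads(clf.params_, S, y)
                clf.params_[key][idx] = orig - 1e-6
                lm, _, _ = clf._loss_and_grads(clf.params_, S, y)
                clf.params_[key][idx] = orig
                num[idx] = (lp - lm) / 2e-6
            denom = max(np.linalg.norm(num), np.linalg.norm(g), 1e-12)
            worst = max(worst, np.linalg.norm(num - g) / denom)
        assert worst < 1e-4


class TestTraining:
    def test_learns_separable_data(self, rng):
        X = np.vstack([
            rng.normal(-1.0, 1.0, size=(100, 24)),
            rng.normal(1.0, 1.0, size=(100, 24)),
        ])
        y = np.array([0] * 100 + [1] * 100)
        clf = MultiHeadAttentionClassifier(random_state=0).fit(X, y)
        hist = clf.history_
        assert hist["train_acc"][-1] > hist["train_acc"][0]
        assert clf.score(X, y) > 0.9
        assert len(hist["train_loss"]) == clf.epochs

    def test_bit_identical_under_seed(self, rng):
        X = rng.normal(size=(90, 24))
        y = np.array([0, 1] * 45)
        a = MultiHeadAttentionClassifier(random_state=42).fit(X, y)
        b = MultiHeadAttentionClassifier(random_state=42).fit(X, y)
        for key in a.params_:
            assert np.array_equal(a.params_[key], b.params_[key])

    def test_permuted_labels_stay_at_chance(self, medium_features):
        """With labels shuffled, held-out accuracy sits at 0.5 +/- 0.07."""
        X, y = medium_features
        Xv = X.to_numpy()
        accs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            perm = g.permutation(y)
            clf = MultiHeadAttentionClassifier(random_state=seed)
            clf.fit(Xv[:140], perm[:140])
            accs.append(clf.score(Xv[140:], perm[140:]))
        assert abs(np.mean(accs) - 0.5) <= 0.07

    def test_single_class_refused(self, rng):
        X = rng.normal(size=(20, 24))
        with pytest.raises(ValueError):
            MultiHeadAttentionClassifier().fit(X, np.zeros(20, dtype=int))

    def test_nonfinite_input_refused(self, rng):
        X = rng.normal(size=(20, 24))
        X[3, 3] = np.nan
        with pytest.raises(ValueError):
            MultiHeadAttentionClassifier().fit(X, np.array([0, 1] * 10))

    def test_validation_history_recorded(self, rng):
        X = rng.normal(size=(60, 24))
        y = np.array([0, 1] * 30)
        clf = MultiHeadAttentionClassifier(random_state=0, epochs=5)
        clf.fit(X[:40], y[:40], validation_data=(X[40:], y[40:]))
        assert len(clf.history_["val_acc"]) == 5


class TestAblationVariants:
    def test_none_variant_has_no_attention_parameters(self, rng):
        clf = ablation_variant("none")
        assert clf.parameter_counts(24)["attention"] == 0
        X = rng.normal(size=(20, 24))
        clf.fit(X, np.array([0, 1] * 10))
        assert not any(k.startswith("Wa") for k in clf.params_)
        fused, alphas = clf.attention_state(X)
        assert fused.shape == (20, 24) and alphas == []

    def test_single_head_fused_dim_24(self, rng):
        clf = ablation_variant("single_head", random_state=0)
        X = rng.normal(size=(20, 24))
        clf.fit(X, np.array([0, 1] * 10))
        fused, alphas = clf.attention_state(X)
        assert fused.shape == (20, 24)
        assert len(alphas) == 1 and alphas[0].shape == (20, 24)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ablation_variant("two_heads")


class TestCrossValidation:
    def test_folds_partition_data(self, medium_features):
        X, y = medium_features
        reports = cross_validate_model(
            MultiHeadAttentionClassifier(epochs=3), X.to_numpy(), y, k=5, seed=0
        )
        all_test = np.concatenate([r.test_index for r in reports])
        assert sorted(all_test.tolist()) == list(range(len(y)))
        for r in reports:
            assert set(r.test_index).isdisjoint(set(r.train_index))
            assert len(r.test_index) == len(y) // 5

    def test_fold_zscore_uses_training_statistics_only(self, medium_features):
        """The stored normalization mean equals the training-fold mean, not
        the full-data mean (no leakage into the test fold)."""
        X, y = medium_features
        Xv = X.to_numpy()
        reports = cross_validate_model(
            MultiHeadAttentionClassifier(epochs=2), Xv, y, k=5, seed=1
        )
        for r in reports:
            assert np.allclose(r.extra["train_mean"], Xv[r.train_index].mean(axis=0))
            assert not np.allclose(r.extra["train_mean"], Xv.mean(axis=0))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate_model(
                MultiHeadAttentionClassifier(), rng.normal(size=(3, 24)),
                np.array([0, 1, 0]), k=5,
            )


class TestRecurrentBaseline:
    def test_sequence_reshape_channels_axis(self, rng):
        clf = RecurrentBaselineClassifier()
        X = np.arange(24.0)[None, :]
        S = clf._to_sequence(X)
        assert S.shape == (1, 8, 3)
        # step for channel 0 carries (ratio, asym, sampen) = columns 0, 8, 16
        assert np.array_equal(S[0, 0], [0.0, 8.0, 16.0])

    def test_domains_axis_option(self):
        clf = RecurrentBaselineClassifier(sequence_axis="domains")
        S = clf._to_sequence(np.arange(24.0)[None, :])
        assert S.shape == (1, 3, 8)

    def test_deterministic_and_learns(self, rng):
        X = np.vstack([
            rng.normal(-1.0, 1.0, size=(80, 24)),
            rng.normal(1.0, 1.0, size=(80, 24)),
        ])
        y = np.array([0] * 80 + [1] * 80)
        a = RecurrentBaselineClassifier(random_state=1).fit(X, y)
        b = RecurrentBaselineClassifier(random_state=1).fit(X, y)
        for key in a.params_:
            assert np.array_equal(a.params_[key], b.params_[key])
        assert a.score(X, y) > 0.9


class TestPersistence:
    def test_json_roundtrip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(80, 24))
        y = np.array([0, 1] * 40)
        model = MultiHeadAttentionClassifier(random_state=6).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = MultiHeadAttentionClassifier.load(path)
        assert np.array_equal(
            model.predict_proba(X), loaded.predict_proba(X)
        )
        assert loaded.get_params() == model.get_params()
        assert "converged_epoch" in model.history_

    def test_load_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"weights": {}}')
        with pytest.raises(ValueError):
            MultiHeadAttentionClassifier.load(path)
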