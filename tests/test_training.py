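"""Splitting, loss, augmentation, the optimization loop, and metrics."""

import numpy as np
import pytest

from ripc import (
    InvalidDatasetError,
    PhantomSpec,
    RIPCSConfig,
    RPNetConfig,
    SamplerConfig,
    TrainConfig,
    augment,
    cosine_lr,
    evaluate,
    metrics_from_predictions,
    smoothed_cross_entropy,
    stratified_split,
    train,
)
from ripc.ripcs import TrainingPointSet, ripcs_select
from ripc.training import build_phantom_clouds, hybrid_riies_count, ripcs_config_for_strategy


class TestStratifiedSplit:
    def test_study_cardinalities(self):
        """(123, 179, 154) at 8:2 gives exactly 364 train / 92 test."""
        labels = np.repeat([0, 1, 2], [123, 179, 154])
        tr, te = stratified_split(labels, 0.8, seed=0)
        assert len(tr) == 364 and len(te) == 92
        assert np.array_equal(np.sort(np.r_[tr, te]), np.arange(456))

    def test_floor_per_class(self):
        labels = np.repeat([0, 1, 2], [4, 3, 3])
        tr, te = stratified_split(labels, 0.8, seed=1)
        assert len(tr) == 7 and len(te) == 3
        for c, n_train in [(0, 3), (1, 2), (2, 2)]:
            assert (labels[tr] == c).sum() == n_train

    def test_deterministic(self):
        labels = np.repeat([0, 1, 2], 10)
        a = stratified_split(labels, 0.8, seed=3)
        b = stratified_split(labels, 0.8, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_class_raises(self):
        with pytest.raises(InvalidDatasetError):
            stratified_split(np.array([]), 0.8, seed=0)


class TestSmoothedCrossEntropy:
    def test_uniform_prediction_is_ln3(self):
        lp = np.log(np.full(3, 1 / 3))
        for alpha in (0.0, 0.1, 0.5):
            for label in range(3):
                assert abs(smoothed_cross_entropy(lp, label, alpha) - np.log(3)) < 1e-6

    def test_alpha_zero_is_nll(self):
        p = np.array([0.7, 0.2, 0.1])
        assert abs(smoothed_cross_entropy(np.log(p), 0, 0.0) + np.log(0.7)) < 1e-12

    def test_hand_computed_value(self):
        """probs (0.7, 0.2, 0.1), label 0, alpha 0.1 -> about 0.4633."""
        p = np.array([0.7, 0.2, 0.1])
        got = smoothed_cross_entropy(np.log(p), 0, 0.1)
        expect = -(
            (0.9 + 0.1 / 3) * np.log(0.7)
            + (0.1 / 3) * np.log(0.2)
            + (0.1 / 3) * np.log(0.1)
        )
        assert abs(got - expect) < 1e-12
        assert abs(got - 0.4633) < 5e-4


class TestAugment:
    def _set(self, rng, k=64):
        xyz = rng.normal(size=(k, 3))
        xyz /= np.abs(xyz).max()
        return TrainingPointSet(xyz, rng.uniform(1.34, 1.36, k), np.zeros(k, np.uint8))

    def test_rotation_preserves_distances(self, rng):
        ts = self._set(rng)
        cfg = TrainConfig(jitter_sigma=0.0, ri_noise_sigma=0.0, augment_prob=1.0)
        out = augment(ts, cfg, seed=0)
        d_in = np.linalg.norm(ts.xyz[:1] - ts.xyz, axis=1)
        d_out = np.linalg.norm(out.xyz[:1] - out.xyz, axis=1)
        assert np.allclose(d_in, d_out, atol=1e-6)
        assert np.array_equal(out.ri, ts.ri)  # geometry never touches RI

    def test_deterministic_and_identity_limits(self, rng):
        ts = self._set(rng)
        cfg = TrainConfig()
        a = augment(ts, cfg, seed=5)
        b = augment(ts, cfg, seed=5)
        assert np.array_equal(a.xyz, b.xyz) and np.array_equal(a.ri, b.ri)
        off = TrainConfig(augment_prob=0.0)
        ident = augment(ts, off, seed=5)
        assert np.array_equal(ident.xyz, ts.xyz) and np.array_equal(ident.ri, ts.ri)

    def test_jitter_clipped(self, rng):
        """With rotation and RI noise disabled, per-coordinate displacement
        never exceeds the clip bound."""
        ts = self._set(rng)
        cfg = TrainConfig(jitter_sigma=0.5, jitter_clip=0.05, augment_prob=1.0)
        for seed in range(5):
            out = augment(ts, cfg, seed=seed)
            rot_or_not = np.abs(out.xyz - ts.xyz)
            # z is untouched by rotation, so its displacement is pure jitter
            assert rot_or_not[:, 2].max() <= 0.05 + 1e-12


class TestCosineSchedule:
    def test_closed_form(self):
        assert abs(cosine_lr(1e-3, 0, 200) - 1e-3) < 1e-12
        assert abs(cosine_lr(1e-3, 100, 200) - 5e-4) < 1e-12
        assert abs(cosine_lr(1e-3, 200, 200)) < 1e-12


class TestMetrics:
    def test_perfect_predictor(self):
        y = np.repeat([0, 1, 2], 5)
        scores = np.eye(3)[y] * 0.98 + 0.01
        rep = metrics_from_predictions(y, scores)
        assert rep.accuracy == 1.0
        assert all(a == 1.0 for a in rep.auc_per_class)
        assert np.array_equal(rep.confusion, np.diag([5, 5, 5]))

    def test_hand_confusion_arithmetic(self):
        """Confusion [[5,0,0],[1,4,0],[0,0,5]]: accuracy 14/15, class-1
        recall 0.8."""
        y_true = np.repeat([0, 1, 2], 5)
        y_pred = y_true.copy()
        y_pred[5] = 0  # one class-1 sample predicted as class 0
        scores = np.eye(3)[y_pred] * 0.9 + 0.05
        rep = metrics_from_predictions(y_true, scores)
        assert abs(rep.accuracy - 14 / 15) < 1e-12
        assert rep.confusion[1, 0] == 1 and rep.confusion[1, 1] == 4
        # macro recall = mean(1, 0.8, 1)
        assert abs(rep.recall_macro - (1 + 0.8 + 1) / 3) < 1e-12

    def test_majority_constant_predictor(self):
        y = np.repeat([0, 1, 2], 10)
        scores = np.tile([0.8, 0.1, 0.1], (30, 1))
        rep = metrics_from_predictions(y, scores)
        assert abs(rep.accuracy - 1 / 3) < 1e-12

    def test_matches_brute_force_on_random_predictions(self, rng):
        y = rng.integers(0, 3, 60)
        scores = rng.dirichlet(np.ones(3), 60)
        rep = metrics_from_predictions(y, scores)
        y_pred = scores.argmax(1)
        conf = np.zeros((3, 3), int)
        for t, p in zip(y, y_pred):
            conf[t, p] += 1
        assert np.array_equal(rep.confusion, conf)
        assert abs(rep.accuracy - np.trace(conf) / 60) < 1e-12
        # macro F1 = mean of per-class 2PR/(P+R)
        f1s = []
        for c in range(3):
            tp = conf[c, c]
            prec = tp / max(conf[:, c].sum(), 1)
            rec = tp / max(conf[c].sum(), 1)
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        assert abs(rep.f1_macro - np.mean(f1s)) < 1e-12

    def test_absent_class_auc_undefined(self):
        y = np.repeat([0, 1], 5)  # class 2 absent
        scores = np.eye(3)[y] * 0.9 + 0.05
        with pytest.warns(UserWarning, match="absent"):
            rep = metrics_from_predictions(y, scores)
        assert rep.auc_per_class[2] is None
        assert abs(rep.auc_mean - 1.0) < 1e-12  # mean over defined classes


class TestHybridSplitRule:
    def test_full_scale_matches_selector_defaults(self):
        cfg = ripcs_config_for_strategy("hybrid", 1024)
        assert (cfg.n_fps, cfg.n_riies) == (800, 224)

    def test_desk_scale_protects_band_share(self):
        """Scaling K down keeps the 224-point band draw and shrinks FPS."""
        cfg = ripcs_config_for_strategy("hybrid", 256)
        assert cfg.n_fps + cfg.n_riies == 256
        assert cfg.n_riies == hybrid_riies_count(256) == 224
        assert hybrid_riies_count(64) == 56  # FPS keeps at least K/8

    def test_fps_and_riies_only(self):
        assert ripcs_config_for_strategy("fps", 256).n_riies == 0
        assert ripcs_config_for_strategy("riies", 256).n_fps == 0


@pytest.fixture(scope="module")
def mini_dataset():
    """Small separable phantom dataset for loop tests (8 per class)."""
    spec = PhantomSpec(grid_shape=(64, 64, 42), voxel_spacing=0.5)
    return build_phantom_clouds(
        spec, (8, 8, 8), SamplerConfig(M=1024, L=6, mode="segmented"), seed=0
    )


class TestTrainLoop:
    def _small_net(self):
        from ripc.rpnet import HeadConfig, SAConfig

        return RPNetConfig(
            input_channels=4,
            sa_levels=(
                SAConfig(16, 0.3, 8, (16, 32)),
                SAConfig(8, 0.6, 8, (32, 64)),
                SAConfig(None, None, None, (64, 128)),
            ),
            head=HeadConfig((64,), (0.3,)),
            ri_scale=0.0035,
        )

    def test_history_schedule_and_loss_progress(self, mini_dataset):
        clouds, labels = mini_dataset
        rcfg = ripcs_config_for_strategy("hybrid", 64)
        tcfg = TrainConfig(epochs=30, seed=0, batch_size=4)
        model, hist = train(clouds, labels, self._small_net(), tcfg, rcfg)
        assert len(hist) == 30
        for h in hist:
            assert abs(h["lr"] - cosine_lr(1e-3, h["epoch"], 30)) < 1e-8
        assert hist[-1]["loss"] < np.log(3)  # beats uniform prediction

    def test_reproducible_end_to_end(self, mini_dataset):
        clouds, labels = mini_dataset
        rcfg = ripcs_config_for_strategy("hybrid", 64)
        tcfg = TrainConfig(epochs=2, seed=4, batch_size=8)
        _, h1 = train(clouds, labels, self._small_net(), tcfg, rcfg)
        _, h2 = train(clouds, labels, self._small_net(), tcfg, rcfg)
        assert h1 == h2

    def test_evaluate_deterministic(self, mini_dataset):
        clouds, labels = mini_dataset
        rcfg = ripcs_config_for_strategy("hybrid", 64)
        tcfg = TrainConfig(epochs=2, seed=0, batch_size=8)
        model, _ = train(clouds, labels, self._small_net(), tcfg, rcfg)
        r1 = evaluate(model, clouds[:6], labels[:6], rcfg)
        r2 = evaluate(model, clouds[:6], labels[:6], rcfg)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_single_class_rejected(self, mini_dataset):
        clouds, labels = mini_dataset
        rcfg = ripcs_config_for_strategy("hybrid", 64)
        with pytest.raises(InvalidDatasetError):
            train(clouds[:8], labels[:8], self._small_net(), TrainConfig(epochs=1), rcfg)

    def test_ripcs_robustness_harness(self, mini_dataset):
        """Repeated evaluation under re-randomized point selection reports a
        mean/sd accuracy pair; identical seeds reproduce it exactly."""
        from ripc.training import ripcs_robustness

        clouds, labels = mini_dataset
        rcfg = ripcs_config_for_strategy("hybrid", 64)
        model, _ = train(
            clouds, labels, self._small_net(), TrainConfig(epochs=2, seed=0, batch_size=8), rcfg
        )
        mean, sd = ripcs_robustness(model, clouds[:9], labels[:9], rcfg, n_runs=3, seed=1)
        assert 0.0 <= mean <= 1.0 and sd >= 0.0
        assert (mean, sd) == ripcs_robustness(model, clouds[:9], labels[:9], rcfg, n_runs=3, seed=1)
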