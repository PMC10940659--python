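"""DP-SGD primitives and training loops."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from dpfair.models import ModelConfig
from dpfair.pipeline import prepare_dataset
from dpfair.synthetic import generate_cxr_like, split_patientwise
from dpfair.training import (
    ArrayDataset,
    TrainConfig,
    clip_per_sample,
    inverse_frequency_weights,
    load_checkpoint,
    noisy_step,
    poisson_sample,
    save_checkpoint,
    train,
    weighted_bce_loss,
)
from conftest import two_group_spec


def tiny_dataset(n=32, shape=(8, 8), n_labels=2, seed=0) -> ArrayDataset:
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age_group": ["[30,60)"] * n,
        }
    )
    labels = (rng.random((n, n_labels)) < 0.5).astype(int)
    images = rng.normal(size=(n,) + shape) * 0.1
    # plant a weak signal so losses can move
    images[labels[:, 0] == 1, 2:5, 2:5] += 0.5
    return ArrayDataset(images, labels, meta, tuple(f"l{j}" for j in range(n_labels)))


THIN = ModelConfig(ndim=2, widths=(3, 4, 4, 4), n_outputs=2, dtype="float64")


class TestPoissonSample:
    def test_extremes(self):
        assert poisson_sample(100, 0.0, 1).size == 0
        np.testing.assert_array_equal(poisson_sample(5, 1.0, 1), np.arange(5))

    def test_batch_size_concentration(self):
        idx = poisson_sample(10_000, 0.5, np.random.default_rng(7))
        assert abs(idx.size - 5000) <= 3 * math.sqrt(10_000 * 0.25)


class TestClipping:
    def test_long_gradient_rescaled_exactly(self):
        g = np.array([3.0, 0.0, 0.0])
        out = clip_per_sample(g, 1.5)
        assert np.linalg.norm(out) == pytest.approx(1.5)
        np.testing.assert_allclose(out / np.linalg.norm(out), [1.0, 0, 0])

    def test_short_gradient_untouched(self):
        g = np.array([0.6, 0.8])  # norm 1 <= 1.5
        np.testing.assert_array_equal(clip_per_sample(g, 1.5), g)

    def test_all_norms_bounded_over_random_batch(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(1000, 37)) * rng.gamma(2, 2, size=(1000, 1))
        norms = np.linalg.norm(clip_per_sample(g, 1.5), axis=1)
        assert np.all(norms <= 1.5 + 1e-9)

    def test_zero_gradient_passes_through(self):
        np.testing.assert_array_equal(clip_per_sample(np.zeros(4), 1.0), np.zeros(4))


class TestNoisyStep:
    def test_noiseless_step_is_clipped_mean(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(8, 10))
        out = noisy_step(g, clip_norm=1e9, sigma=0.0, expected_batch=8.0, rng=rng)
        np.testing.assert_allclose(out, g.mean(axis=0))

    def test_empty_batch_releases_pure_noise(self):
        rng = np.random.default_rng(1)
        out = noisy_step(np.zeros((0, 5)), 1.0, 2.0, expected_batch=10.0, rng=rng)
        assert out.shape == (5,)
        assert np.any(out != 0.0)

    def test_noise_scale_matches_sigma_c_over_batch(self):
        """Marginal std per coordinate = sigma*C/expected_batch (Monte Carlo)."""
        rng = np.random.default_rng(2)
        sigma, c, eb, n = 2.0, 1.5, 64.0, 10_000
        draws = np.array(
            [noisy_step(np.zeros((0, 1)), c, sigma, eb, rng)[0] for _ in range(n)]
        )
        expected = sigma * c / eb
        se = expected / math.sqrt(2 * n)  # SE of a sample std
        assert abs(draws.std() - expected) <= 3 * se


class TestLoss:
    def test_vanishes_on_confident_correct_predictions(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[1 - 1e-9, 1e-9]])
        assert weighted_bce_loss(p, y, None)[0] == pytest.approx(0.0, abs=1e-7)

    def test_unit_weights_reduce_to_plain_bce(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, size=(6, 3))
        y = (rng.random((6, 3)) < 0.5).astype(float)
        plain = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean(axis=1)
        np.testing.assert_allclose(
            weighted_bce_loss(p, y, np.ones(3)), plain
        )

    def test_weighted_positive_term_arithmetic(self):
        # y=1, p=0.5, w=3 -> 3*ln 2 for that label
        loss = weighted_bce_loss(
            np.array([[0.5]]), np.array([[1.0]]), np.array([3.0])
        )
        assert loss[0] == pytest.approx(3 * math.log(2))

    def test_inverse_frequency_weights(self):
        labels = np.array([[1, 0], [1, 0], [0, 0], [1, 1]])
        w = inverse_frequency_weights(labels)
        np.testing.assert_allclose(w, [1 / 3, 3.0])


class TestTrainConfigContracts:
    def test_dp_mode_forbids_augmentation(self):
        with pytest.raises(ValueError, match="augmentation"):
            TrainConfig(mode="dp", epsilon_target=1.0, delta=1e-3,
                        augment_rotate=True)

    def test_dp_mode_needs_budget_or_sigma(self):
        with pytest.raises(ValueError, match="epsilon_target"):
            TrainConfig(mode="dp")
        TrainConfig(mode="dp", sigma=1.0, delta=1e-3)  # fine


class TestTrainingLoops:
    def test_dp_with_zero_noise_matches_plain_sgd(self):
        """sigma=0, C=1e9, full batch: the DP trajectory is plain training."""
        ds = tiny_dataset(n=32)
        dp_cfg = TrainConfig(
            mode="dp", learning_rate=1e-2, batch_size=32, epochs=3,
            sigma=0.0, delta=1e-3, clip_norm=1e9, seed=0,
            loss_weighting="none",
        )
        plain_cfg = TrainConfig(
            mode="nonprivate", learning_rate=1e-2, batch_size=32, epochs=3,
            seed=0, loss_weighting="none",
        )
        m_dp, _ = train(ds, THIN, dp_cfg)
        m_plain, _ = train(ds, THIN, plain_cfg)
        np.testing.assert_allclose(m_dp.loss_trace, m_plain.loss_trace, rtol=1e-9)
        for a, b in zip(m_dp.network.params(), m_plain.network.params()):
            # atol floors the conv biases cancelled exactly by group norm,
            # which sit at optimizer round-off scale (~1e-11) in both runs
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8)

    def test_zero_epochs_leaves_weights_at_init_and_spends_delta_term(self):
        from dpfair.accounting import DEFAULT_ORDERS
        from dpfair.models import build_model

        ds = tiny_dataset(n=8)
        cfg = TrainConfig(mode="dp", epochs=0, batch_size=8, sigma=1.0,
                          delta=1e-3, seed=1)
        model, _ = train(ds, THIN, cfg)
        init = build_model(THIN, seed=1)
        for a, b in zip(model.network.params(), init.params()):
            np.testing.assert_array_equal(a, b)
        expected = math.log(1e3) / (max(DEFAULT_ORDERS) - 1)
        assert model.spend.epsilon == pytest.approx(expected)

    def test_same_seed_reproduces_weights(self):
        ds = tiny_dataset(n=16)
        cfg = TrainConfig(mode="dp", learning_rate=5e-3, batch_size=8,
                          epochs=2, sigma=0.8, delta=1e-2, seed=4)
        m1, _ = train(ds, THIN, cfg)
        m2, _ = train(ds, THIN, cfg)
        for a, b in zip(m1.network.params(), m2.network.params()):
            np.testing.assert_array_equal(a, b)

    def test_reported_spend_stays_within_target(self):
        ds = tiny_dataset(n=24)
        cfg = TrainConfig(mode="dp", learning_rate=1e-3, batch_size=8,
                          epochs=2, epsilon_target=2.0, delta=1e-2, seed=0)
        model, _ = train(ds, THIN, cfg)
        assert model.spend is not None
        assert model.spend.epsilon <= 2.0 + cfg.calibration_tolerance

    def test_nonprivate_augmentation_path_runs(self):
        ds = tiny_dataset(n=16)
        cfg = TrainConfig(mode="nonprivate", learning_rate=1e-3, batch_size=8,
                          epochs=1, augment_rotate=True, augment_flip=True,
                          seed=2)
        model, _ = train(ds, THIN, cfg)
        assert len(model.loss_trace) == 2  # two mini-batches

    def test_non_finite_loss_aborts_with_diagnostic(self):
        ds = tiny_dataset(n=16)
        ds.images[0, 0, 0] = np.inf  # poisoned record must not pass silently
        cfg = TrainConfig(mode="nonprivate", learning_rate=1e-3,
                          batch_size=16, epochs=1, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train(ds, THIN, cfg)

    def test_prediction_table_emitted_on_eval_split(self):
        ds = tiny_dataset(n=24, seed=1)
        holdout = tiny_dataset(n=10, seed=2)
        cfg = TrainConfig(mode="nonprivate", learning_rate=1e-3, batch_size=8,
                          epochs=1, seed=0)
        _, table = train(ds, THIN, cfg, holdout)
        assert len(table) == 10
        assert set(table.labels) == {"l0", "l1"}

    def test_checkpoint_round_trip(self, tmp_path):
        ds = tiny_dataset(n=16)
        cfg = TrainConfig(mode="nonprivate", learning_rate=1e-3, batch_size=8,
                          epochs=1, seed=0)
        model, _ = train(ds, THIN, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        x = ds.model_input()
        np.testing.assert_allclose(
            model.network.predict_proba(x), loaded.network.predict_proba(x)
        )
        assert loaded.train_config.learning_rate == 1e-3


class TestVolumetricTraining:
    def test_ct_pipeline_trains_and_scores(self):
        """3D path end to end: generate CT-like volumes, window, train a thin
        3D CNN with DP-SGD for a couple of steps, score a held-out split."""
        from dpfair.synthetic import (
            DatasetSpec, SubgroupSpec, generate_ct_like, split_patientwise,
        )

        spec = DatasetSpec(
            n_patients=60, image_shape=(8, 8, 8), labels=("tumor",),
            subgroups=(SubgroupSpec("all", 1.0, {"tumor": 0.5}, sex="male"),),
            seed=17,
        )
        ds = generate_ct_like(spec)
        tr, _, te = split_patientwise(ds, (0.7, 0.0, 0.3), "tumor", seed=0)
        ptr, pte = prepare_dataset(tr), prepare_dataset(te)
        cfg = TrainConfig(
            mode="dp", learning_rate=3e-3, batch_size=16, epochs=1,
            epsilon_target=8.0, delta=1e-2, clip_norm=1.5, seed=0,
            loss_weighting="none",
        )
        mc = ModelConfig(ndim=3, widths=(3, 4, 4, 4), n_outputs=1)
        model, table = train(ptr, mc, cfg, pte)
        assert model.spend is not None and model.spend.epsilon <= 8.001
        assert len(table) == len(pte)
        assert np.all((table.scores("tumor") > 0) & (table.scores("tumor") < 1))


class TestDifficultyMonotonicity:
    def test_harder_images_learn_worse(self):
        """Same generator, same training, 2x difficulty: lower held-out AUROC
        (mean over 3 seeds)."""
        from dpfair.evaluation import macro_auroc

        scores = {}
        for name, difficulty in (("easy", 1.0), ("hard", 3.0)):
            spec = two_group_spec(
                n_patients=360, image_shape=(16, 16), labels=("finding_a",),
                prevalence=0.5, difficulty_ratio=difficulty, seed=21,
                proportions=(0.0, 1.0),  # single subgroup carries difficulty
            )
            ds = generate_cxr_like(spec)
            tr, _, te = split_patientwise(ds, (0.7, 0.0, 0.3), seed=0)
            ptr, pte = prepare_dataset(tr), prepare_dataset(te)
            vals = []
            for seed in (0, 1, 2):
                cfg = TrainConfig(mode="nonprivate", learning_rate=5e-3,
                                  batch_size=64, epochs=4, seed=seed,
                                  loss_weighting="none")
                mc = ModelConfig(ndim=2, widths=(4, 8, 8, 8), n_outputs=1)
                _, table = train(ptr, mc, cfg, pte)
                vals.append(macro_auroc(table))
            scores[name] = float(np.mean(vals))
        assert scores["hard"] < scores["easy"]
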