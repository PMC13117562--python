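"""Regression network: forward pass, schedule, training, cross-validation."""

import numpy as np
import pytest

from cranioland.network import (
    DivergenceError,
    NetworkConfig,
    TrainConfig,
    cross_validate,
    forward,
    init_params,
    lr_at_epoch,
    stratified_folds,
    train,
)


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 1e-3), (99, 1e-3), (100, 5e-4), (199, 5e-4), (200, 2.5e-4), (399, 1.25e-4)],
    )
    def test_step_decay_values(self, epoch, expected):
        assert lr_at_epoch(TrainConfig(), epoch) == pytest.approx(expected, rel=0, abs=0)

    def test_closed_form_over_all_epochs(self):
        cfg = TrainConfig()
        for e in range(400):
            assert lr_at_epoch(cfg, e) == cfg.lr0 * cfg.decay_factor ** (e // cfg.decay_every)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), -1)


class TestForward:
    def test_zero_parameters_give_zero_output(self):
        cfg = NetworkConfig()
        params = {k: np.zeros_like(v) for k, v in init_params(cfg, np.random.default_rng(0)).items()}
        out = forward(params, cfg, np.ones(14))
        assert np.array_equal(out, np.zeros(3))

    def test_inference_is_deterministic(self):
        cfg = NetworkConfig()
        params = init_params(cfg, np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=14)
        a = forward(params, cfg, x)
        b = forward(params, cfg, x)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_raises(self):
        cfg = NetworkConfig()
        params = init_params(cfg, np.random.default_rng(1))
        with pytest.raises(ValueError):
            forward(params, cfg, np.ones(13))

    def test_matches_hand_computed_evaluation(self):
        # one small instance evaluated layer by layer with explicit
        # arithmetic, independent of the packaged forward pass
        cfg = NetworkConfig(input_dim=2, hidden_width=2, n_identity_blocks=3, output_dim=2)
        params = {
            "W0": np.array([[1.0, -1.0], [0.5, 2.0]]),
            "b0": np.array([0.1, -0.2]),
            "W1": np.array([[0.0, 1.0], [1.0, 0.0]]),
            "b1": np.array([0.0, 0.5]),
            "W2": np.array([[-1.0, 0.0], [0.0, -1.0]]),
            "b2": np.array([1.0, 1.0]),
            "W3": np.array([[0.2, 0.3], [0.4, 0.5]]),
            "b3": np.array([-0.1, 0.2]),
            "Wh": np.array([[1.0, 2.0], [3.0, -1.0]]),
            "bh": np.array([0.5, -0.5]),
        }
        x = np.array([1.0, 2.0])
        h = np.maximum(params["W0"] @ x + params["b0"], 0)  # [0, 4.3]
        for k in (1, 2, 3):
            h = h + np.maximum(params[f"W{k}"] @ h + params[f"b{k}"], 0)
        expected = params["Wh"] @ h + params["bh"]
        got = forward(params, cfg, x)
        assert np.allclose(got, expected, atol=1e-12)

    def test_batched_equals_single(self):
        cfg = NetworkConfig()
        params = init_params(cfg, np.random.default_rng(3))
        X = np.random.default_rng(4).normal(size=(5, 14))
        batched = forward(params, cfg, X)
        singles = np.array([forward(params, cfg, x) for x in X])
        assert np.allclose(batched, singles, atol=1e-12)


class TestTrain:
    def test_zero_head_zero_targets_is_fixed_point(self):
        cfg = NetworkConfig()
        rng = np.random.default_rng(0)
        params = init_params(cfg, rng)
        params["Wh"] = np.zeros_like(params["Wh"])
        params["bh"] = np.zeros_like(params["bh"])
        X = rng.normal(size=(10, 14))
        Y = np.zeros((10, 3))
        model = train(X, Y, cfg, TrainConfig(epochs=5), seed=1, initial_params=params)
        assert np.array_equal(model.loss_history, np.zeros(5))

    def test_same_seed_reproduces_loss_history(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 14))
        Y = rng.normal(size=(20, 3))
        a = train(X, Y, None, TrainConfig(epochs=8), seed=5)
        b = train(X, Y, None, TrainConfig(epochs=8), seed=5)
        assert np.array_equal(a.loss_history, b.loss_history)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_loss_history_finite_and_correct_length(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 14))
        Y = rng.normal(size=(15, 3))
        model = train(X, Y, None, TrainConfig(epochs=12), seed=0)
        assert len(model.loss_history) == 12
        assert np.all(np.isfinite(model.loss_history))

    def test_noiseless_linear_target_is_learned(self):
        # the true map (sella = linear function of the scores) lies inside
        # the model class: with dropout disabled the optimizer must recover
        # it to well under 1 mm; with the architecture's dropout active the
        # fit is shrunk (multiplicative noise on 8 units acts as heavy
        # regularization) but must still explain most of the target spread
        rng = np.random.default_rng(12)
        X = np.hstack([rng.normal(size=(200, 10)), np.tile([1.0, 0, 0, 0], (200, 1))])
        L = rng.normal(0.0, 2.0, size=(14, 3))
        Y = X @ L
        clean_cfg = NetworkConfig(dropout_in=0.0, dropout_out=0.0)
        model = train(X, Y, clean_cfg, TrainConfig(epochs=400), seed=3)
        rmse = np.sqrt(np.mean((model.predict(X) - Y) ** 2))
        assert rmse < 1.0
        model_d = train(X, Y, NetworkConfig(), TrainConfig(epochs=400), seed=3)
        rmse_d = np.sqrt(np.mean((model_d.predict(X) - Y) ** 2))
        assert rmse_d < 0.75 * Y.std()

    def test_non_finite_loss_raises_with_epoch(self):
        cfg = NetworkConfig()
        bad = init_params(cfg, np.random.default_rng(0))
        bad["W0"] = bad["W0"] * np.inf
        rng = np.random.default_rng(1)
        with pytest.raises(DivergenceError) as err:
            train(
                rng.normal(size=(4, 14)),
                rng.normal(size=(4, 3)),
                cfg,
                TrainConfig(epochs=3),
                seed=0,
                initial_params=bad,
            )
        assert err.value.epoch == 0


class TestFolds:
    def test_partition_and_balance(self):
        rng = np.random.default_rng(0)
        subtypes = ["control"] * 12 + ["scaphocephaly"] * 9 + ["plagiocephaly"] * 9
        folds = stratified_folds(subtypes, 5, rng)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.sum() == 30
        assert sizes.max() - sizes.min() <= 1
        # stratification: controls spread over folds as evenly as possible
        ctrl = np.bincount(folds[:12], minlength=5)
        assert ctrl.max() - ctrl.min() <= 1

    def test_small_subtype_warns(self):
        rng = np.random.default_rng(1)
        subtypes = ["control"] * 10 + ["trigonocephaly"] * 2
        with pytest.warns(UserWarning, match="trigonocephaly"):
            stratified_folds(subtypes, 5, rng)

    def test_fewer_subjects_than_folds_raise(self):
        with pytest.raises(ValueError):
            stratified_folds(["control"] * 3, 5, np.random.default_rng(0))


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cv_result(self, small_standardized):
        from cranioland.config import RunConfig

        config = RunConfig(epochs=25, folds=4)
        return cross_validate(small_standardized, config, seed=2)

    def test_every_subject_predicted_exactly_once(self, cv_result, small_standardized):
        ids = cv_result.predictions["id"]
        assert sorted(ids) == sorted(s.id for s in small_standardized)
        assert ids.is_unique

    def test_fold_sizes_differ_by_at_most_one(self, cv_result):
        sizes = cv_result.predictions["fold"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_pooled_metrics_equal_per_subject_recomputation(self, cv_result):
        df = cv_result.predictions
        # independent aggregation: mean Euclidean error recomputed rowwise
        err = np.sqrt(
            (df["ffnn_x"] - df["true_x"]) ** 2
            + (df["ffnn_y"] - df["true_y"]) ** 2
            + (df["ffnn_z"] - df["true_z"]) ** 2
        )
        from cranioland.metrics import evaluate_cohort

        report = evaluate_cohort(df, compute_maps=False)
        t = report.subject_table
        pooled = t.loc[t["method"] == "ffnn"].set_index("id")["euclidean"]
        assert np.allclose(pooled.sort_index(), err.groupby(df["id"]).mean().sort_index())

    def test_per_fold_models_are_kept(self, cv_result):
        assert len(cv_result.fold_models) == 4
        assert len(cv_result.fold_pcas) == 4
        assert len(cv_result.fold_offsets) == 4

    def test_error_degrades_monotonically_with_annotation_noise(self):
        # quadrupling the sella annotation noise cannot improve the
        # cross-validated error (checked at sd 0.5, 1 and 2 mm, fixed seed)
        from cranioland import SellaLandmarkModel
        from cranioland.config import RunConfig

        errs = {}
        for sd in (0.5, 1.0, 2.0):
            model = SellaLandmarkModel.from_synthetic(
                n_per_class=12, seed=31, config=RunConfig(epochs=80), st_noise_sd=sd
            )
            errs[sd] = model.fit(seed=31).mean_euclidean_error("ffnn")
        assert errs[0.5] < errs[2.0]
        assert errs[1.0] < errs[2.0]
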