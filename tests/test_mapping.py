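import numpy as np
import pytest

from wristhrv.mapping import (
    ModelSpec,
    PairedDataset,
    default_model_specs,
    evaluate_models,
    fit_predict,
    grid_search,
    kfold_cv,
    split_train_test,
)


def dataset(n_per_subject=40, subjects=("A", "B"), noise_sd=0.0, offset=0.0, seed=0):
    rng = np.random.default_rng(seed)
    wrist, ref, sid, ts = [], [], [], []
    for s in subjects:
        x = 70 + 8 * rng.random(n_per_subject)
        wrist.append(x)
        ref.append(x + offset + rng.normal(0, noise_sd, n_per_subject))
        sid.append([s] * n_per_subject)
        ts.append(np.arange(n_per_subject, dtype=float))
    return PairedDataset(
        wrist_hr=np.concatenate(wrist),
        reference_hr=np.concatenate(ref),
        subject_ids=np.concatenate(sid),
        timestamps=np.concatenate(ts),
    )


class TestSplit:
    def test_eight_rows_split_six_two(self):
        ds = split_train_test(dataset(8, subjects=("A",)))
        assert (ds.split_assignment == "train").sum() == 6
        assert (ds.split_assignment == "test").sum() == 2

    def test_every_subject_in_both_halves(self):
        ds = split_train_test(dataset(20))
        for s in ("A", "B"):
            rows = ds.split_assignment[ds.subject_ids == s]
            assert "train" in rows and "test" in rows

    def test_split_is_chronological_per_subject(self):
        ds = split_train_test(dataset(20))
        for s in ("A", "B"):
            m = ds.subject_ids == s
            t_train = ds.timestamps[m & (ds.split_assignment == "train")]
            t_test = ds.timestamps[m & (ds.split_assignment == "test")]
            assert t_train.max() < t_test.min()

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(dataset(), train_fraction=1.0)

    def test_small_subject_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            split_train_test(dataset(3, subjects=("A",)))


class TestCvAndGridSearch:
    def test_constant_target_scores_zero(self):
        ds = dataset(20, subjects=("A",))
        ds.reference_hr[:] = 75.0
        spec = ModelSpec("linear_regression")
        assert kfold_cv(spec, {}, ds, k=5, seed=0) == pytest.approx(0.0, abs=1e-20)

    def test_folds_partition_rows(self):
        from sklearn.model_selection import KFold

        folds = list(KFold(5, shuffle=True, random_state=0).split(np.arange(10)))
        sizes = [len(v) for _, v in folds]
        assert sizes == [2] * 5

    def test_same_seed_reproduces_score(self):
        ds = dataset(25, noise_sd=1.0)
        spec = ModelSpec("knn", {"n_neighbors": [3]})
        s1 = kfold_cv(spec, {"n_neighbors": 3}, ds, seed=4)
        s2 = kfold_cv(spec, {"n_neighbors": 3}, ds, seed=4)
        assert s1 == s2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(ModelSpec("linear_regression"), {}, dataset(2, subjects=("A",)), k=5)

    def test_singleton_grid_returned(self):
        ds = dataset(20)
        out = grid_search(ModelSpec("knn", {"n_neighbors": [3]}), ds)
        assert out["best_hyperparameters"] == {"n_neighbors": 3}

    def test_linear_regression_reports_empty_hyperparameters(self):
        ds = dataset(20)
        out = grid_search(ModelSpec("linear_regression"), ds)
        assert out["best_hyperparameters"] == {}
        assert np.isfinite(out["best_score"])

    def test_empty_grid_rejected_except_linear(self):
        with pytest.raises(ValueError):
            ModelSpec("knn", {})


class TestFitPredict:
    def test_identity_task_linear_regression_is_exact(self):
        ds = split_train_test(dataset(40))
        tr, te = ds.rows("train"), ds.rows("test")
        pred, _ = fit_predict(ModelSpec("linear_regression"), {}, tr, te.wrist_hr,
                              te.subject_ids)
        assert np.sqrt(np.mean((pred - te.reference_hr) ** 2)) <= 1e-6

    def test_linear_regression_recovers_slope_and_intercept(self):
        ds = dataset(100, offset=5.0)
        mapper = fit_predict(ModelSpec("linear_regression"), {}, ds, ds.wrist_hr[:1])[1]
        assert mapper.model.coef_[0] == pytest.approx(1.0, abs=1e-9)
        assert mapper.model.intercept_ == pytest.approx(5.0, abs=1e-7)

    def test_knn_one_neighbour_memorises_training_inputs(self):
        ds = dataset(30, noise_sd=1.0)
        spec = ModelSpec("knn", {"n_neighbors": [1]})
        pred, _ = fit_predict(spec, {"n_neighbors": 1}, ds, ds.wrist_hr, ds.subject_ids)
        assert pred == pytest.approx(ds.reference_hr)

    def test_multinomial_logistic_predicts_integer_categories(self):
        ds = dataset(60, noise_sd=1.0, seed=2)
        spec = ModelSpec("multinomial_logistic", {"C": [1.0]})
        pred, _ = fit_predict(spec, {"C": 1.0}, ds, ds.wrist_hr[:10], ds.subject_ids[:10])
        assert np.allclose(pred, np.round(pred))

    @pytest.mark.parametrize("alg", ["rnn", "lstm"])
    def test_net_training_loss_decreases_on_learnable_task(self, alg):
        ds = split_train_test(dataset(300, noise_sd=0.5, seed=1))
        tr = ds.rows("train")
        spec = default_model_specs([alg])[0]
        _, mapper = fit_predict(spec, {"hidden_units": 8}, tr, tr.wrist_hr[:1],
                                tr.subject_ids[:1], seed=0)
        assert mapper.history[-1] < mapper.history[0]
        assert len(mapper.history) == 15

    @pytest.mark.parametrize("alg", ["rnn", "lstm"])
    def test_net_predictions_finite_and_in_target_range(self, alg):
        ds = split_train_test(dataset(200, noise_sd=1.0, seed=3))
        tr, te = ds.rows("train"), ds.rows("test")
        spec = default_model_specs([alg])[0]
        pred, _ = fit_predict(spec, {"hidden_units": 8}, tr, te.wrist_hr, te.subject_ids,
                              seed=0)
        assert np.all(np.isfinite(pred))
        assert pred.min() >= tr.reference_hr.min() - 1e-9
        assert pred.max() <= tr.reference_hr.max() + 1e-9


class TestEvaluateModels:
    def test_identity_task_won_by_linear_regression(self):
        ds = split_train_test(dataset(40))
        specs = default_model_specs(["linear_regression", "knn", "decision_tree"])
        report = evaluate_models(ds, specs, seed=0)
        assert report.winner == "linear_regression"
        assert report.entries[0]["test_rmse"] == pytest.approx(0.0, abs=1e-6)

    def test_report_sorted_ascending(self):
        ds = split_train_test(dataset(60, noise_sd=2.0, seed=5))
        report = evaluate_models(ds, default_model_specs(["knn", "linear_regression",
                                                          "adaboost"]), seed=0)
        rmses = [e["test_rmse"] for e in report.entries]
        assert rmses == sorted(rmses)
        assert all(r >= 0 for r in rmses)

    def test_test_rows_never_influence_fitting(self):
        ds = split_train_test(dataset(60, noise_sd=1.0, seed=6))
        spec = ModelSpec("linear_regression")
        tr = ds.rows("train")
        pred_before, _ = fit_predict(spec, {}, tr, ds.rows("test").wrist_hr)
        mutated = split_train_test(dataset(60, noise_sd=1.0, seed=6))
        mask = mutated.split_assignment == "test"
        mutated.reference_hr[mask] += 1000.0  # corrupt test targets only
        pred_after, _ = fit_predict(spec, {}, mutated.rows("train"),
                                    mutated.rows("test").wrist_hr)
        assert np.array_equal(pred_before, pred_after)

    def test_selected_point_has_best_cv_score(self):
        ds = split_train_test(dataset(60, noise_sd=2.0, seed=7))
        tr = ds.rows("train")
        spec = ModelSpec("knn", {"n_neighbors": [1, 5, 11]})
        best = grid_search(spec, tr, seed=0)
        for hp in spec.grid_points():
            assert kfold_cv(spec, hp, tr, seed=0) <= best["best_score"] + 1e-12
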