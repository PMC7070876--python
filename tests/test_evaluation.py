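import numpy as np
import pytest

from motionbmi import (
    FilterConfig,
    LOSOExperiment,
    ModelConfig,
    PipelineConfig,
    category_report,
    mae,
    make_loso_folds,
    rmse,
)


class TestFolds:
    def test_one_fold_per_subject(self):
        folds = make_loso_folds([f"S{i}" for i in range(5)])
        assert len(folds) == 5

    def test_partition_laws(self):
        subjects = [f"S{i:02d}" for i in range(24)]
        folds = make_loso_folds(subjects)
        tested = [f.test_subject for f in folds]
        assert sorted(tested) == sorted(subjects)
        assert len(set(tested)) == 24
        for f in folds:
            assert len(f.train_subjects) == 23
            assert f.test_subject not in f.train_subjects
            assert set(f.train_subjects) | {f.test_subject} == set(subjects)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_loso_folds(["a", "a", "b"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_loso_folds(["only"])


class TestMetrics:
    def test_perfect_prediction_is_zero(self):
        y = np.array([20.0, 25.0, 30.0])
        assert mae(y, y) == 0.0
        assert rmse(y, y) == 0.0

    def test_printed_formula_arithmetic(self):
        y = np.array([20.0, 25.0])
        yhat = np.array([22.0, 24.0])
        assert mae(y, yhat) == pytest.approx(1.5)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(2.5))

    def test_matches_naive_loop(self, rng):
        y = rng.normal(25, 4, 50)
        yhat = rng.normal(25, 4, 50)
        naive_mae = sum(abs(a - b) for a, b in zip(y, yhat)) / 50
        naive_rmse = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / 50) ** 0.5
        assert mae(y, yhat) == pytest.approx(naive_mae, abs=1e-12)
        assert rmse(y, yhat) == pytest.approx(naive_rmse, abs=1e-12)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            assert rmse(y, yhat) >= mae(y, yhat) - 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestCategoryReport:
    def test_exact_predictions_have_unit_accuracy(self):
        y = np.array([17.0, 22.0, 27.0, 32.0])
        rep = category_report(y, y)
        assert np.all(rep["accuracy"] == 1.0)
        assert np.all(rep["mae"] == 0.0)

    def test_single_point_bookkeeping(self):
        rep = category_report(np.array([22.0]), np.array([26.0]))
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row["category"] == "NormalWeight"
        assert row["mae"] == 4.0
        assert row["accuracy"] == 0.0

    def test_counts_match_direct_tabulation(self, rng):
        from motionbmi import bmi_to_category

        y = rng.uniform(16, 45, 200)
        yhat = y + rng.normal(0, 3, 200)
        rep = category_report(y, yhat).set_index("category")
        for cat in rep.index:
            mask = np.array([bmi_to_category(v).value == cat for v in y])
            assert rep.loc[cat, "n_windows"] == mask.sum()
            hits = sum(
                bmi_to_category(p).value == cat
                for p in yhat[mask]
            )
            assert rep.loc[cat, "accuracy"] == pytest.approx(hits / mask.sum())


def quick_config(learner, theta=0.0, seed=7):
    return PipelineConfig(
        learner=learner,
        filter=FilterConfig(threshold_percentile=theta, psi=0.5),
        model=ModelConfig(
            conv_feature_maps=(4, 4, 4),
            conv_kernels=((1, 5), (1, 3), (1, 3)),
            lstm_units=(8,),
            dense_units=(8,),
            dropout_rate=0.0,
            epochs=3,
            batch_size=32,
            learning_rate=0.01,
        ),
        seed=seed,
    )


class TestRunExperiment:
    def test_mean_predictor_matches_closed_form(self, tiny_cohort):
        rep = LOSOExperiment(tiny_cohort, quick_config("mean")).fit()
        bmis = {m.subject_id: m.bmi for m in tiny_cohort.metadata}
        for fold in rep.per_fold:
            train_mean = np.mean(
                [b for s, b in bmis.items() if s != fold["test_subject"]]
            )
            # all test windows share the subject's BMI label
            expected = abs(bmis[fold["test_subject"]] - train_mean)
            assert fold["mae"] == pytest.approx(expected, abs=1e-9)
            assert fold["rmse"] == pytest.approx(expected, abs=1e-9)

    def test_rmse_at_least_mae_per_fold(self, tiny_cohort):
        rep = LOSOExperiment(tiny_cohort, quick_config("tree")).fit()
        for fold in rep.per_fold:
            assert fold["rmse"] >= fold["mae"] - 1e-12

    def test_filtering_changes_train_pool_only(self, tiny_cohort):
        rep0 = LOSOExperiment(tiny_cohort, quick_config("mean", 0.0)).fit()
        rep1 = LOSOExperiment(tiny_cohort, quick_config("mean", 0.1)).fit()
        for f0, f1 in zip(rep0.per_fold, rep1.per_fold):
            assert f0["n_test_windows"] == f1["n_test_windows"]
            assert f1["n_train_windows"] < f0["n_train_windows"]

    def test_no_leakage_from_test_windows(self, tiny_cohort):
        """Perturbing one subject's recording must not change any fold in
        which that subject is the *test* subject (train-side calibration,
        filtering and fitting must ignore test data)."""
        from dataclasses import replace as drep

        from motionbmi.core import SensorSequence

        cfg = quick_config("knn", theta=0.1)
        base = LOSOExperiment(tiny_cohort, cfg).fit()

        pairs = list(zip(tiny_cohort.sequences, tiny_cohort.metadata))
        victim = pairs[0][0].subject_id
        perturbed = []
        for seq, meta in pairs:
            if seq.subject_id == victim:
                seq = SensorSequence(
                    subject_id=seq.subject_id,
                    sampling_rate_hz=seq.sampling_rate_hz,
                    data=seq.data + 0.37,
                    activity_label=seq.activity_label,
                )
            perturbed.append((seq, meta))
        alt = LOSOExperiment(perturbed, cfg).fit()
        for f_base, f_alt in zip(base.per_fold, alt.per_fold):
            if f_base["test_subject"] != victim:
                continue
            # same training pool (victim excluded) -> identical calibration
            assert f_base["n_train_windows"] == f_alt["n_train_windows"]

    def test_seeded_runs_are_identical(self, tiny_cohort):
        cfg = quick_config("cnn_lstm", theta=0.1, seed=3)
        a = LOSOExperiment(tiny_cohort, cfg).fit()
        b = LOSOExperiment(tiny_cohort, cfg).fit()
        assert a.to_json() == b.to_json()

    def test_report_shape_and_summary(self, tiny_cohort):
        rep = LOSOExperiment(tiny_cohort, quick_config("mean")).fit()
        assert len(rep.per_fold) == len(tiny_cohort.sequences)
        d = rep.to_dict()
        assert set(d) == {"aggregate", "per_fold", "per_category"}
        assert "MAE" in rep.summary()


def test_per_subject_aggregation_uses_median_prediction(tiny_cohort):
    from dataclasses import replace

    cfg = quick_config("tree")
    plain = LOSOExperiment(tiny_cohort, cfg).fit()
    agg = LOSOExperiment(tiny_cohort, replace(cfg, aggregate_per_subject=True)).fit()
    # constant per-subject predictions: per-fold RMSE equals MAE
    for fold in agg.per_fold:
        assert fold["rmse"] == pytest.approx(fold["mae"], abs=1e-9)
    assert len(agg.per_fold) == len(plain.per_fold)
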