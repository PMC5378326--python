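import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import deltol as dt
from deltol.exceptions import (
    DegenerateLabelError,
    EncodingError,
    UndefinedAUCError,
)
from deltol.model import (
    encode_design,
    fit_logistic,
    fit_svm_rbf,
    kfold_partition,
    pooled_cv_predictions,
)

from conftest import welch_oracle


class TestModelSpecs:
    def test_fifteen_specs_per_learner(self):
        for learner in ("logistic", "svm_rbf"):
            specs = dt.enumerate_model_specs(learner)
            assert len(specs) == 15
            assert len({s.predictors for s in specs}) == 15

    def test_four_singletons_first(self):
        specs = dt.enumerate_model_specs()
        assert sum(len(s.predictors) == 1 for s in specs[:4]) == 4

    def test_order_is_deterministic(self):
        assert dt.enumerate_model_specs() == dt.enumerate_model_specs()

    def test_empty_predictors_rejected(self):
        with pytest.raises(ValueError):
            dt.ModelSpec(predictors=())

    def test_display_names(self):
        spec = dt.ModelSpec(("mean_score", "wcn", "rsa"))
        assert spec.name == "RSA + WCN + Mean Score"


class TestEncodeDesign:
    def test_single_continuous_column(self, default_table):
        table, _ = default_table
        d = encode_design(table, dt.ModelSpec(("wcn",)))
        assert d.X.shape == (72, 1)
        assert d.columns == ["wcn"]

    def test_ss_reference_dropped_for_logistic(self, default_table):
        table, _ = default_table
        d = encode_design(table, dt.ModelSpec(("rsa", "wcn", "ss")))
        assert d.X.shape[1] == 4  # 2 continuous + 2 indicators
        assert "ss_helix" not in d.columns

    def test_ss_full_indicators_for_svm(self, default_table):
        table, _ = default_table
        d = encode_design(table, dt.ModelSpec(("ss",), learner="svm_rbf"))
        assert d.columns == ["ss_helix", "ss_loop", "ss_sheet"]
        np.testing.assert_allclose(d.X.sum(axis=1), 1.0)

    def test_missing_values_listed(self, default_table):
        table, _ = default_table
        broken = table.copy()
        broken.loc[3, "wcn"] = np.nan
        with pytest.raises(EncodingError, match="mut004"):
            encode_design(broken, dt.ModelSpec(("wcn",)))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # ML intercept of an empty model is the log-odds of the base rate
        y = np.array([1] * 34 + [0] * 38)
        table = pd.DataFrame(
            {"rsa": np.zeros(72), "functional": y, "ss": "loop",
             "wcn": 0.0, "mean_score": 0.0}
        )
        d = encode_design(table, dt.ModelSpec(("rsa",)))
        d.X = d.X[:, :0]  # drop all predictors -> intercept only
        d.columns = []
        fit = fit_logistic(d)
        assert fit.params["const"] == pytest.approx(np.log(34 / 38), abs=1e-6)

    def test_simulation_recovery_within_3se(self):
        params = dt.SynthParams(
            n_mutants=2000, label_mode="logistic",
            coefficients={"const": 0.0, "wcn": -2.0},
            wcn_distributions={"tolerated": (0.0, 1.0),
                               "non_tolerated": (0.0, 1.0)},
            seed=12,
        )
        table, _ = dt.synth_feature_table(params)
        fit = fit_logistic(encode_design(table, dt.ModelSpec(("wcn",))))
        assert abs(fit.params["wcn"] - (-2.0)) < 3 * fit.bse["wcn"]
        assert abs(fit.params["const"]) < 3 * fit.bse["const"]

    def test_perfect_separation_flagged_order_preserved(self):
        x = np.linspace(-1, 1, 20)
        table = pd.DataFrame(
            {"wcn": x, "functional": x > 0, "rsa": 0.0,
             "ss": "loop", "mean_score": 0.0}
        )
        fit = fit_logistic(encode_design(table, dt.ModelSpec(("wcn",))))
        assert fit.separation
        order = np.argsort(fit.fitted)
        assert (table["functional"].to_numpy()[order][-10:]).all()

    def test_single_class_rejected(self):
        table = pd.DataFrame(
            {"wcn": [0.1, 0.2, 0.3], "functional": True, "rsa": 0.0,
             "ss": "loop", "mean_score": 0.0}
        )
        with pytest.raises(DegenerateLabelError):
            fit_logistic(encode_design(table, dt.ModelSpec(("wcn",))))


class TestFitSVM:
    def _cluster_table(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(10, 0.1, size=(10, 2))
        return pd.DataFrame(
            {"rsa": np.r_[a[:, 0], b[:, 0]], "wcn": np.r_[a[:, 1], b[:, 1]],
             "functional": [False] * 10 + [True] * 10,
             "ss": "loop", "mean_score": 0.0}
        )

    def test_separated_clusters_training_accuracy_one(self):
        d = encode_design(self._cluster_table(),
                          dt.ModelSpec(("rsa", "wcn"), learner="svm_rbf"))
        fit = fit_svm_rbf(d)
        assert np.all((fit.fitted > 0) == d.y.astype(bool))

    def test_gamma_defaults_to_one_over_d(self, default_table):
        table, _ = default_table
        d = encode_design(
            table, dt.ModelSpec(("rsa", "wcn", "mean_score"),
                                learner="svm_rbf")
        )
        fit = fit_svm_rbf(d)
        assert fit.gamma == pytest.approx(1 / 3)
        d5 = encode_design(
            table, dt.ModelSpec(("rsa", "wcn", "ss"), learner="svm_rbf")
        )
        assert fit_svm_rbf(d5).gamma == pytest.approx(1 / 5)

    def test_decision_sign_consistent_with_prediction(self, default_table):
        table, _ = default_table
        d = encode_design(table, dt.ModelSpec(("rsa", "wcn"),
                                              learner="svm_rbf"))
        fit = fit_svm_rbf(d)
        preds = fit.svc.predict(fit.scaler.transform(d.X))
        assert np.all((fit.fitted > 0) == (preds == 1))


class TestKFoldPartition:
    def test_72_in_10_fold_sizes(self):
        folds = kfold_partition(72, 10, 0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [7] * 8 + [8] * 2
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(72))

    def test_leave_one_out_singletons(self):
        folds = kfold_partition(10, 10, 1)
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_same_partition(self):
        a = kfold_partition(30, 4, 99)
        b = kfold_partition(30, 4, 99)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(5, 6, 0)


class TestROCAUC:
    def test_perfect_separation(self):
        r = dt.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties(self):
        r = dt.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert r.auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(17)
        scores = rng.integers(0, 20, size=200).astype(float)  # with ties
        labels = rng.integers(0, 2, size=200)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        u = scipy.stats.mannwhitneyu(
            scores[labels == 1], scores[labels == 0], alternative="two-sided"
        ).statistic
        assert dt.roc_auc(scores, labels).auc == pytest.approx(
            u / (n_pos * n_neg), abs=1e-12
        )

    def test_curve_is_monotone_from_0_to_1(self):
        rng = np.random.default_rng(2)
        r = dt.roc_auc(rng.normal(size=50), rng.integers(0, 2, 50))
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            dt.roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_negation_symmetry_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(30).astype(float)  # distinct -> tie-free
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        a = dt.roc_auc(scores, labels).auc
        b = dt.roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a = dt.roc_auc(scores, labels).auc
        b = dt.roc_auc(np.exp(3 * scores) + 5, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestPooledCV:
    def test_every_row_scored_once_by_heldout_model(self, small_table):
        spec = dt.ModelSpec(("rsa", "wcn"))
        partition = kfold_partition(len(small_table), 10, 3)
        scores = pooled_cv_predictions(small_table, spec, partition)
        assert np.isfinite(scores).all() and len(scores) == len(small_table)

    def test_leave_one_out_matches_handrolled_loop(self, small_table):
        table = small_table.iloc[:14].reset_index(drop=True)
        spec = dt.ModelSpec(("wcn",))
        partition = kfold_partition(len(table), len(table), 5)
        ours = pooled_cv_predictions(table, spec, partition)
        # independent loop: statsmodels logit per left-out row
        import statsmodels.api as sm
        expected = np.empty(len(table))
        x = table["wcn"].to_numpy()
        y = table["functional"].to_numpy(dtype=int)
        for i in range(len(table)):
            mask = np.arange(len(table)) != i
            m = sm.Logit(y[mask], sm.add_constant(x[mask]))
            m.raise_on_perfect_prediction = False
            res = m.fit(disp=0, maxiter=100, warn_convergence=False)
            expected[i] = res.predict([1.0, x[i]])[0]
        np.testing.assert_allclose(ours, expected, rtol=1e-8)

    def test_degenerate_training_fold_rejected(self):
        table = pd.DataFrame(
            {"wcn": np.arange(6, dtype=float),
             "functional": [True] + [False] * 5,
             "rsa": 0.0, "ss": "loop", "mean_score": 0.0}
        )
        # fold containing the single positive row makes training one-class
        partition = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        with pytest.raises(DegenerateLabelError):
            pooled_cv_predictions(table, dt.ModelSpec(("wcn",)), partition)

    def test_deterministic_under_fixed_seed(self, small_table):
        spec = dt.ModelSpec(("rsa", "wcn"), learner="svm_rbf")
        p1 = kfold_partition(len(small_table), 10, 7)
        p2 = kfold_partition(len(small_table), 10, 7)
        np.testing.assert_array_equal(
            pooled_cv_predictions(small_table, spec, p1),
            pooled_cv_predictions(small_table, spec, p2),
        )


class TestRepeatedCV:
    def test_se_zero_when_all_repetitions_identical(self):
        # perfectly separable single feature -> every repetition AUC = 1
        table = pd.DataFrame(
            {"wcn": np.r_[np.zeros(10), np.ones(10)],
             "functional": [False] * 10 + [True] * 10,
             "rsa": 0.0, "ss": "loop", "mean_score": 0.0}
        )
        s = dt.repeated_cv_auc(
            table, dt.ModelSpec(("wcn",)), dt.CVConfig(k=5, repetitions=5,
                                                       seed=0)
        )
        np.testing.assert_allclose(s.repetition_aucs, 1.0)
        assert s.se_auc == 0.0

    def test_informative_predictor_high_auc(self):
        params = dt.SynthParams(n_mutants=100, seed=6)
        table, _ = dt.synth_feature_table(params)
        table["wcn"] = np.where(table["functional"], 0.0, 1.0) \
            + np.random.default_rng(0).normal(0, 0.01, 100)
        s = dt.repeated_cv_auc(
            table, dt.ModelSpec(("wcn",)),
            dt.CVConfig(repetitions=5, seed=1),
        )
        assert s.mean_auc >= 0.95

    def test_summary_mentions_spec(self, small_table):
        s = dt.repeated_cv_auc(
            small_table, dt.ModelSpec(("rsa",)),
            dt.CVConfig(repetitions=3, seed=2),
        )
        assert "RSA" in s.summary()
        assert s.repetitions == 3


class TestFullFitAndComparison:
    def test_separable_data_full_fit_auc_one(self):
        table = pd.DataFrame(
            {"wcn": np.r_[np.zeros(8), np.ones(8)],
             "functional": [False] * 8 + [True] * 8,
             "rsa": 0.0, "ss": "loop", "mean_score": 0.0}
        )
        assert dt.full_fit_auc(table, dt.ModelSpec(("wcn",))) == 1.0

    def test_shuffled_labels_near_half(self):
        params = dt.SynthParams(n_mutants=400, label_mode="logistic",
                                coefficients={"const": 0.0}, seed=3)
        table, _ = dt.synth_feature_table(params)
        auc = dt.full_fit_auc(table, dt.ModelSpec(("rsa", "wcn")))
        assert abs(auc - 0.5) < 0.1

    def test_full_fit_at_least_cv_on_signal(self, default_table):
        table, _ = default_table
        spec = dt.ModelSpec(("rsa", "wcn", "mean_score"))
        full = dt.full_fit_auc(table, spec)
        cv = dt.repeated_cv_auc(table, spec,
                                dt.CVConfig(repetitions=20, seed=4))
        assert full >= cv.mean_auc - 2 * cv.se_auc

    def test_identical_auc_lists_t0_p1(self):
        a = dt.CVSummary(dt.ModelSpec(("wcn",)), [0.8] * 10)
        t, p = dt.compare_models(a, a)
        assert (t, p) == (0.0, 1.0)

    def test_separated_auc_lists_tiny_p(self):
        rng = np.random.default_rng(1)
        a = dt.CVSummary(dt.ModelSpec(("wcn",)),
                         0.9 + rng.normal(0, 1e-3, 100))
        b = dt.CVSummary(dt.ModelSpec(("rsa",)),
                         0.5 + rng.normal(0, 1e-3, 100))
        _, p = dt.compare_models(a, b)
        assert p < 1e-3 / 1e10

    def test_matches_welch_formula_on_fixture(self):
        xa = [0.81, 0.83, 0.82, 0.85, 0.80]
        xb = [0.78, 0.80, 0.77, 0.81, 0.79]
        a = dt.CVSummary(dt.ModelSpec(("wcn",)), xa)
        b = dt.CVSummary(dt.ModelSpec(("rsa",)), xb)
        t, p = dt.compare_models(a, b)
        t_ref, _, p_ref = welch_oracle(xa, xb)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_paired_comparison(self):
        a = dt.CVSummary(dt.ModelSpec(("wcn",)), [0.9, 0.91, 0.92, 0.93])
        b = dt.CVSummary(dt.ModelSpec(("rsa",)), [0.8, 0.81, 0.82, 0.83])
        t, p = dt.compare_models(a, b, paired=True)
        assert p < 1e-6  # constant difference of 0.1


class TestToleranceModelFrontEnd:
    def test_fit_summary_and_predict(self, default_table):
        table, _ = default_table
        model = dt.ToleranceModel(table, predictors=("rsa", "wcn"),
                                  learner="logistic")
        res = model.fit()
        assert 0.5 < res.auc <= 1.0
        assert set(res.params.index) == {"const", "rsa", "wcn"}
        assert "Model AUC" in res.summary()
        np.testing.assert_allclose(res.predict(table), res.fittedvalues,
                                   rtol=1e-10)

    def test_svm_results_report_gamma(self, default_table):
        table, _ = default_table
        res = dt.ToleranceModel(
            table, predictors=("rsa", "wcn", "ss"), learner="svm_rbf"
        ).fit()
        assert res.params is None
        assert "gamma = 0.2000" in res.summary()

    def test_cross_validate_matches_function(self, small_table):
        model = dt.ToleranceModel(small_table, predictors=("wcn",))
        cv = dt.CVConfig(repetitions=4, seed=5)
        s1 = model.cross_validate(cv)
        s2 = dt.repeated_cv_auc(small_table, model.spec, cv)
        np.testing.assert_allclose(s1.repetition_aucs, s2.repetition_aucs)

    def test_evaluate_models_shape_and_sort(self, small_table):
        df = dt.evaluate_models(small_table, "logistic",
                                dt.CVConfig(repetitions=2, seed=0))
        assert len(df) == 15
        assert list(df.columns) == ["model", "model_auc", "mean_cv_auc",
                                    "se_cv_auc"]
        assert (df["mean_cv_auc"].diff().dropna() <= 1e-12).all()
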