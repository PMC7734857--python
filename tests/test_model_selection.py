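"""Tests for design-matrix assembly, the logistic fit, CV folds and the GA."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from hrvoutcome import (
    CVScheme,
    GAConfig,
    build_design_matrix,
    fit_logistic,
    ga_select,
    make_folds,
    predict_prob,
    youden_fitness,
)
from hrvoutcome.model_selection import training_rows
from tests.conftest import make_noise_cohort


@pytest.fixture(scope="module")
def noise_cohort():
    return make_noise_cohort(seed=0)


class TestDesignMatrix:
    def test_constant_severity_covariate(self, noise_cohort):
        pids = [p.patient_id for p in noise_cohort.patients[:4]]
        rows = [(pid, tp) for pid in pids for tp in range(1, 6)]
        X, y, row_pids = build_design_matrix(noise_cohort, ["APACHE_II"], rows)
        assert X.shape == (20, 1)
        for pid in pids:
            vals = X[[i for i, p in enumerate(row_pids) if p == pid], 0]
            assert np.all(vals == vals[0])

    def test_mixed_plain_and_distance_features(self, noise_cohort):
        feats = ["HR", "DistHR", "DistHF_Hz", "DistVLF_perc", "DistHF_perc", "DistLF_HF"]
        rows = [(p.patient_id, tp) for p in noise_cohort.patients[:5] for tp in (1, 2, 3, 4, 5)]
        X, y, _ = build_design_matrix(noise_cohort, feats, rows)
        assert X.shape == (25, 6)
        assert np.all(np.isfinite(X))

    def test_unknown_feature_lists_valid_names(self, noise_cohort):
        with pytest.raises(ValueError, match="valid names"):
            build_design_matrix(noise_cohort, ["NotAFeature"], [("S01", 1)])

    def test_time_point_beyond_record_rejected(self, noise_cohort):
        with pytest.raises(ValueError, match="no distance window"):
            build_design_matrix(noise_cohort, ["DistHR"], [("S01", 99)])


class TestFitLogistic:
    def test_symmetric_toy_data_zero_intercept(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        model = fit_logistic(X, y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        assert model.coef[0] > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_slope_recovered(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, size=5000)
        y = (rng.random(5000) < expit(2.0 * x)).astype(int)
        model = fit_logistic(x[:, None], y)
        assert model.coef[0] == pytest.approx(2.0, abs=0.15)

    def test_constant_column_shrunk_not_crashing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = (x > 0).astype(int)
        X = np.column_stack([x, np.full(100, 7.0)])
        model = fit_logistic(X, y)
        assert np.isfinite(model.coef).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(np.ones((5, 1)), np.zeros(5))

    def test_matches_sklearn_ridge_equivalent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < expit(X @ [1.0, -0.5, 0.25])).astype(int)
        ours = fit_logistic(X, y, ridge=1e-4)
        sk = LogisticRegression(C=1e4, solver="lbfgs", tol=1e-10, max_iter=5000).fit(X, y)
        assert ours.intercept == pytest.approx(sk.intercept_[0], abs=1e-3)
        assert ours.coef == pytest.approx(sk.coef_[0], abs=1e-3)

    def test_matches_bruteforce_grid_search(self):
        # independent oracle: nested grid refinement of the penalized
        # negative log-likelihood on a 20-row 1-feature problem
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = (rng.random(20) < expit(0.8 * x)).astype(int)
        ridge = 1e-4

        b0, b1, half = 0.0, 0.0, 4.0
        for _ in range(12):
            g0 = np.linspace(b0 - half, b0 + half, 41)
            g1 = np.linspace(b1 - half, b1 + half, 41)
            eta = g0[:, None, None] + g1[None, :, None] * x[None, None, :]
            vals = np.sum(np.logaddexp(0.0, eta) - y * eta, axis=-1)
            vals += 0.5 * ridge * g1[None, :] ** 2
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            b0, b1, half = g0[i], g1[j], half / 8.0
        model = fit_logistic(x[:, None], y, ridge=ridge)
        assert model.intercept == pytest.approx(b0, abs=0.01)
        assert model.coef[0] == pytest.approx(b1, abs=0.01)


class TestPredictProb:
    def test_null_model_gives_half(self):
        rng = np.random.default_rng(0)
        model = fit_logistic(rng.normal(size=(10, 2)), np.array([0, 1] * 5))
        from hrvoutcome.model_selection import FittedClassifier
        null = FittedClassifier(intercept=0.0, coef=np.zeros(2))
        assert predict_prob(null, rng.normal(size=(5, 2))) == pytest.approx(np.full(5, 0.5))
        del model

    def test_monotone_in_linear_predictor(self):
        from hrvoutcome.model_selection import FittedClassifier
        model = FittedClassifier(intercept=0.0, coef=np.array([1.0]))
        xs = np.linspace(-50, 50, 11)[:, None]
        p = predict_prob(model, xs)
        assert np.all(np.diff(p) >= 0)
        assert 0.0 < p[0] and p[-1] < 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < expit(X @ [1.0, -1.0, 0.5])).astype(int)
        m1 = fit_logistic(X, y)
        perm = [2, 0, 1]
        m2 = fit_logistic(X[:, perm], y)
        assert predict_prob(m1, X) == pytest.approx(predict_prob(m2, X[:, perm]), abs=1e-8)

    def test_column_mismatch_rejected(self):
        from hrvoutcome.model_selection import FittedClassifier
        model = FittedClassifier(intercept=0.0, coef=np.array([1.0, 2.0]),
                                 feature_names=("a", "b"))
        with pytest.raises(ValueError, match="column mismatch"):
            predict_prob(model, np.ones((3, 3)))
        with pytest.raises(ValueError, match="column mismatch"):
            predict_prob(model, np.ones((3, 2)), feature_names=("b", "a"))


class TestMakeFolds:
    def test_default_cohort_fold_composition(self, short_cohort):
        dataset, _ = short_cohort
        folds = make_folds(dataset, CVScheme(rng_seed=5))
        assert len(folds) == 25  # 5 repeats x 5 folds
        for fold in folds:
            labels = [dataset.get(pid).label for pid in fold.test_patients]
            assert sum(labels) == 1 and len(labels) == 5  # 1 non-survivor + 4 survivors
            assert len(fold.test_rows) == 25

    def test_no_patient_leaks_between_train_and_test(self, short_cohort):
        dataset, _ = short_cohort
        for fold in make_folds(dataset, CVScheme(rng_seed=6)):
            train_pids = {pid for pid, _ in training_rows(dataset, fold)}
            assert train_pids.isdisjoint(fold.test_patients)

    def test_paper_literal_keeps_other_rows_of_test_patients(self):
        # 16 epoch rows -> 9 valid windows, of which 5 become test rows
        dataset = make_noise_cohort(seed=2, n_rows=16)
        fold = make_folds(dataset, CVScheme(rng_seed=6))[0]
        literal = training_rows(dataset, fold, paper_literal=True)
        assert set(literal).isdisjoint(fold.test_rows)
        assert any(pid in fold.test_patients for pid, _ in literal)

    def test_same_seed_reproduces_folds(self, short_cohort):
        dataset, _ = short_cohort
        f1 = make_folds(dataset, CVScheme(rng_seed=7))
        f2 = make_folds(dataset, CVScheme(rng_seed=7))
        assert f1 == f2

    def test_patient_with_few_windows_contributes_all_with_warning(self):
        cohort = make_noise_cohort(seed=2, n_rows=10)  # 3 valid windows each
        with pytest.warns(UserWarning, match="valid windows"):
            folds = make_folds(cohort, CVScheme(n_repeats=1, rng_seed=0))
        assert all(len(f.test_rows) == 3 * len(f.test_patients) for f in folds)


class TestYoudenFitness:
    def test_oracle_feature_reaches_one(self):
        cohort = make_noise_cohort(seed=3)
        for p in cohort.patients:  # plant a perfectly separating feature
            p.features["HR"] = 100.0 + 50.0 * p.label + p.features["HR"] * 0.01
            p.distf["DistHR"] = 0.0  # keep distance columns finite
        scheme = CVScheme(n_repeats=1, rng_seed=1)
        assert youden_fitness(["HR"], cohort, scheme) == pytest.approx(1.0)

    def test_all_negative_classifier_scores_zero(self):
        cohort = make_noise_cohort(seed=4)
        folds = make_folds(cohort, CVScheme(n_repeats=1, rng_seed=2))
        from hrvoutcome.model_selection import _fold_youden
        y = np.array([cohort.get(pid).label for pid, _ in folds[0].test_rows])
        j = _fold_youden(y, np.full(y.size, 0.1), cutoff=0.5)
        assert j == pytest.approx(0.0)  # sensitivity 0, specificity 1

    def test_empty_feature_set_scores_minus_one(self):
        cohort = make_noise_cohort(seed=5)
        assert youden_fitness([], cohort, CVScheme(rng_seed=0)) == -1.0

    def test_uninformative_features_score_near_zero_on_average(self):
        js = [
            youden_fitness(["SDNN", "DistRMSSD"], make_noise_cohort(seed=100 + s),
                           CVScheme(n_repeats=1, rng_seed=s))
            for s in range(50)
        ]
        assert abs(float(np.mean(js))) < 0.12

    def test_bounds(self):
        for s in range(5):
            j = youden_fitness(["HR"], make_noise_cohort(seed=200 + s),
                               CVScheme(n_repeats=1, rng_seed=s))
            assert -1.0 <= j <= 1.0


class TestGASelect:
    def test_zero_generations_returns_best_of_initial_population(self):
        cohort = make_noise_cohort(seed=6)
        config = GAConfig(population_size=10, n_generations=0, n_runs=2, rng_seed=3)
        res = ga_select(cohort, CVScheme(n_repeats=1, rng_seed=3), config,
                        candidate_features=["HR", "SDNN", "RMSSD"])
        assert len(res.run_best) == 2
        assert res.final_feature_set

    def test_constant_fitness_treats_features_symmetrically(self):
        # with parsimony tie-breaking (default) a flat landscape collapses
        # to the smallest chromosome, so every frequency is equal and low
        config = GAConfig(population_size=20, n_generations=5, n_runs=50, rng_seed=4)
        res = ga_select(None, None, config, candidate_features=list("abcdefgh"),
                        fitness_fn=lambda mask: 0.0)
        freqs = np.array(list(res.selection_frequency.values()))
        assert np.all(freqs <= 0.2)

    def test_constant_fitness_without_parsimony_keeps_frequencies_near_half(self):
        config = GAConfig(population_size=20, n_generations=5, n_runs=50, rng_seed=4,
                          parsimony_ties=False)
        res = ga_select(None, None, config, candidate_features=list("abcdefgh"),
                        fitness_fn=lambda mask: 0.0)
        freqs = np.array(list(res.selection_frequency.values()))
        assert np.all((0.25 <= freqs) & (freqs <= 0.75))

    def test_best_fitness_history_monotone_under_elitism(self):
        cohort = make_noise_cohort(seed=7)
        config = GAConfig(population_size=10, n_generations=10, n_runs=2, rng_seed=5)
        res = ga_select(cohort, CVScheme(n_repeats=1, rng_seed=5), config,
                        candidate_features=["HR", "SDNN", "DistHR", "DistSDNN"])
        for hist in res.best_fitness_history:
            assert np.all(np.diff(hist) >= 0)

    def test_identical_seeds_give_identical_results(self):
        cohort = make_noise_cohort(seed=8)
        config = GAConfig(population_size=10, n_generations=5, n_runs=3, rng_seed=6)
        r1 = ga_select(cohort, CVScheme(n_repeats=1, rng_seed=6), config,
                       candidate_features=["HR", "SDNN", "DistHR"])
        r2 = ga_select(cohort, CVScheme(n_repeats=1, rng_seed=6), config,
                       candidate_features=["HR", "SDNN", "DistHR"])
        assert r1.run_best == r2.run_best
        assert r1.selection_frequency == r2.selection_frequency
        assert r1.final_feature_set == r2.final_feature_set

    def test_population_size_must_be_even(self):
        with pytest.raises(ValueError, match="even"):
            GAConfig(population_size=7)

    def test_serialisation_round_trip(self):
        cohort = make_noise_cohort(seed=9)
        config = GAConfig(population_size=10, n_generations=2, n_runs=2, rng_seed=7)
        res = ga_select(cohort, CVScheme(n_repeats=1, rng_seed=7), config,
                        candidate_features=["HR", "SDNN"])
        d = res.to_dict()
        assert set(d) == {"candidate_features", "runs", "selection_frequency",
                          "final_feature_set"}
        assert all(set(r["chromosome"]) <= {"0", "1"} for r in d["runs"])
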