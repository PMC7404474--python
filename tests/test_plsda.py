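import warnings

import numpy as np
import pytest

from oracles import bayes_threshold_grid, kennard_stone_greedy_check
from olivegrade.core import OliveGradeError
from olivegrade.plsda import (
    PLSDAModel,
    RankExhaustedError,
    bayes_threshold,
    choose_n_lv,
    fit_pls,
    kennard_stone_split,
    predict_proba,
    venetian_blinds_folds,
)


class TestKennardStone:
    def test_three_point_worked_example(self):
        X = np.array([[0.0], [1.0], [10.0]])
        split = kennard_stone_split(X, 1 / 3, sample_ids=["a", "b", "c"])
        # the calibration set is the mutually most distant pair {0, 10}
        assert split.calibration_ids == ["a", "c"]
        assert split.external_ids == ["b"]

    def test_forced_selection_on_a_line(self):
        X = np.array([[0.0], [1.0], [10.0], [20.0]])
        split = kennard_stone_split(X, 0.25, sample_ids=list("abcd"))
        # start pair {0, 20}; next max-min point is 10 -> external = {1}
        assert set(split.calibration_ids) == {"a", "c", "d"}
        assert split.external_ids == ["b"]

    def test_deterministic(self, rng):
        X = rng.normal(0, 1, (17, 6))
        a = kennard_stone_split(X, 0.25)
        b = kennard_stone_split(X, 0.25)
        assert a.calibration_ids == b.calibration_ids
        assert a.external_ids == b.external_ids

    def test_external_count_rounds_half_up(self, rng):
        X = rng.normal(0, 1, (10, 3))
        split = kennard_stone_split(X, 0.25)
        assert len(split.external_ids) == 3  # round(2.5) half-up

    def test_greedy_steps_optimal_small_n(self, rng):
        for _ in range(12):
            n = int(rng.integers(5, 9))
            X = rng.normal(0, 1, (n, 3))
            split = kennard_stone_split(X, 0.25)
            order = [int(s) for s in split.selection_order]
            assert kennard_stone_greedy_check(X, order)

    def test_fraction_bounds(self, rng):
        X = rng.normal(0, 1, (8, 2))
        for bad in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(OliveGradeError):
                kennard_stone_split(X, bad)


class TestNIPALS:
    def test_full_rank_fit_reproduces_ols(self, rng):
        for _ in range(20):
            n, p = 12, 5
            X = rng.normal(0, 1, (n, p))
            y = (rng.normal(0, 1, n) > 0).astype(float)
            if min(y.sum(), n - y.sum()) < 2:  # need 2+ per class for the score stats
                continue
            model = fit_pls(X, y, p)
            yhat = model.decision_function(X)
            Xc = (X - model.x_mean) / model.x_sd
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), Xc]), y, rcond=None
            )
            ols = beta[0] + Xc @ beta[1:]
            np.testing.assert_allclose(yhat, ols, rtol=1e-6, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(0, 1, (30, 40))
        y = (rng.normal(0, 1, 30) > 0).astype(float)
        from olivegrade.plsda import _nipals
        from olivegrade.preprocess import autoscale_fit

        s = autoscale_fit(X)
        Xc = (X - s.mean) / s.sd
        _, _, _, _, T, got = _nipals(Xc, y - y.mean(), 8)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_deflation_residual_norms_decrease(self, rng):
        X = rng.normal(0, 1, (25, 30)).cumsum(axis=1)
        y = (rng.normal(0, 1, 25) > 0).astype(float)
        from olivegrade.plsda import _nipals
        from olivegrade.preprocess import autoscale_fit

        s = autoscale_fit(X)
        Xc = (X - s.mean) / s.sd
        W, P, q, B, T, got = _nipals(Xc, y - y.mean(), 6)
        residual = Xc.copy()
        norms = [np.linalg.norm(residual)]
        for k in range(got):
            residual -= np.outer(T[:, k], P[:, k])
            norms.append(np.linalg.norm(residual))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_rank_one_signal_single_lv_is_univariate_ls(self, rng):
        direction = rng.normal(0, 1, 15)
        t_true = rng.normal(0, 2, 20)
        X = np.outer(t_true, direction)
        y = (t_true > 0).astype(float)
        model = fit_pls(X, y, 1)
        Xc = (X - model.x_mean) / model.x_sd
        t = Xc @ model.W[:, 0]
        slope = (y - y.mean()) @ t / (t @ t)
        np.testing.assert_allclose(
            model.decision_function(X), y.mean() + slope * t, rtol=1e-8, atol=1e-10
        )

    def test_requesting_beyond_rank_names_achievable_max(self, rng):
        X = rng.normal(0, 1, (10, 3))
        y = np.array([0.0, 1.0] * 5)
        with pytest.raises(RankExhaustedError, match="at most"):
            fit_pls(X, y, 9)

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (6, 4))
        with pytest.raises(OliveGradeError, match="zero variance|single class"):
            fit_pls(X, np.ones(6), 1)

    def test_separable_clouds_zero_calibration_errors(self, tiny_fitted_model):
        model, X, y = tiny_fitted_model
        preds = np.array(model.predict(X))
        truth = np.where(y == 1.0, "hi", "lo")
        assert (preds == truth).all()

    def test_variable_permutation_invariance(self, tiny_fitted_model, rng):
        model, X, y = tiny_fitted_model
        perm = rng.permutation(X.shape[1])
        model_p = fit_pls(X[:, perm], y, 2, class_labels=model.class_labels)
        np.testing.assert_allclose(
            model.decision_function(X), model_p.decision_function(X[:, perm]), rtol=1e-9
        )

    def test_matches_sklearn_pls_regression(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(0, 1, (25, 40))
        y = (rng.normal(0, 1, 25) > 0).astype(float)
        model = fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False)
        Xc = (X - model.x_mean) / model.x_sd
        ref.fit(Xc, y - y.mean())
        np.testing.assert_allclose(
            model.decision_function(X),
            y.mean() + ref.predict(Xc).ravel(),
            rtol=1e-6,
            atol=1e-8,
        )


class TestBayesThreshold:
    def test_symmetric_case_is_exact_midpoint(self, rng):
        s0 = rng.normal(0, 0.5, 500) - 1.0
        s1 = -(s0 + 1.0) + 1.0  # mirror image: mean +1, same spread
        thr = bayes_threshold(s0, s1)
        assert thr == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        s0 = rng.normal(-1.0, 0.2, 4000)
        s1 = rng.normal(1.0, 0.8, 4000)
        thr = bayes_threshold(s0, s1)
        mu0, sd0 = s0.mean(), s0.std(ddof=1)
        mu1, sd1 = s1.mean(), s1.std(ddof=1)
        expected = bayes_threshold_grid(mu0, sd0, mu1, sd1)
        assert thr == pytest.approx(expected, abs=1e-4)

    def test_unequal_priors_shift_toward_rarer_class(self):
        rng = np.random.default_rng(6)
        s0 = rng.normal(-1.0, 0.5, 1000)
        s1 = rng.normal(1.0, 0.5, 1000)
        equal = bayes_threshold(s0, s1, (0.5, 0.5))
        skew = bayes_threshold(s0, s1, (0.9, 0.1))
        assert skew > equal  # stronger evidence needed to call the rare class1

    def test_grid_oracle_with_priors(self):
        rng = np.random.default_rng(7)
        s0 = rng.normal(-1.0, 0.3, 4000)
        s1 = rng.normal(1.5, 0.6, 4000)
        thr = bayes_threshold(s0, s1, (0.7, 0.3))
        expected = bayes_threshold_grid(
            s0.mean(), s0.std(ddof=1), s1.mean(), s1.std(ddof=1), (0.7, 0.3)
        )
        assert thr == pytest.approx(expected, abs=1e-4)

    def test_coincident_means_fall_back_to_midpoint_with_warning(self):
        s = np.array([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="midpoint"):
            thr = bayes_threshold(s, s)
        assert thr == pytest.approx(1.0)


class TestPredictProba:
    def test_probabilities_sum_to_one(self, tiny_fitted_model, rng):
        model, X, _ = tiny_fitted_model
        proba = predict_proba(model, rng.normal(1, 2, (40, X.shape[1])))
        np.testing.assert_allclose(proba[:, 0] + proba[:, 1], 1.0, atol=1e-12)

    def test_half_probability_exactly_at_threshold(self, tiny_fitted_model):
        model, X, _ = tiny_fitted_model
        # synthesize a sample whose decision value is the threshold itself
        x = np.zeros(X.shape[1])
        yhat = model.decision_function(x)[0]
        # move along the regression vector to land on the threshold
        direction = model.b / model.x_sd
        step = (model.threshold - yhat) / (direction @ direction)
        x_at = x + step * direction
        p = predict_proba(model, x_at)
        assert p[0, 2] == pytest.approx(model.threshold, abs=1e-9)
        assert p[0, 1] == pytest.approx(0.5, abs=1e-6)

    def test_confident_at_class_mean(self, tiny_fitted_model):
        model, X, y = tiny_fitted_model
        proba = predict_proba(model, X[y == 1.0].mean(axis=0))
        assert proba[0, 1] > 0.99

    def test_labels_agree_with_threshold_rule(self, tiny_fitted_model, rng):
        model, X, _ = tiny_fitted_model
        Z = rng.normal(1, 2, (60, X.shape[1]))
        proba = predict_proba(model, Z)
        labels = model.predict(Z)
        for row, label in zip(proba, labels):
            expected = model.class_labels[1] if row[2] > model.threshold else model.class_labels[0]
            assert label == expected


class TestChooseNLV:
    def test_venetian_blind_fold_structure(self):
        folds = venetian_blinds_folds(10, 4)
        assert [f.tolist() for f in folds] == [[0, 4, 8], [1, 5, 9], [2, 6], [3, 7]]

    def test_one_lv_structure_selected_with_high_probability(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            direction = rng.normal(0, 1, 25)
            t_true = np.concatenate([rng.normal(-2.5, 0.8, 20), rng.normal(2.5, 0.8, 20)])
            X = np.outer(t_true, direction) + rng.normal(0, 0.4, (40, 25))
            y = np.array([0.0] * 20 + [1.0] * 20)
            n_lv, _ = choose_n_lv(X, y, max_lv=6, n_blinds=5)
            hits += n_lv == 1
        assert hits >= 45  # >= 90% of seeds

    def test_exact_tie_prefers_fewer_lvs(self):
        # fully separable along one direction: every LV count scores zero CV
        # error, so the tie rule must return the minimal count
        rng = np.random.default_rng(2)
        direction = rng.normal(0, 1, 15)
        t_true = np.concatenate([rng.normal(-5, 0.3, 15), rng.normal(5, 0.3, 15)])
        X = np.outer(t_true, direction) + rng.normal(0, 0.1, (30, 15))
        y = np.array([0.0] * 15 + [1.0] * 15)
        n_lv, errors = choose_n_lv(X, y, max_lv=5, n_blinds=5)
        assert n_lv == 1
        assert errors[0] == 0.0

    def test_pure_noise_selection_valid_and_deterministic(self):
        rng = np.random.default_rng(100)
        X = rng.normal(0, 1, (40, 30))
        y = np.array([0.0, 1.0] * 20)
        a, ea = choose_n_lv(X, y, max_lv=8, n_blinds=5)
        b, eb = choose_n_lv(X, y, max_lv=8, n_blinds=5)
        assert a == b and ea == eb
        assert 1 <= a <= 8
        # the selected count is the first minimum of the CV error curve
        assert ea[a - 1] == min(ea) and a - 1 == ea.index(min(ea))

    def test_label_permutation_gives_chance_external_accuracy(self):
        rng = np.random.default_rng(11)
        direction = rng.normal(0, 1, 20)
        t_true = np.concatenate([rng.normal(-2, 1, 40), rng.normal(2, 1, 40)])
        X = np.outer(t_true, direction) + rng.normal(0, 0.5, (80, 20))
        y_true = np.array([0.0] * 40 + [1.0] * 40)
        correct = 0
        total = 0
        for rep in range(8):
            y = rng.permutation(y_true)
            train = np.arange(60)
            test = np.arange(60, 80)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_pls(X[train], y[train], 2)
            preds = model.decision_function(X[test]) > model.threshold
            correct += np.sum(preds == (y[test] == 1.0))
            total += test.size
        acc = correct / total
        sigma = np.sqrt(0.25 / total)
        assert abs(acc - 0.5) < 4 * sigma

    def test_fold_losing_a_class_is_an_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (12, 5))
        y = np.array([1.0] + [0.0] * 11)  # the single positive sits in one fold
        with pytest.raises(OliveGradeError, match="class"):
            choose_n_lv(X, y, max_lv=2, n_blinds=4)
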