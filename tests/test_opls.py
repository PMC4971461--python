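"""OPLS fit/predict/CV/permutation against independent oracles.

The oracle below is a deliberately plain, loop-heavy transcription of the
single-y NIPALS OPLS algorithm, kept independent of the package code path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neckstrain as ns
from neckstrain.opls import (DegenerateResponseError, correlation_scaled_loading,
                             cross_validate, fit_opls, permutation_test,
                             predict_scores)


# ---------------------------------------------------------------------------
# oracle: explicit NIPALS-style OPLS for a single response


def oracle_opls(X, y, n_orth):
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    w = Xc.T @ yc
    w = w / np.sqrt(np.sum(w * w))

    W_o, P_o, T_o = [], [], []
    for _ in range(n_orth):
        t = Xc @ w
        p = Xc.T @ t / np.sum(t * t)
        w_o = p - np.sum(w * p) * w
        norm = np.sqrt(np.sum(w_o * w_o))
        if norm < 1e-12:
            break
        w_o = w_o / norm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / np.sum(t_o * t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = Xc @ w
    p = Xc.T @ t / np.sum(t * t)
    q = np.sum(yc * t) / np.sum(t * t)
    resid = yc - t * q
    r2y = 1.0 - np.sum(resid * resid) / np.sum(yc * yc)
    return {"w": w, "t": t, "p": p, "q": q, "r2y": r2y,
            "W_o": W_o, "P_o": P_o, "T_o": T_o,
            "x_mean": x_mean, "y_mean": y_mean}


def oracle_predict(fit, X_new):
    Xc = np.atleast_2d(np.array(X_new, dtype=float)) - fit["x_mean"]
    for w_o, p_o in zip(fit["W_o"], fit["P_o"]):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    t = Xc @ fit["w"]
    return t, fit["y_mean"] + t * fit["q"]


def oracle_loo_q2(X, y, n_orth):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    ss = 0.0
    for i in range(len(y)):
        keep = [j for j in range(len(y)) if j != i]
        fit = oracle_opls(X[keep], y[keep], n_orth)
        _, yhat = oracle_predict(fit, X[i])
        press += (y[i] - yhat[0]) ** 2
        ss += (y[i] - y[keep].mean()) ** 2
    return 1.0 - press / ss


# ---------------------------------------------------------------------------


class TestFitOpls:
    def test_pure_signal_perfect_fit(self):
        """X = y v' exactly: R2Y = 1 and no orthogonal variation."""
        y = np.array([0.0, 0, 0, 1, 1, 1])
        v = np.array([1.0, -2.0, 0.5, 3.0])
        model = fit_opls(np.outer(y, v), y, n_orth=1)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)
        assert model.n_orth == 0 or np.allclose(model.T_o, 0, atol=1e-10)

    def test_matches_nipals_oracle(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X, y, n_orth=1)
        ora = oracle_opls(X, y, n_orth=1)
        np.testing.assert_allclose(model.w, ora["w"], atol=1e-10)
        np.testing.assert_allclose(model.t, ora["t"], atol=1e-10)
        np.testing.assert_allclose(model.p, ora["p"], atol=1e-10)
        assert model.q == pytest.approx(ora["q"], abs=1e-10)
        assert model.r2y == pytest.approx(ora["r2y"], abs=1e-10)
        np.testing.assert_allclose(model.T_o[:, 0], ora["T_o"][0], atol=1e-10)
        # orthogonality and exact reconstruction
        assert abs(model.t @ model.T_o[:, 0]) < 1e-10
        np.testing.assert_allclose(model.reconstruct_x(), X, atol=1e-10)

    def test_orthogonal_confound_removed(self):
        """A dominant y-orthogonal direction added to X leaves the
        predictive component unchanged once one orthogonal component is
        extracted."""
        rng = np.random.default_rng(3)
        n, p = 8, 6
        y = np.array([0.0] * 4 + [1.0] * 4)
        yc = y - y.mean()
        X = np.outer(yc, rng.normal(size=p))  # purely predictive structure
        s = rng.normal(size=n)
        s -= s.mean()
        s -= (s @ yc) / (yc @ yc) * yc  # confound scores orthogonal to y
        confound = 5.0 * np.outer(s, rng.normal(size=p))

        base = fit_opls(X, y, n_orth=1)
        shifted = fit_opls(X + confound, y, n_orth=1)
        np.testing.assert_allclose(shifted.t, base.t, atol=1e-8)
        np.testing.assert_allclose(shifted.fitted_y, base.fitted_y, atol=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateResponseError):
            fit_opls(np.eye(4), np.ones(4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_orth=st.integers(0, 3))
    def test_invariants_on_random_problems(self, seed, n_orth):
        """t _|_ T_o, exact reconstruction, R2Y in [0, 1] for any fit."""
        rng = np.random.default_rng(seed)
        n, p = 8, 12
        y = rng.integers(0, 2, n).astype(float)
        if np.ptp(y) == 0:
            y[0] = 1 - y[0]
        X = rng.normal(size=(n, p)) + np.outer(y, rng.normal(size=p))
        model = fit_opls(X, y, n_orth=n_orth)
        if model.n_orth:
            np.testing.assert_allclose(model.t @ model.T_o, 0, atol=1e-8)
        np.testing.assert_allclose(model.reconstruct_x(), X, atol=1e-8)
        assert -1e-12 <= model.r2y <= 1.0 + 1e-12


class TestPredictScores:
    def test_training_rows_reproduce_training_scores(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X, y, n_orth=1)
        t, yhat = predict_scores(model, X)
        np.testing.assert_allclose(t, model.t, atol=1e-10)
        np.testing.assert_allclose(yhat, model.fitted_y, atol=1e-10)

    def test_mean_row_maps_to_mean_response(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X, y, n_orth=1)
        t, yhat = predict_scores(model, X.mean(axis=0))
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert yhat[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_held_out_row_matches_oracle(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X[:-1], y[:-1], n_orth=1)
        ora = oracle_opls(X[:-1], y[:-1], n_orth=1)
        t, yhat = predict_scores(model, X[-1])
        t_o, yhat_o = oracle_predict(ora, X[-1])
        assert t[0] == pytest.approx(t_o[0], abs=1e-10)
        assert yhat[0] == pytest.approx(yhat_o[0], abs=1e-10)

    def test_column_mismatch_rejected(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X, y)
        with pytest.raises(ValueError):
            predict_scores(model, np.zeros((2, X.shape[1] + 1)))


class TestCrossValidate:
    def test_separable_archetypes_fully_classified(self):
        """Two well-separated class archetypes: all correct, Q2Y > 0.9."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = a + 5.0
        X = np.vstack([a + rng.normal(0, 0.05, 20) for _ in range(5)]
                      + [b + rng.normal(0, 0.05, 20) for _ in range(5)])
        y = np.array([0.0] * 5 + [1.0] * 5)
        cv = cross_validate(X, y, n_orth=1)
        assert cv.n_correct == 10
        assert cv.q2y > 0.9

    def test_q2_matches_explicit_loop_oracle(self, seeded_xy):
        X, y = seeded_xy
        cv = cross_validate(X, y, n_orth=1)
        assert cv.q2y == pytest.approx(oracle_loo_q2(X, y, 1), abs=1e-10)

    def test_permuted_labels_give_nonpositive_median_q2(self):
        """Null calibration: median Q2Y <= 0 under label permutation."""
        rng = np.random.default_rng(1)
        base_y = np.array([0.0] * 5 + [1.0] * 5)
        X = rng.normal(size=(10, 30)) + np.outer(base_y, rng.normal(size=30))
        q2s = []
        for _ in range(100):
            y_perm = rng.permutation(base_y)
            q2s.append(cross_validate(X, y_perm, n_orth=1).q2y)
        assert np.median(q2s) <= 0.0

    def test_q2_not_above_r2(self, small_cohort_matrix):
        mat = small_cohort_matrix
        model = fit_opls(mat.X, mat.y, n_orth=1)
        cv = cross_validate(mat.X, mat.y, n_orth=1)
        assert cv.q2y <= 1.0
        assert cv.q2y <= model.r2y + 1e-12

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        y = np.array([1.0, 0, 0, 0, 0])
        with pytest.raises(DegenerateResponseError):
            cross_validate(X, y)


class TestPls1Equivalence:
    def test_n_orth_zero_equals_single_component_pls1(self, seeded_xy):
        """Without orthogonal filtering the model is 1-component PLS1."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = seeded_xy
        model = fit_opls(X, y, n_orth=0)
        sk = PLSRegression(n_components=1, scale=False).fit(X, y)
        yhat_sk = sk.predict(X).ravel()
        np.testing.assert_allclose(model.fitted_y, yhat_sk, atol=1e-10)
        t_sk = sk.x_scores_.ravel()
        sgn = np.sign(t_sk @ model.t)
        np.testing.assert_allclose(model.t, sgn * t_sk, atol=1e-10)


class TestPermutation:
    def test_identity_permutation_reproduces_original(self, seeded_xy):
        X, y = seeded_xy
        perm = permutation_test(X, y, n_perm=5, seed=0)
        model = fit_opls(X, y)
        cv = cross_validate(X, y)
        assert perm.correlations[-1] == 1.0
        assert perm.r2y[-1] == pytest.approx(model.r2y, abs=1e-12)
        assert perm.q2y[-1] == pytest.approx(cv.q2y, abs=1e-12)

    def test_default_run_has_twenty_permuted_models(self, small_cohort_matrix):
        mat = small_cohort_matrix
        perm = permutation_test(mat.X, mat.y, seed=3)
        assert perm.n_perm == 20
        assert perm.correlations.size == 21
        assert perm.correlations[-1] == 1.0

    def test_large_effect_original_beats_all_permutations(self):
        spec = ns.CohortSpec(seed=6, effect_size=2.0)
        seqs, _ = ns.generate_cohort(spec)
        from neckstrain.pipeline import build_matrices
        mat = build_matrices(seqs, spec.muscles, 800)["multifidus"]
        perm = permutation_test(mat.X, mat.y, n_perm=20, seed=6)
        assert perm.q2y[-1] > perm.q2y[:-1].max()


class TestCorrelationLoading:
    def test_rank_one_matrix_gives_unit_correlations(self):
        t = np.array([-1.0, 0.5, 2.0, -1.5])
        p = np.array([1.0, -2.0, 0.3])
        X = np.outer(t, p)
        y = np.array([0.0, 0, 1, 1])
        model = fit_opls(X, y, n_orth=0)
        corr = correlation_scaled_loading(model, X)
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_orthogonal_column_gives_zero(self, seeded_xy):
        X, y = seeded_xy
        model = fit_opls(X, y, n_orth=0)
        t = model.t
        col = np.linalg.qr(np.column_stack([t, np.ones_like(t)]),
                           mode="complete")[0][:, -1]
        X2 = np.column_stack([X, col])
        model2 = fit_opls(X2[:, :-1], y, n_orth=0)
        corr = correlation_scaled_loading(model2, X2)
        # the appended column was built orthogonal to t and to the mean
        assert corr[-1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_correlation_oracle(self, small_cohort_matrix):
        mat = small_cohort_matrix
        model = fit_opls(mat.X, mat.y, n_orth=1)
        with np.errstate(invalid="ignore"):
            corr = correlation_scaled_loading(model, mat.X)
            direct = np.array([np.corrcoef(mat.X[:, j], model.t)[0, 1]
                               for j in range(mat.X.shape[1])])
        # frame 0 is exactly 0 strain for everyone: direct corr is nan
        # there, the pipeline reports 0 by convention
        defined = np.isfinite(direct)
        np.testing.assert_allclose(corr[defined], direct[defined], atol=1e-12)
        np.testing.assert_array_equal(corr[~defined], 0.0)
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)
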