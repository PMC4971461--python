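"""Orthogonal partial least squares (OPLS) discrimination of strain matrices.

OPLS regresses the cohort matrix X (participants x 800 strain values)
against the 0/1 patient-status vector y, splitting X-variation into a
single y-correlated (predictive) component t p' and one or more
y-orthogonal components T_o P_o':

    X_c = t p' + T_o P_o' + E,      y_c = t q + f

where X_c, y_c are the column-centered data.  The orthogonal filtering is
the NIPALS-style single-y algorithm: the candidate weight w is the
normalized covariance direction X_c' y_c; each orthogonal component uses
the part of the loading p that is not collinear with w, and deflates X.
The final predictive component is fitted on the fully deflated matrix.

Model strength is summarised by R2Y (explained y-variance of the fit) and
Q2Y (PRESS-based, from leave-one-out cross-validation where centering,
orthogonal filtering and the predictive fit are all redone inside each
fold).  Permutation validation refits and cross-validates the model
against randomly permuted y-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np


class DegenerateResponseError(ValueError):
    """y is constant — no discrimination problem to solve."""


class NoPredictiveSignalError(ValueError):
    """X'y vanishes — no y-correlated direction in X."""


def _normalize(v: np.ndarray, what: str) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise NoPredictiveSignalError(f"{what} has (near-)zero norm")
    return v / nrm


@dataclass
class OplsModel:
    """Fitted OPLS model with one predictive and n_orth orthogonal components."""

    t: np.ndarray            # predictive score, per participant
    p: np.ndarray            # predictive loading, per frame
    w: np.ndarray            # predictive weight, per frame
    q: float                 # regression scalar: y_hat = y_mean + t*q
    T_o: np.ndarray          # orthogonal scores, n x n_orth
    P_o: np.ndarray          # orthogonal loadings, p x n_orth
    W_o: np.ndarray          # orthogonal weights, p x n_orth
    x_mean: np.ndarray
    y_mean: float
    r2y: float
    residual: np.ndarray     # E of the X-decomposition

    @property
    def n_orth(self) -> int:
        return self.T_o.shape[1]

    @property
    def fitted_y(self) -> np.ndarray:
        return self.y_mean + self.t * self.q

    def reconstruct_x(self) -> np.ndarray:
        return (self.x_mean + np.outer(self.t, self.p)
                + self.T_o @ self.P_o.T + self.residual)


@dataclass
class CvResult:
    """Leave-one-out cross-validation summary."""

    cv_scores: np.ndarray      # predictive score of each left-out participant
    cv_y_pred: np.ndarray
    q2y: float
    predicted_labels: np.ndarray
    n_correct: int


@dataclass
class PermutationResult:
    """Permutation validation: R2Y/Q2Y of models on permuted y-vectors."""

    correlations: np.ndarray   # |corr(y_perm, y)|, original last at 1.0
    r2y: np.ndarray
    q2y: np.ndarray
    r2_trend: tuple[float, float] = (0.0, 0.0)  # slope, intercept vs correlation
    q2_trend: tuple[float, float] = (0.0, 0.0)
    n_perm: int = 0


def fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OplsModel:
    """Fit an OPLS model of X against a single response vector y.

    ``n_orth`` orthogonal components are extracted and removed before the
    predictive component is fitted; with ``n_orth=0`` the model reduces to
    single-component PLS1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with one y value per row")
    if n_orth < 0:
        raise ValueError("n_orth must be non-negative")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("constant response vector")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean

    w = _normalize(Xd.T @ yc, "X'y")

    n, p = Xd.shape
    T_o = np.empty((n, 0))
    P_o = np.empty((p, 0))
    W_o = np.empty((p, 0))
    for _ in range(n_orth):
        t = Xd @ w
        pvec = Xd.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_o = np.column_stack([T_o, t_o])
        P_o = np.column_stack([P_o, p_o])
        W_o = np.column_stack([W_o, w_o])

    t = Xd @ w
    tt = float(t @ t)
    if tt < 1e-24:
        raise NoPredictiveSignalError("predictive score has zero variance")
    pvec = Xd.T @ t / tt
    q = float(yc @ t / tt)
    E = Xd - np.outer(t, pvec)

    f = yc - t * q
    ss_y = float(yc @ yc)
    r2y = 1.0 - float(f @ f) / ss_y
    return OplsModel(t=t, p=pvec, w=w, q=q, T_o=T_o, P_o=P_o, W_o=W_o,
                     x_mean=x_mean, y_mean=y_mean, r2y=r2y, residual=E)


def predict_scores(model: OplsModel, X_new: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Predictive scores and y-predictions for new observations.

    New rows are centered with the training mean, the orthogonal variation
    is removed with the training W_o/P_o, and the predictive score is the
    projection onto w; y_hat = y_mean + t*q.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError("column count mismatch with the training matrix")
    Xd = X_new - model.x_mean
    for j in range(model.n_orth):
        t_o = Xd @ model.W_o[:, j]
        Xd = Xd - np.outer(t_o, model.P_o[:, j])
    t = Xd @ model.w
    return t, model.y_mean + t * model.q


def cross_validate(X: np.ndarray, y: np.ndarray, n_orth: int = 1,
                   threshold: float = 0.5) -> CvResult:
    """Leave-one-out cross-validation of the OPLS model.

    Each participant is predicted by a model fitted without them (centering
    included).  Q2Y = 1 - PRESS/SS, with SS the squared deviations of each
    held-out y about its training-fold mean.  Predicted label is 1 iff
    y_hat >= ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 participants for leave-one-out")

    cv_scores = np.empty(n)
    cv_pred = np.empty(n)
    press = 0.0
    ss = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if np.ptp(y_train) == 0:
            raise DegenerateResponseError(
                f"training fold without participant {i} has a single class")
        sub = fit_opls(X[mask], y_train, n_orth=n_orth)
        t_i, yhat_i = predict_scores(sub, X[i])
        cv_scores[i] = t_i[0]
        cv_pred[i] = yhat_i[0]
        press += (y[i] - yhat_i[0]) ** 2
        ss += (y[i] - y_train.mean()) ** 2

    q2y = 1.0 - press / ss
    labels = (cv_pred >= threshold).astype(int)
    n_correct = int(np.sum(labels == y.astype(int)))
    return CvResult(cv_scores=cv_scores, cv_y_pred=cv_pred, q2y=q2y,
                    predicted_labels=labels, n_correct=n_correct)


def permutation_test(X: np.ndarray, y: np.ndarray, n_perm: int = 20,
                     n_orth: int = 1, seed: int | np.random.Generator = 0
                     ) -> PermutationResult:
    """Permutation validation of an OPLS model.

    Fits and cross-validates ``n_perm`` models on randomly permuted copies
    of y; each is recorded with the absolute Pearson correlation of its
    permuted y to the original.  The original model is appended at
    correlation 1.0, and least-squares trend lines of R2Y and Q2Y against
    correlation are fitted over all points.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    corrs, r2s, q2s = [], [], []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        corrs.append(abs(float(np.corrcoef(y_perm, y)[0, 1])))
        model = fit_opls(X, y_perm, n_orth=n_orth)
        cv = cross_validate(X, y_perm, n_orth=n_orth)
        r2s.append(model.r2y)
        q2s.append(cv.q2y)

    model = fit_opls(X, y, n_orth=n_orth)
    cv = cross_validate(X, y, n_orth=n_orth)
    corrs.append(1.0)
    r2s.append(model.r2y)
    q2s.append(cv.q2y)

    corrs_a = np.asarray(corrs)
    r2_a = np.asarray(r2s)
    q2_a = np.asarray(q2s)
    r2_slope, r2_icpt = np.polyfit(corrs_a, r2_a, 1)
    q2_slope, q2_icpt = np.polyfit(corrs_a, q2_a, 1)
    return PermutationResult(correlations=corrs_a, r2y=r2_a, q2y=q2_a,
                             r2_trend=(float(r2_slope), float(r2_icpt)),
                             q2_trend=(float(q2_slope), float(q2_icpt)),
                             n_perm=n_perm)


def correlation_scaled_loading(model: OplsModel, X: np.ndarray) -> np.ndarray:
    """Predictive loading rescaled as per-frame correlation coefficients.

    Element j is the Pearson correlation between column j of X and the
    predictive score t, so the strain-loading line plot reads directly as
    the frame-wise correlation (in [-1, 1]) between strain and group
    membership signal.  Zero-variance columns yield 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    t = model.t - model.t.mean()
    t_norm = np.linalg.norm(t)
    col_norms = np.linalg.norm(Xc, axis=0)
    out = np.zeros(X.shape[1])
    ok = col_norms > 1e-12
    if not ok.all():
        warnings.warn("zero-variance columns set to correlation 0",
                      RuntimeWarning, stacklevel=2)
    out[ok] = (Xc[:, ok].T @ t) / (col_norms[ok] * t_norm)
    return out
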