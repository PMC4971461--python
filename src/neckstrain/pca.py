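"""Principal component analysis of strain matrices.

Unsupervised exploration of the per-muscle cohort matrices: SVD-based PCA
of the column-centered matrix, X = mean + T P' + E, with explained-variance
percentages and Hotelling's T-squared 95% confidence ellipses for
two-component score plots.  The SVD route is exact and deterministic; the
component sign is fixed so the largest-magnitude loading element of each
component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .prep import center_matrix


@dataclass
class PcaModel:
    """Scores T (n x k), loadings P (p x k), residual E, variance shares."""

    scores: np.ndarray
    loadings: np.ndarray
    residual: np.ndarray
    explained_var_pct: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.mean + self.scores @ self.loadings.T + self.residual


@dataclass
class EllipseSpec:
    """Hotelling's T-squared confidence ellipse in a 2-D score plane."""

    centre: np.ndarray
    semi_axes: np.ndarray        # lengths, descending
    axes_directions: np.ndarray  # 2 x 2, columns are the axis directions
    level: float
    t2_crit: float

    @property
    def orientation_rad(self) -> float:
        """Angle of the major axis against the first score axis."""
        v = self.axes_directions[:, 0]
        return float(np.arctan2(v[1], v[0]))

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """Points on the ellipse boundary, (n_points x 2)."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circ = np.stack([np.cos(theta), np.sin(theta)])
        return (self.centre[:, None]
                + self.axes_directions @ (self.semi_axes[:, None] * circ)).T


def fit_pca(X: np.ndarray, k: int | None = None) -> PcaModel:
    """Fit a k-component PCA to the rows of X (observations x variables).

    Components are ordered by decreasing variance.  ``k`` defaults to the
    full rank, min(n - 1, p).
    """
    Xc, mean = center_matrix(np.asarray(X, dtype=float))
    n, p = Xc.shape
    max_k = min(n - 1, p) if n > 1 else 1
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}], got {k}")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :max_k], s[:max_k], Vt[:max_k]

    # deterministic sign: largest-|.| loading element positive per component
    for j in range(max_k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    T = U[:, :k] * s[:k]
    P = Vt[:k].T
    E = Xc - T @ P.T

    total_var = float(np.sum(s ** 2))
    if total_var == 0.0:
        expl = np.zeros(k)
    else:
        expl = 100.0 * s[:k] ** 2 / total_var
    return PcaModel(scores=T, loadings=P, residual=E,
                    explained_var_pct=expl, mean=mean)


def explained_variance(model: PcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative explained variance, in percent."""
    per = model.explained_var_pct
    return per, np.cumsum(per)


def hotelling_t2(scores2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point T-squared values of a 2-column score set.

    Returns (t2 values, centre, covariance).  Raises on a degenerate
    (singular) score covariance.
    """
    Z = np.asarray(scores2, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError("need an n x 2 score array")
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a T2 ellipse")
    centre = Z.mean(axis=0)
    Zc = Z - centre
    S = Zc.T @ Zc / (n - 1)
    if np.linalg.matrix_rank(S) < 2 or np.linalg.det(S) <= 0:
        raise ValueError("degenerate score covariance")
    Sinv = np.linalg.inv(S)
    t2 = np.einsum("ij,jk,ik->i", Zc, Sinv, Zc)
    return t2, centre, S


def hotelling_ellipse(scores2: np.ndarray, level: float = 0.95
                      ) -> tuple[EllipseSpec, np.ndarray]:
    """Hotelling's T-squared confidence ellipse of a 2-D score plot.

    The critical value is T2_crit = 2(n-1)/(n-2) * F_level(2, n-2); the
    ellipse is the {T2 = T2_crit} contour of the sample covariance, and a
    point is inside iff its T2 <= T2_crit.  Returns the ellipse and the
    per-point inside flags.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    t2, centre, S = hotelling_t2(scores2)
    n = np.asarray(scores2).shape[0]
    f_crit = stats.f.ppf(level, 2, n - 2)
    t2_crit = 2.0 * (n - 1) / (n - 2) * f_crit

    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi_axes = np.sqrt(eigval * t2_crit)
    inside = t2 <= t2_crit
    return EllipseSpec(centre=centre, semi_axes=semi_axes,
                       axes_directions=eigvec, level=level,
                       t2_crit=float(t2_crit)), inside
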