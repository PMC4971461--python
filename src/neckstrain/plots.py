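"""Figure set mirroring the standard strain-sequence report.

Per muscle: strain line plot (groups coloured), PCA score scatter with the
Hotelling T2 ellipse, PCA loading line, OPLS cross-validated score plot,
permutation-validation plot and the correlation-scaled loading line.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

GROUP_COLORS = {0: "0.7", 1: "black"}
GROUP_NAMES = {0: "control", 1: "WAD"}


def _by_group(ax, x, y, groups):
    for g in (0, 1):
        m = groups == g
        if m.any():
            ax.scatter(x[m], y[m], c=GROUP_COLORS[g], edgecolors="k",
                       s=45, label=GROUP_NAMES[g], zorder=3)
    ax.legend(frameon=False, fontsize=8)


def strain_lines(mat, ax=None):
    ax = ax or plt.gca()
    for i in range(mat.n_participants):
        g = int(mat.y[i])
        ax.plot(mat.X[i], color=GROUP_COLORS[g], lw=0.8,
                label=GROUP_NAMES[g] if i in (0, mat.n_participants - 1) else None)
    ax.set_xlabel("frame")
    ax.set_ylabel("strain (%)")
    ax.set_title(f"{mat.muscle}: strain sequences")
    return ax


def pca_score_plot(model, ellipse, groups, ax=None):
    ax = ax or plt.gca()
    _by_group(ax, model.scores[:, 0], model.scores[:, 1], groups)
    b = ellipse.boundary()
    ax.plot(b[:, 0], b[:, 1], "k--", lw=0.8)
    ax.axhline(0, color="0.85", lw=0.5)
    ax.axvline(0, color="0.85", lw=0.5)
    ax.set_xlabel("t1")
    ax.set_ylabel("t2")
    ax.set_title("PCA scores, Hotelling T2 95% ellipse")
    return ax


def loading_line(values, ylabel, ax=None):
    ax = ax or plt.gca()
    ax.plot(np.arange(values.size), values, "k-", lw=0.9)
    ax.axhline(0, color="0.85", lw=0.5)
    ax.set_xlabel("frame")
    ax.set_ylabel(ylabel)
    return ax


def cv_score_plot(cv, T_o_first, groups, ax=None):
    ax = ax or plt.gca()
    y2 = T_o_first if T_o_first is not None else np.zeros_like(cv.cv_scores)
    _by_group(ax, cv.cv_scores, y2, groups)
    ax.axvline(0, color="0.85", lw=0.5)
    ax.set_xlabel("cross-validated predictive score")
    ax.set_ylabel("orthogonal score")
    ax.set_title(f"OPLS CV scores ({cv.n_correct}/{cv.cv_scores.size} correct)")
    return ax


def permutation_plot(perm, ax=None):
    ax = ax or plt.gca()
    ax.scatter(perm.correlations[:-1], perm.r2y[:-1], marker="s",
               facecolors="none", edgecolors="k", label="R2Y (permuted)")
    ax.scatter(perm.correlations[:-1], perm.q2y[:-1], marker="o",
               facecolors="0.6", edgecolors="k", label="Q2Y (permuted)")
    ax.scatter([1.0], [perm.r2y[-1]], marker="s", c="k")
    ax.scatter([1.0], [perm.q2y[-1]], marker="o", c="k")
    xs = np.linspace(0, 1, 50)
    ax.plot(xs, perm.r2_trend[0] * xs + perm.r2_trend[1], "k--", lw=0.8)
    ax.plot(xs, perm.q2_trend[0] * xs + perm.q2_trend[1], "k:", lw=0.8)
    ax.set_xlabel("|corr(y_perm, y)|")
    ax.set_ylabel("R2Y / Q2Y")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title("permutation validation")
    return ax


def muscle_report_figures(mat, objs, out_dir: str | Path, muscle: str) -> list[Path]:
    """Write the whole per-muscle figure set as PNGs; returns the paths."""
    out = Path(out_dir)
    paths = []

    def save(name, draw):
        fig, ax = plt.subplots(figsize=(5, 3.6), dpi=110)
        draw(ax)
        fig.tight_layout()
        p = out / f"{name}_{muscle}.png"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)

    groups = mat.y.astype(int)
    save("strain", lambda ax: strain_lines(mat, ax))
    save("pca_scores", lambda ax: pca_score_plot(objs["pca"], objs["ellipse"],
                                                 groups, ax))
    save("pca_loading", lambda ax: loading_line(objs["pca"].loadings[:, 0],
                                                "PCA loading p1", ax))
    model = objs["opls"]
    t_o = model.T_o[:, 0] if model.n_orth else None
    save("opls_cv_scores", lambda ax: cv_score_plot(objs["cv"], t_o, groups, ax))
    if objs.get("perm") is not None:
        save("permutation", lambda ax: permutation_plot(objs["perm"], ax))
    save("corr_loading", lambda ax: loading_line(objs["corr_loading"],
                                                 "correlation-scaled loading", ax))
    return paths
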