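"""End-to-end orchestration: cohort -> matrices -> PCA/OPLS -> report bundle.

``run_pipeline`` drives the full analysis from a :class:`PipelineConfig`:
obtain per-participant per-muscle strain sequences (synthetic cohort,
strain CSV, or tracked phantom movies), resample them to a common length,
and for every muscle fit the PCA overview, the OPLS discrimination with
leave-one-out cross-validation and permutation validation, and the
Mann-Whitney test on the cross-validated scores.  Outputs are CSV tables,
a deterministic JSON summary and (optionally) the figure set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_stats, io, opls, pca, prep, synthetic, tracking


@dataclass
class PipelineConfig:
    """Configuration of one analysis run (YAML-serialisable)."""

    input_mode: str = "synthetic"        # synthetic | strain-csv | movies
    strain_csv: str | None = None
    movies: list[dict] = field(default_factory=list)
    muscles: tuple[str, ...] = synthetic.DEFAULT_MUSCLES
    n_wad: int = 9
    n_control: int = 9
    effect_size: float = 0.5
    noise_sd: float = 1.0
    resample_len: int = 800
    n_orth: int = 1
    n_perm: int = 20
    alpha: float = 0.05
    seed: int = 0
    make_figures: bool = True
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.resample_len < 2:
            raise ValueError("resample length must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "muscles" in data:
            data["muscles"] = tuple(data["muscles"])
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; names the muscle and stage."""


def _load_sequences(config: PipelineConfig
                    ) -> dict[tuple[str, str], synthetic.StrainSequence]:
    if config.input_mode == "synthetic":
        spec = synthetic.CohortSpec(
            n_wad=config.n_wad, n_control=config.n_control,
            muscles=tuple(config.muscles), effect_size=config.effect_size,
            noise_sd=config.noise_sd, seed=config.seed)
        sequences, _ = synthetic.generate_cohort(spec)
        return sequences
    if config.input_mode == "strain-csv":
        if not config.strain_csv:
            raise ValueError("strain-csv mode needs a strain_csv path")
        return io.read_strain_csv(config.strain_csv)
    if config.input_mode == "movies":
        sequences = {}
        for entry in config.movies:
            movie = io.read_movie(entry["dir"])
            roi = tracking.place_roi(
                movie.frames[0], centre=tuple(entry["centre"]),
                length_mm=entry.get("length_mm", tracking.DEFAULT_ROI_LENGTH_MM),
                width_mm=entry.get("width_mm", tracking.DEFAULT_ROI_WIDTH_MM),
                spacing=movie.pixel_spacing_mm)
            track = tracking.track_points(movie, roi)
            seq = tracking.compute_strain_sequence(
                track, participant_id=entry["participant_id"],
                group=int(entry["group"]), muscle=entry["muscle"],
                frame_rate=movie.frame_rate)
            sequences[(seq.participant_id, seq.muscle)] = seq
        return sequences
    raise ValueError(f"unknown input mode {config.input_mode!r}")


def build_matrices(sequences: dict[tuple[str, str], synthetic.StrainSequence],
                   muscles: tuple[str, ...], resample_len: int
                   ) -> dict[str, prep.StrainMatrix]:
    """Resample every sequence and assemble one StrainMatrix per muscle."""
    matrices = {}
    for muscle in muscles:
        per_muscle = [prep.resample_sequence(seq, resample_len)
                      for (pid, m), seq in sorted(sequences.items())
                      if m == muscle]
        if not per_muscle:
            raise StageError(f"no sequences for muscle {muscle!r}")
        matrices[muscle] = prep.assemble_matrix(per_muscle)
    return matrices


def analyse_muscle(mat: prep.StrainMatrix, n_orth: int = 1, n_perm: int = 20,
                   alpha: float = 0.05, seed: int = 0) -> dict:
    """Full multivariate analysis of one muscle's StrainMatrix."""
    out: dict = {"muscle": mat.muscle, "n_participants": mat.n_participants}

    model_pca = pca.fit_pca(mat.X, k=min(4, mat.n_participants - 1))
    per, cum = pca.explained_variance(model_pca)
    ellipse, inside = pca.hotelling_ellipse(model_pca.scores[:, :2])
    out["pca"] = {
        "explained_var_pct": [round(float(v), 4) for v in per],
        "pc12_explained_pct": round(float(cum[1]), 4),
        "all_inside_t2_ellipse": bool(inside.all()),
    }

    model = opls.fit_opls(mat.X, mat.y, n_orth=n_orth)
    cv = opls.cross_validate(mat.X, mat.y, n_orth=n_orth)
    test = group_stats.mann_whitney(cv.cv_scores, mat.y, alpha=alpha)
    out["opls"] = {
        "r2y": round(model.r2y, 6),
        "q2y": round(cv.q2y, 6),
        "n_correct": cv.n_correct,
        "n_total": mat.n_participants,
    }
    out["mann_whitney"] = {
        "U": test.u_statistic,
        "p_value": round(test.p_value, 8),
        "method": test.method,
        "significant": bool(test.p_value <= alpha),
    }
    if n_perm > 0:
        perm = opls.permutation_test(mat.X, mat.y, n_perm=n_perm,
                                     n_orth=n_orth, seed=seed)
        out["permutation"] = {
            "n_perm": perm.n_perm,
            "max_permuted_q2y": round(float(perm.q2y[:-1].max()), 6),
            "original_q2y": round(float(perm.q2y[-1]), 6),
            "q2_trend_slope": round(perm.q2_trend[0], 6),
            "r2_trend_slope": round(perm.r2_trend[0], 6),
        }
    with warnings.catch_warnings():
        # frame 0 is 0% strain for everyone by definition; its loading is 0
        warnings.simplefilter("ignore", RuntimeWarning)
        corr_loading = opls.correlation_scaled_loading(model, mat.X)
    out["_objects"] = {"pca": model_pca, "ellipse": ellipse, "opls": model,
                       "cv": cv,
                       "perm": perm if n_perm > 0 else None,
                       "corr_loading": corr_loading}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to
    ``out_dir/summary.json`` with the intermediate CSVs and figures)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sequences = _load_sequences(config)
    io.write_strain_csv(sequences, out_dir / "strain_sequences.csv")
    matrices = build_matrices(sequences, tuple(config.muscles),
                              config.resample_len)

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "muscles": {},
    }
    mwu_results = {}
    for muscle, mat in matrices.items():
        try:
            res = analyse_muscle(mat, n_orth=config.n_orth,
                                 n_perm=config.n_perm, alpha=config.alpha,
                                 seed=config.seed)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(f"analysis failed for muscle {muscle!r}") from exc
        objs = res.pop("_objects")
        summary["muscles"][muscle] = res
        mwu_results[muscle] = group_stats.TestResult(
            u_statistic=res["mann_whitney"]["U"],
            p_value=res["mann_whitney"]["p_value"],
            method=res["mann_whitney"]["method"],
            significant=res["mann_whitney"]["significant"],
            alpha=config.alpha)

        scores_df = pd.DataFrame({
            "participant_id": mat.participant_ids,
            "group": mat.y.astype(int),
            "pca_t1": objs["pca"].scores[:, 0],
            "pca_t2": objs["pca"].scores[:, 1],
            "opls_t": objs["opls"].t,
            "cv_score": objs["cv"].cv_scores,
            "cv_y_pred": objs["cv"].cv_y_pred,
        })
        scores_df.to_csv(out_dir / f"scores_{muscle}.csv", index=False)
        loadings_df = pd.DataFrame({
            "frame": np.arange(mat.n_frames),
            "pca_p1": objs["pca"].loadings[:, 0],
            "opls_p": objs["opls"].p,
            "corr_loading": objs["corr_loading"],
        })
        loadings_df.to_csv(out_dir / f"loadings_{muscle}.csv", index=False)

        if config.make_figures:
            from . import plots
            plots.muscle_report_figures(mat, objs, out_dir, muscle)

    table = group_stats.summarize_muscles(mwu_results, alpha=config.alpha)
    table.to_csv(out_dir / "muscle_tests.csv", index=False)
    summary["significant_muscles"] = sorted(
        table.loc[table["significant"], "muscle"])

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
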