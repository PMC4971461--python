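"""Reading and writing of strain tables and phantom movie stacks.

Strain sequences travel as long-format CSV with columns
``participant_id, group, muscle, frame, strain_pct``; phantom movies as a
directory of 8-bit grayscale PNG frames plus a ``movie.json`` sidecar
holding pixel spacing, frame rate and the ground-truth deformation
parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import (DeformationProfile, RampProfile, SpeckleMovie,
                        SpeckleMovieSpec, StrainSequence)

STRAIN_COLUMNS = ["participant_id", "group", "muscle", "frame", "strain_pct"]


def write_strain_csv(sequences: dict[tuple[str, str], StrainSequence],
                     path: str | Path) -> None:
    frames = []
    for (pid, muscle), seq in sorted(sequences.items()):
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "group": seq.group,
            "muscle": muscle,
            "frame": np.arange(seq.n_frames),
            "strain_pct": seq.strain,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_strain_csv(path: str | Path,
                    frame_rate: float = 235.0
                    ) -> dict[tuple[str, str], StrainSequence]:
    df = pd.read_csv(path)
    missing = set(STRAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"strain CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], StrainSequence] = {}
    for (pid, muscle), grp in df.groupby(["participant_id", "muscle"], sort=True):
        grp = grp.sort_values("frame")
        out[(str(pid), str(muscle))] = StrainSequence(
            participant_id=str(pid),
            group=int(grp["group"].iloc[0]),
            muscle=str(muscle),
            strain=grp["strain_pct"].to_numpy(dtype=float),
            frame_rate=frame_rate,
        )
    return out


def write_movie(movie: SpeckleMovie, out_dir: str | Path) -> Path:
    """Write a movie as frame_0000.png ... + movie.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in range(movie.n_frames):
        iio.imwrite(out / f"frame_{f:04d}.png", movie.frames[f])
    spec = movie.spec
    deform = spec.deformation
    sidecar = {
        "pixel_spacing_mm": movie.pixel_spacing_mm,
        "frame_rate": movie.frame_rate,
        "n_frames": movie.n_frames,
        "deformation": {
            "kind": type(deform).__name__,
            **{k: getattr(deform, k) for k in
               ("peak_strain_pct", "phase_split") if hasattr(deform, k)},
            **{k: getattr(deform, k) for k in
               ("final_strain_pct", "ramp_end") if hasattr(deform, k)},
        },
        "translation_px_per_frame": list(spec.translation_px_per_frame),
        "seed": spec.seed,
    }
    (out / "movie.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_movie(movie_dir: str | Path) -> SpeckleMovie:
    """Read a PNG-stack movie written by :func:`write_movie`."""
    d = Path(movie_dir)
    sidecar = json.loads((d / "movie.json").read_text())
    paths = sorted(d.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {d}")
    frames = np.stack([iio.imread(p) for p in paths])
    meta = sidecar["deformation"]
    if meta.get("kind") == "RampProfile":
        deform = RampProfile(final_strain_pct=meta["final_strain_pct"],
                             ramp_end=meta.get("ramp_end", 1.0))
    else:
        deform = DeformationProfile(peak_strain_pct=meta["peak_strain_pct"],
                                    phase_split=meta.get("phase_split", 0.5))
    spec = SpeckleMovieSpec(
        height=frames.shape[1], width=frames.shape[2],
        pixel_spacing_mm=sidecar["pixel_spacing_mm"],
        frame_rate=sidecar["frame_rate"], n_frames=frames.shape[0],
        deformation=deform,
        translation_px_per_frame=tuple(sidecar.get(
            "translation_px_per_frame", (0.0, 0.0))),
        seed=sidecar.get("seed", 0),
    )
    return SpeckleMovie(frames=frames, pixel_spacing_mm=spec.pixel_spacing_mm,
                        frame_rate=spec.frame_rate, spec=spec)
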