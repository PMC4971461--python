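"""Resampling of strain sequences and assembly of per-muscle matrices.

Each participant's recording has its own length (about 946 +/- 336 frames);
before multivariate analysis all sequences are resampled onto a common
800-point time base (linear interpolation on normalized time), and for each
muscle the cohort is stacked into an observations x 800 matrix X with a 0/1
group vector y.  Columns are mean-centered only — every column is strain in
percent, so unit-variance scaling is not applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .synthetic import StrainSequence

DEFAULT_RESAMPLE_LEN = 800


class DataError(ValueError):
    """Invalid sequence data (non-finite values, bad lengths)."""


class AssemblyError(ValueError):
    """Inconsistent inputs when stacking sequences into a matrix."""


@dataclass
class StrainMatrix:
    """Per-muscle cohort matrix: participants x resampled frames."""

    X: np.ndarray
    y: np.ndarray
    muscle: str
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise AssemblyError("X must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise AssemblyError("row count must equal label count")
        if not np.isfinite(self.X).all():
            raise DataError("X contains non-finite values")

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    @property
    def n_frames(self) -> int:
        return self.X.shape[1]


def resample_sequence(seq: StrainSequence, target_len: int = DEFAULT_RESAMPLE_LEN,
                      method: str = "linear") -> StrainSequence:
    """Resample a strain sequence to ``target_len`` frames.

    Interpolation is on normalized time [0, 1]; the first and last samples
    are preserved exactly, and an input already at the target length is
    returned unchanged (as a copy).  ``method`` is "linear" (default) or
    "cubic" (natural cubic spline).
    """
    if seq.n_frames < 2 or target_len < 2:
        raise DataError("need at least 2 frames on both sides of a resample")
    if not np.isfinite(seq.strain).all():
        raise DataError("sequence contains non-finite values")

    t_in = np.linspace(0.0, 1.0, seq.n_frames)
    t_out = np.linspace(0.0, 1.0, target_len)
    if seq.n_frames == target_len:
        out = seq.strain.copy()
    elif method == "linear":
        out = np.interp(t_out, t_in, seq.strain)
    elif method == "cubic":
        out = CubicSpline(t_in, seq.strain, bc_type="natural")(t_out)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    out[0] = seq.strain[0]
    out[-1] = seq.strain[-1]
    new_rate = seq.frame_rate * (target_len - 1) / (seq.n_frames - 1)
    return StrainSequence(participant_id=seq.participant_id, group=seq.group,
                          muscle=seq.muscle, strain=out, frame_rate=new_rate)


def assemble_matrix(sequences: dict[str, StrainSequence] | list[StrainSequence],
                    labels: dict[str, int] | None = None) -> StrainMatrix:
    """Stack one muscle's resampled sequences into a StrainMatrix.

    ``sequences`` maps participant id -> StrainSequence (or is a list of
    sequences carrying their ids); rows are ordered by participant id.
    Labels default to each sequence's own group attribute.
    """
    if isinstance(sequences, dict):
        seq_list = list(sequences.values())
    else:
        seq_list = list(sequences)
    if not seq_list:
        raise AssemblyError("no sequences to assemble")

    ids = [s.participant_id for s in seq_list]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate participant ids")
    muscles = {s.muscle for s in seq_list}
    if len(muscles) != 1:
        raise AssemblyError(f"mixed muscles in one matrix: {sorted(muscles)}")
    lengths = {s.n_frames for s in seq_list}
    if len(lengths) != 1:
        raise AssemblyError(f"mixed sequence lengths: {sorted(lengths)}")

    seq_list.sort(key=lambda s: s.participant_id)
    X = np.vstack([s.strain for s in seq_list])
    if labels is None:
        y = np.array([s.group for s in seq_list], dtype=float)
    else:
        y = np.array([labels[s.participant_id] for s in seq_list], dtype=float)
    return StrainMatrix(X=X, y=y, muscle=muscles.pop(),
                        participant_ids=[s.participant_id for s in seq_list])


def center_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; returns (centered X, column mean vector)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DataError("need a non-empty 2-D matrix")
    mean = X.mean(axis=0)
    return X - mean, mean
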