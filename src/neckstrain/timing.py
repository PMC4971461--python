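"""Timing arithmetic of the recording protocol.

The exercise is paced by a metronome: extend the neck on beat 1, reach 20
degrees on beat 2, be back at neutral on beat 3.  At 30 beats/min the
three-beat window spans 4 s.  Recordings run at 235 frames/s, and the
common 800-frame resampled sequence corresponds to 800/235 ~ 3.4 s.
"""

from __future__ import annotations

DEFAULT_FRAME_RATE = 235.0
DEFAULT_METRONOME_BPM = 30.0


def sequence_duration_s(n_frames: int, frame_rate: float = DEFAULT_FRAME_RATE) -> float:
    """Duration in seconds of an ``n_frames`` recording at ``frame_rate``."""
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    return n_frames / frame_rate


def exercise_window_s(n_beats: int = 3, bpm: float = DEFAULT_METRONOME_BPM) -> float:
    """Span in seconds from the first to the last of ``n_beats`` metronome
    beats at ``bpm`` beats per minute."""
    if n_beats < 1 or bpm <= 0:
        raise ValueError("need n_beats >= 1 and positive bpm")
    return (n_beats - 1) * 60.0 / bpm
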