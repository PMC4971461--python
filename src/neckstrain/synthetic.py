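"""Synthetic strain cohorts and speckle phantoms.

The study this package reimplements recorded B-mode ultrasound of the dorsal
neck muscles during a metronome-paced neck extension (neutral -> 20 degrees
-> neutral) and reduced each recording to a per-muscle *strain sequence*:
percent longitudinal deformation per frame, zero at the start of the
exercise.  The recordings themselves are not public, so this module generates

* strain sequences with the cohort's statistical structure (9 patients +
  9 controls, 5 muscles, variable sequence lengths around 946 +/- 336
  frames, group differences confined to chosen muscles and exercise
  phases), and
* speckle-textured movie phantoms under a known longitudinal deformation,
  with an analytic ground-truth displacement field,

so that every downstream stage (tracking, resampling, PCA, OPLS,
nonparametric testing) is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

DEFAULT_MUSCLES = (
    "trapezius",
    "splenius_capitis",
    "semispinalis_capitis",
    "semispinalis_cervicis",
    "multifidus",
)

# Peak longitudinal shortening (strain %) per muscle for the control group.
# Chosen to span the range seen in published dorsal-muscle strain curves.
DEFAULT_PEAK_STRAIN = {
    "trapezius": -8.0,
    "splenius_capitis": -6.0,
    "semispinalis_capitis": -10.0,
    "semispinalis_cervicis": -7.0,
    "multifidus": -9.0,
}

# (extension-phase, return-phase) effect weights per muscle; multiplied by
# CohortSpec.effect_size.  The affected muscles/phases mirror the reported
# group differences: trapezius in the extension phase, multifidus in both.
DEFAULT_EFFECT_WEIGHTS = {
    "trapezius": (1.0, 0.0),
    "multifidus": (1.0, 1.0),
}


class ConfigurationError(ValueError):
    """Invalid generator configuration (unknown muscle, empty cohort...)."""


@dataclass(frozen=True)
class DeformationProfile:
    """Noiseless longitudinal strain profile of one exercise repetition.

    Raised-cosine ramp from 0 to ``peak_strain_pct`` over the extension
    phase (fraction ``phase_split`` of the exercise) and back to 0 over the
    return phase.  Continuous, zero at time 0, extremal exactly at the
    phase boundary.
    """

    peak_strain_pct: float = -10.0
    phase_split: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.phase_split < 1.0:
            raise ConfigurationError("phase_split must lie in (0, 1)")

    def shape(self, tau: np.ndarray) -> np.ndarray:
        """Unit-amplitude profile value at normalized time tau in [0, 1]."""
        tau = np.asarray(tau, dtype=float)
        s = self.phase_split
        up = 0.5 * (1.0 - np.cos(np.pi * np.clip(tau, 0.0, s) / s))
        down = 0.5 * (1.0 - np.cos(np.pi * np.clip(1.0 - tau, 0.0, 1.0 - s) / (1.0 - s)))
        return np.where(tau <= s, up, down)

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        """Strain % at normalized time tau in [0, 1]."""
        return self.peak_strain_pct * self.shape(tau)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the study conditions: nine patients with whiplash
    associated disorders (WAD) and nine matched controls, five dorsal neck
    muscles, original sequence lengths drawn from a truncated normal with
    mean 946 and sd 336 frames (floor 100), and an amplitude-only group
    effect confined to the muscles/phases in ``effect_weights``.
    """

    n_wad: int = 9
    n_control: int = 9
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    effect_size: float = 0.5
    effect_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    peak_strain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_STRAIN)
    )
    length_mean: float = 946.0
    length_sd: float = 336.0
    min_length: int = 100
    noise_sd: float = 1.0
    noise_smooth_frames: float = 40.0
    participant_amp_sd: float = 0.25
    phase_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wad < 0 or self.n_control < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.length_mean <= 0:
            raise ConfigurationError("length_mean must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if len(set(self.muscles)) != len(self.muscles):
            raise ConfigurationError("muscle names must be unique")

    def profile_for(self, muscle: str) -> DeformationProfile:
        if muscle not in self.muscles:
            raise ConfigurationError(f"unknown muscle {muscle!r}")
        peak = self.peak_strain.get(muscle, -10.0)
        return DeformationProfile(peak_strain_pct=peak, phase_split=self.phase_split)


@dataclass
class StrainSequence:
    """Frame-indexed strain (%) of one participant x one muscle."""

    participant_id: str
    group: int  # patient = 1, control = 0
    muscle: str
    strain: np.ndarray
    frame_rate: float = 235.0

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        if self.strain.ndim != 1:
            raise ValueError("strain must be a 1-D array")

    @property
    def n_frames(self) -> int:
        return self.strain.size


def _draw_length(spec: CohortSpec, rng: np.random.Generator) -> int:
    a = (spec.min_length - spec.length_mean) / spec.length_sd if spec.length_sd > 0 else -np.inf
    if spec.length_sd == 0:
        return max(int(round(spec.length_mean)), spec.min_length)
    n = stats.truncnorm.rvs(a, np.inf, loc=spec.length_mean, scale=spec.length_sd,
                            random_state=rng)
    return max(int(round(float(n))), spec.min_length)


def _phase_gate(tau: np.ndarray, split: float, g_ext: float, g_ret: float,
                width: float = 0.1) -> np.ndarray:
    """Smoothly interpolate the per-phase amplitude multiplier.

    A hard per-phase multiplier would put a step at the phase boundary where
    the profile is extremal; a raised-cosine cross-fade of half-width
    ``width/2`` (normalized time) keeps the strain curve continuous.
    """
    x = np.clip((tau - split) / width + 0.5, 0.0, 1.0)
    blend = 0.5 * (1.0 - np.cos(np.pi * x))
    return g_ext + (g_ret - g_ext) * blend


def generate_strain_sequence(group: int, muscle: str, spec: CohortSpec,
                             profile: DeformationProfile | None = None,
                             seed: int | np.random.SeedSequence = 0,
                             participant_id: str = "p00") -> StrainSequence:
    """Generate one participant x muscle strain sequence.

    The noiseless curve is the muscle's deformation profile scaled by a
    per-participant log-normal amplitude multiplier; for patients (group=1)
    the amplitude is additionally multiplied by ``1 + effect_size * weight``
    in the configured phases.  Smooth correlated noise (Gaussian-smoothed
    white noise, sd ``noise_sd``) is added and re-anchored so strain[0] = 0
    exactly.  Deterministic for a fixed seed; the group label changes only
    the effect multiplier, never the random draws.
    """
    if muscle not in spec.muscles:
        raise ConfigurationError(f"unknown muscle {muscle!r}")
    if profile is None:
        profile = spec.profile_for(muscle)
    rng = np.random.default_rng(seed)

    n = _draw_length(spec, rng)
    tau = np.linspace(0.0, 1.0, n)

    amp = float(np.exp(rng.normal(0.0, spec.participant_amp_sd))) \
        if spec.participant_amp_sd > 0 else 1.0

    w_ext, w_ret = spec.effect_weights.get(muscle, (0.0, 0.0))
    if group == 1 and spec.effect_size != 0.0:
        gate = _phase_gate(tau, profile.phase_split,
                           1.0 + spec.effect_size * w_ext,
                           1.0 + spec.effect_size * w_ret)
    else:
        gate = 1.0

    strain = amp * gate * profile(tau)

    if spec.noise_sd > 0:
        white = rng.normal(0.0, 1.0, n)
        smooth = ndimage.gaussian_filter1d(white, spec.noise_smooth_frames,
                                           mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth *= spec.noise_sd / sd
        smooth -= smooth[0]  # keep strain[0] exactly 0
        strain = strain + smooth

    strain[0] = 0.0
    return StrainSequence(participant_id=participant_id, group=group,
                          muscle=muscle, strain=strain)


def generate_cohort(spec: CohortSpec) -> tuple[dict[tuple[str, str], StrainSequence], np.ndarray]:
    """Generate all participant x muscle sequences of a cohort.

    Returns ``(sequences, y)`` where ``sequences`` is keyed by
    ``(participant_id, muscle)`` and ``y`` holds one 0/1 label per
    participant (patient = 1, control = 0), ordered by participant id.
    Every (participant, muscle) pair gets an independent child seed spawned
    from ``spec.seed``, so the whole cohort is reproducible bit for bit.
    """
    n_total = spec.n_wad + spec.n_control
    if n_total == 0:
        raise ConfigurationError("empty cohort: n_wad + n_control must be > 0")
    root = np.random.SeedSequence(spec.seed)
    children = iter(root.spawn(n_total * len(spec.muscles)))

    sequences: dict[tuple[str, str], StrainSequence] = {}
    labels = []
    for i in range(n_total):
        group = 1 if i < spec.n_wad else 0
        pid = f"{'wad' if group else 'ctl'}{i:02d}"
        labels.append(group)
        for muscle in spec.muscles:
            seq = generate_strain_sequence(group, muscle, spec,
                                           seed=next(children),
                                           participant_id=pid)
            sequences[(pid, muscle)] = seq
    return sequences, np.asarray(labels, dtype=int)


@dataclass(frozen=True)
class RampProfile:
    """Monotone strain ramp 0 -> ``final_strain_pct``, then hold.

    Convenience profile for phantom movies: a raised-cosine ramp over the
    first ``ramp_end`` fraction of the movie reaching the target strain,
    which is then held to the final frame (unlike the exercise profile,
    which returns to zero).
    """

    final_strain_pct: float = 10.0
    ramp_end: float = 1.0

    @property
    def peak_strain_pct(self) -> float:
        return self.final_strain_pct

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        x = np.clip(tau / self.ramp_end, 0.0, 1.0)
        return self.final_strain_pct * 0.5 * (1.0 - np.cos(np.pi * x))


# ---------------------------------------------------------------------------
# Speckle phantoms


class GenerationError(RuntimeError):
    """Phantom generation failed (e.g. deformation exceeds the image)."""


@dataclass(frozen=True)
class SpeckleMovieSpec:
    """Parameters of a speckle phantom movie.

    The phantom is a fixed speckle texture stretched/compressed
    longitudinally (image column axis) about the frame centre according to
    a :class:`DeformationProfile`; optional per-frame translation and
    additive sensor noise.
    """

    height: int = 200
    width: int = 260
    pixel_spacing_mm: float = 0.1
    frame_rate: float = 235.0
    n_frames: int = 80
    grain_px: float = 2.0
    noise_sd: float = 0.0
    deformation: DeformationProfile = DeformationProfile()
    translation_px_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame rate must be positive")
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel spacing must be positive")


@dataclass
class SpeckleMovie:
    """Frame stack + metadata + analytic ground-truth displacement."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    pixel_spacing_mm: float
    frame_rate: float
    spec: SpeckleMovieSpec

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def strain_at(self, frame: int) -> float:
        """Imposed longitudinal strain (fraction, not %) at a frame."""
        tau = frame / (self.n_frames - 1)
        return float(self.spec.deformation(tau)) / 100.0

    def true_position(self, points: np.ndarray, frame: int) -> np.ndarray:
        """Ground-truth (row, col) positions at ``frame`` of material points
        given by their frame-0 (row, col) coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        s = self.strain_at(frame)
        c_col = (self.frames.shape[2] - 1) / 2.0
        dr, dc = self.spec.translation_px_per_frame
        pts[:, 1] = c_col + (1.0 + s) * (pts[:, 1] - c_col) + dc * frame
        pts[:, 0] = pts[:, 0] + dr * frame
        return pts


def _speckle_texture(h: int, w: int, grain_px: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Granular speckle-like texture in [0, 1].

    Smoothed white noise pushed through a tanh contrast stretch: granular
    like a thresholded field but still smooth enough that image gradients
    are informative for sub-pixel tracking.
    """
    noise = rng.normal(0.0, 1.0, (h, w))
    smooth = ndimage.gaussian_filter(noise, grain_px)
    smooth /= smooth.std()
    return 0.5 * (np.tanh(1.5 * smooth) + 1.0)


def generate_speckle_movie(spec: SpeckleMovieSpec) -> SpeckleMovie:
    """Render a speckle phantom under the spec's deformation profile.

    Every frame is warped directly from the frame-0 texture (inverse
    mapping with cubic interpolation), so there is no error accumulation
    and the ground-truth displacement of any point is analytic.
    """
    rng = np.random.default_rng(spec.seed)
    base = _speckle_texture(spec.height, spec.width, spec.grain_px, rng)

    peak = abs(spec.deformation.peak_strain_pct) / 100.0
    c_col = (spec.width - 1) / 2.0
    max_shift = peak * c_col + abs(spec.translation_px_per_frame[1]) * spec.n_frames
    if max_shift >= spec.width / 2.0:
        raise GenerationError("deformation would move the field of view "
                              "outside the image")

    rows, cols = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    dr, dc = spec.translation_px_per_frame
    for f in range(spec.n_frames):
        tau = f / (spec.n_frames - 1)
        s = float(spec.deformation(tau)) / 100.0
        # inverse map: pixel (r, c) in frame f came from this frame-0 point
        src_c = c_col + (cols - dc * f - c_col) / (1.0 + s)
        src_r = rows - dr * f
        img = ndimage.map_coordinates(base, [src_r, src_c], order=3,
                                      mode="nearest")
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[f] = np.clip(img * 255.0, 0, 255).round().astype(np.uint8)
    return SpeckleMovie(frames=frames, pixel_spacing_mm=spec.pixel_spacing_mm,
                        frame_rate=spec.frame_rate, spec=spec)
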