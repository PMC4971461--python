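"""Speckle tracking: ROI placement, pyramidal Lucas-Kanade point tracking,
and cumulative longitudinal strain.

A rectangular region of interest (default 15 mm x 3.3 mm, the marker size
placed in the middle of each muscle) is seeded with a grid of measuring
points in the first frame.  Each point is tracked frame-to-frame with a
pyramidal Lucas-Kanade optical-flow solver (Kanade-Lucas-Tomasi family):
coarse-to-fine iterative refinement of the local translation that best
matches the point's speckle neighbourhood between consecutive frames,
with positions accumulated over the movie (cumulative tracking).  A
forward-backward consistency check flags drifting points invalid from the
failing frame onward.

The longitudinal strain at frame f is the percent change of the effective
ROI length: L(f) is the mean column coordinate of the rightmost valid
measuring-point column minus that of the leftmost, and
strain(f) = 100 * (L(f) - L(0)) / L(0).  Elongation is positive,
shortening negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import SpeckleMovie, StrainSequence

DEFAULT_ROI_LENGTH_MM = 15.0
DEFAULT_ROI_WIDTH_MM = 3.3
DEFAULT_GRID = (5, 25)


class PlacementError(ValueError):
    """ROI rectangle does not fit inside the image."""


class TrackingFailure(RuntimeError):
    """All measuring points lost before the final frame."""


class StrainUndefinedError(RuntimeError):
    """Fewer than two valid measuring-point columns at some frame."""


@dataclass(frozen=True)
class TrackerParams:
    """Pyramidal Lucas-Kanade settings (standard robust defaults)."""

    window: int = 21            # odd window side, pixels
    levels: int = 3             # pyramid levels
    max_iter: int = 30
    eps: float = 0.01           # convergence threshold on the update, px
    fb_threshold: float = 1.0   # forward-backward error limit, px

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")


@dataclass
class Roi:
    """Measuring-point grid of one muscle's rectangular marker."""

    centre: tuple[float, float]       # (row, col), pixels
    length_mm: float
    width_mm: float
    pixel_spacing_mm: float
    points: np.ndarray                # (n_points, 2) as (row, col)
    grid_shape: tuple[int, int]       # (n_rows, n_cols)
    col_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def length_px(self) -> float:
        return self.length_mm / self.pixel_spacing_mm

    @property
    def width_px(self) -> float:
        return self.width_mm / self.pixel_spacing_mm


@dataclass
class TrackResult:
    """Tracked coordinates (frames x points x 2) and validity flags."""

    positions: np.ndarray   # (n_frames, n_points, 2), (row, col)
    valid: np.ndarray       # (n_frames, n_points) bool
    roi: Roi

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def displacements(self) -> np.ndarray:
        """Displacement of every point relative to frame 0."""
        return self.positions - self.positions[0]


def place_roi(image: np.ndarray, centre: tuple[float, float],
              length_mm: float = DEFAULT_ROI_LENGTH_MM,
              width_mm: float = DEFAULT_ROI_WIDTH_MM,
              spacing: float = 0.1,
              grid: tuple[int, int] = DEFAULT_GRID) -> Roi:
    """Place the rectangular ROI and its measuring-point grid.

    The long axis (``length_mm``) runs along the image column axis.  The
    grid has ``grid = (n_rows, n_cols)`` points evenly partitioning the
    rectangle; a single row/column collapses onto the centre line.
    """
    if spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    n_rows, n_cols = grid
    if n_cols < 2:
        raise ValueError("need >= 2 point columns along the ROI length")
    h, w = image.shape[-2:]
    cr, cc = centre
    half_w = width_mm / spacing / 2.0
    half_l = length_mm / spacing / 2.0
    if (cr - half_w < 0 or cr + half_w > h - 1
            or cc - half_l < 0 or cc + half_l > w - 1):
        raise PlacementError(
            f"ROI {length_mm}x{width_mm} mm at {centre} exceeds the "
            f"{h}x{w} px image")

    rows = np.linspace(cr - half_w, cr + half_w, n_rows) if n_rows > 1 \
        else np.array([cr])
    cols = np.linspace(cc - half_l, cc + half_l, n_cols)
    rr, cc_grid = np.meshgrid(rows, cols, indexing="ij")
    points = np.column_stack([rr.ravel(), cc_grid.ravel()])
    col_index = np.tile(np.arange(n_cols), len(rows))
    return Roi(centre=centre, length_mm=length_mm, width_mm=width_mm,
               pixel_spacing_mm=spacing, points=points,
               grid_shape=(len(rows), n_cols), col_index=col_index)


# ---------------------------------------------------------------------------
# Pyramidal Lucas-Kanade


def _build_pyramid(img: np.ndarray, levels: int
                   ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(image, d/drow, d/dcol) triple per level, finest first."""
    out = []
    cur = img.astype(float)
    for lev in range(levels):
        gr, gc = np.gradient(cur)
        out.append((cur, gr, gc))
        if lev < levels - 1:
            cur = ndimage.gaussian_filter(cur, 1.0)[::2, ::2]
    return out


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (n, 2) (row, col) coordinates."""
    return ndimage.map_coordinates(img, coords.T, order=1, mode="nearest")


def _lk_flow(pyr_i, pyr_j, points: np.ndarray, params: TrackerParams
             ) -> tuple[np.ndarray, np.ndarray]:
    """Displacement of ``points`` from image I to image J.

    Vectorized over points; returns (displacements (n,2), ok flags).
    Windows are matched coarse-to-fine; a point fails if its window leaves
    the image at the finest level or the 2x2 gradient matrix is singular.
    """
    n_pts = points.shape[0]
    half = params.window // 2
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    offsets = np.column_stack([dr.ravel(), dc.ravel()]).astype(float)
    n_win = offsets.shape[0]

    d = np.zeros((n_pts, 2))
    ok = np.ones(n_pts, dtype=bool)
    for lev in range(params.levels - 1, -1, -1):
        I, gIr, gIc = pyr_i[lev]
        J, _, _ = pyr_j[lev]
        scale = 2.0 ** lev
        pts_lev = points / scale
        d_lev = d / scale  # d is carried between levels in finest-level px

        # window coordinates around each template point: (n_pts*n_win, 2)
        base = (pts_lev[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        T = _sample(I, base).reshape(n_pts, n_win)
        Ir = _sample(gIr, base).reshape(n_pts, n_win)
        Ic = _sample(gIc, base).reshape(n_pts, n_win)

        g_rr = np.sum(Ir * Ir, axis=1)
        g_rc = np.sum(Ir * Ic, axis=1)
        g_cc = np.sum(Ic * Ic, axis=1)
        det = g_rr * g_cc - g_rc ** 2
        ok &= det > 1e-12

        active = ok.copy()
        for _ in range(params.max_iter):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            coords = (pts_lev[idx, None, :] + d_lev[idx, None, :]
                      + offsets[None, :, :]).reshape(-1, 2)
            Jw = _sample(J, coords).reshape(idx.size, n_win)
            diff = T[idx] - Jw
            b_r = np.sum(diff * Ir[idx], axis=1)
            b_c = np.sum(diff * Ic[idx], axis=1)
            inv_det = 1.0 / det[idx]
            dd_r = (g_cc[idx] * b_r - g_rc[idx] * b_c) * inv_det
            dd_c = (g_rr[idx] * b_c - g_rc[idx] * b_r) * inv_det
            d_lev[idx, 0] += dd_r
            d_lev[idx, 1] += dd_c
            moved = np.hypot(dd_r, dd_c)
            active[idx] = moved >= params.eps
        d = d_lev * scale

    # reject points whose matched window leaves the finest image
    I0 = pyr_i[0][0]
    h, w = I0.shape
    tgt = points + d
    ok &= (tgt[:, 0] >= half) & (tgt[:, 0] <= h - 1 - half) \
        & (tgt[:, 1] >= half) & (tgt[:, 1] <= w - 1 - half)
    return d, ok


def track_points(movie: SpeckleMovie | np.ndarray, roi: Roi,
                 params: TrackerParams = TrackerParams()) -> TrackResult:
    """Track the ROI's measuring points through the whole movie.

    Frame-to-frame pyramidal Lucas-Kanade with accumulated coordinates.
    Each step is verified by tracking the matched position back to the
    previous frame; a forward-backward error above ``params.fb_threshold``
    invalidates the point from that frame onward.
    """
    frames = movie.frames if isinstance(movie, SpeckleMovie) else np.asarray(movie)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("movie must be a (n_frames, H, W) stack with >= 2 frames")
    imgs = frames.astype(float) / 255.0

    n_frames = frames.shape[0]
    n_pts = roi.points.shape[0]
    positions = np.empty((n_frames, n_pts, 2))
    valid = np.ones((n_frames, n_pts), dtype=bool)
    positions[0] = roi.points

    pyr_cur = _build_pyramid(imgs[0], params.levels)
    for f in range(n_frames - 1):
        pyr_next = _build_pyramid(imgs[f + 1], params.levels)
        alive = valid[f]
        positions[f + 1] = positions[f]
        valid[f + 1] = alive
        if not alive.any():
            raise TrackingFailure(f"all measuring points lost at frame {f}")
        pts = positions[f][alive]
        d_fwd, ok_fwd = _lk_flow(pyr_cur, pyr_next, pts, params)
        d_bwd, ok_bwd = _lk_flow(pyr_next, pyr_cur, pts + d_fwd, params)
        fb_err = np.linalg.norm(d_fwd + d_bwd, axis=1)
        good = ok_fwd & ok_bwd & (fb_err <= params.fb_threshold)

        idx = np.flatnonzero(alive)
        positions[f + 1, idx] = pts + d_fwd
        valid[f + 1, idx] = good
        pyr_cur = pyr_next

    if not valid[-1].any():
        raise TrackingFailure(f"all measuring points lost at frame {n_frames - 1}")
    return TrackResult(positions=positions, valid=valid, roi=roi)


def compute_strain_sequence(track: TrackResult, roi: Roi | None = None,
                            participant_id: str = "p00", group: int = 0,
                            muscle: str = "muscle",
                            frame_rate: float = 235.0) -> StrainSequence:
    """Cumulative longitudinal strain (%) from tracked point columns.

    Per frame, the effective ROI length is the mean column coordinate of
    the rightmost valid measuring-point column minus that of the leftmost;
    strain is the percent change against frame 0.
    """
    roi = roi or track.roi
    n_frames = track.n_frames
    col_idx = roi.col_index
    strain = np.empty(n_frames)
    length0 = None
    for f in range(n_frames):
        v = track.valid[f]
        cols_present = np.unique(col_idx[v])
        if cols_present.size < 2:
            raise StrainUndefinedError(
                f"fewer than 2 valid point columns at frame {f}")
        left, right = cols_present[0], cols_present[-1]
        c_left = track.positions[f, v & (col_idx == left), 1].mean()
        c_right = track.positions[f, v & (col_idx == right), 1].mean()
        length = c_right - c_left
        if f == 0:
            length0 = length
        strain[f] = 100.0 * (length - length0) / length0
    strain[0] = 0.0
    return StrainSequence(participant_id=participant_id, group=group,
                          muscle=muscle, strain=strain, frame_rate=frame_rate)
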