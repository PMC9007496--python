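"""Calibrated kymograph construction from a time-lapse stream along a neurite.

A kymograph maps a 3D image stream (time x row x col) to a 2D matrix
(time x position-along-path). Each entry is the maximum intensity in a short
band perpendicular to the neurite path, so a moving punctum appears as a
sloped dark/bright line whose slope is its velocity.

Conventions
-----------
* Pixel coordinates are 0-based (row, col); the first path vertex is the end
  nearest the cell body, and position increases away from it (anterograde).
* Time is measured from the start of the stream; windows are half-open
  ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._geometry import as_vertices, cumulative_arclength_px, points_at_arc
from .errors import ConfigurationError, RangeError

__all__ = ["ImageStream", "NeuritePath", "Kymograph", "build_kymograph", "bleach_mask"]


@dataclass
class ImageStream:
    """Single-channel fluorescence time-lapse with acquisition calibration.

    Parameters
    ----------
    frames : ndarray, shape (t, rows, cols)
        Intensity stack, one 2D frame per time point.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    pixel_size_um : float
        Physical size of one pixel, micrometers.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ConfigurationError(
                f"frames must be a (time, row, col) stack with >= 1 frame, "
                f"got shape {self.frames.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class NeuritePath:
    """Polyline along a neurite, origin at the cell-body end.

    ``sampling_step_px`` sets the spacing of kymograph columns along the path;
    ``roi_halfwidth_px`` the half-width of the perpendicular max-projection
    band (halfwidth 1 = a 3-pixel band, standard for thin neurites).
    """

    vertices: np.ndarray
    sampling_step_px: float = 1.0
    roi_halfwidth_px: int = 1

    def __post_init__(self):
        self.vertices = as_vertices(self.vertices)
        if self.sampling_step_px <= 0:
            raise ConfigurationError("sampling_step_px must be > 0")
        if self.roi_halfwidth_px < 0:
            raise ConfigurationError("roi_halfwidth_px must be >= 0")
        # raises on zero-length paths
        cumulative_arclength_px(self.vertices)

    @property
    def arc_length_px(self) -> float:
        return float(cumulative_arclength_px(self.vertices)[-1])


@dataclass
class Kymograph:
    """Position x time intensity matrix with axis calibrations.

    Rows are time (increasing downward, matching the usual display), columns
    are position along the path in steps of ``position_step_um`` away from the
    cell body. ``t0_s`` records the window start within the source stream.
    """

    matrix: np.ndarray
    frame_interval_s: float
    position_step_um: float
    t0_s: float = 0.0
    path_origin: str = "cell-body end"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ConfigurationError("kymograph matrix must be 2D (time x position)")
        if self.frame_interval_s <= 0 or self.position_step_um <= 0:
            raise ConfigurationError("kymograph calibrations must be > 0")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_rows * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Absolute acquisition time of each row (stream clock)."""
        return self.t0_s + np.arange(self.n_rows) * self.frame_interval_s

    @property
    def positions_um(self) -> np.ndarray:
        """Position of each column center, micrometers from the cell body."""
        return np.arange(self.n_cols) * self.position_step_um

    @property
    def extent_um(self) -> float:
        return float((self.n_cols - 1) * self.position_step_um)


def build_kymograph(stream: ImageStream, path: NeuritePath, window=None) -> Kymograph:
    """Build a kymograph from ``stream`` along ``path`` over a time window.

    The path is resampled at ``path.sampling_step_px`` intervals; for every
    frame in the half-open window ``[t_start, t_end)`` and every sample point
    the kymograph records the maximum bilinearly-interpolated intensity over
    pixel offsets within ``roi_halfwidth_px`` of the point, perpendicular to
    the local path direction.

    Parameters
    ----------
    window : (t_start_s, t_end_s), optional
        Defaults to the full stream. Must lie within the stream duration.
    """
    dt = stream.frame_interval_s
    if window is None:
        window = (0.0, stream.duration_s)
    t_start, t_end = float(window[0]), float(window[1])
    eps = 1e-9
    if not (0.0 - eps <= t_start < t_end <= stream.duration_s + eps):
        raise RangeError(
            f"window [{t_start}, {t_end}) outside stream duration "
            f"[0, {stream.duration_s}]"
        )
    i0 = int(np.ceil(t_start / dt - eps))
    i1 = min(int(np.ceil(t_end / dt - eps)), stream.n_frames)
    if i1 <= i0:
        raise RangeError(f"window [{t_start}, {t_end}) selects no frames")

    step = path.sampling_step_px
    arc_len = path.arc_length_px
    n_cols = int(np.floor(arc_len / step + eps)) + 1
    s_px = np.arange(n_cols) * step
    pts = points_at_arc(path.vertices, s_px)  # (S, 2)

    n_rows_img, n_cols_img = stream.frames.shape[1:]
    if (
        pts[:, 0].min() < -eps
        or pts[:, 0].max() > n_rows_img - 1 + eps
        or pts[:, 1].min() < -eps
        or pts[:, 1].max() > n_cols_img - 1 + eps
    ):
        raise RangeError("path leaves the image bounds")

    # unit tangents via centered differences; normals are tangents rotated 90°
    tang = np.gradient(pts, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    h = int(path.roi_halfwidth_px)
    offsets = np.arange(-h, h + 1, dtype=float)  # (O,) in pixel steps
    rr = pts[:, 0][:, None] + offsets[None, :] * normal[:, 0][:, None]  # (S, O)
    cc = pts[:, 1][:, None] + offsets[None, :] * normal[:, 1][:, None]
    # the band may poke past the border at the image edge; clamp (edge-replicate)
    rr = np.clip(rr, 0, n_rows_img - 1)
    cc = np.clip(cc, 0, n_cols_img - 1)

    frames = stream.frames
    if not np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    n_t = i1 - i0
    tt = np.arange(i0, i1, dtype=float)
    # one trilinear interpolation call over the whole window; time coordinates
    # are integers so the interpolation along time is exact
    coords = np.empty((3, n_t, pts.shape[0], offsets.size))
    coords[0] = tt[:, None, None]
    coords[1] = rr[None, :, :]
    coords[2] = cc[None, :, :]
    vals = ndimage.map_coordinates(
        frames, coords.reshape(3, -1), order=1, mode="nearest"
    ).reshape(n_t, pts.shape[0], offsets.size)
    matrix = vals.max(axis=2)

    return Kymograph(
        matrix=matrix,
        frame_interval_s=dt,
        position_step_um=step * stream.pixel_size_um,
        t0_s=i0 * dt,
    )


def bleach_mask(kymo: Kymograph, bleach_window_um) -> tuple[int, int]:
    """Half-open column interval ``[c0, c1)`` covering a bleached segment.

    Columns whose center position lies in ``[start_um, end_um)`` are selected;
    an ``end_um`` at (or past) the kymograph extent includes the last column,
    so ``(0, extent)`` selects every column. Used to restrict event detection
    to the photobleached, low-background stretch of the neurite.
    """
    start_um, end_um = float(bleach_window_um[0]), float(bleach_window_um[1])
    eps = 1e-9
    step = kymo.position_step_um
    extent = kymo.extent_um
    if start_um > end_um or start_um < -eps or end_um > extent + step:
        raise RangeError(
            f"bleach window ({start_um}, {end_um}) outside kymograph "
            f"position extent [0, {extent}]"
        )
    if end_um - start_um <= eps:
        return (0, 0)
    c0 = int(np.ceil(start_um / step - eps))
    c1 = int(np.ceil(end_um / step - eps))
    if end_um >= extent - eps:
        c1 = kymo.n_cols
    return (c0, min(c1, kymo.n_cols))
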