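"""Polyline geometry helpers: arc-length parameterization of a neurite path.

Paths are ordered (row, col) vertices in 0-based pixel coordinates with the
first vertex at the cell-body end. Arc length is measured in pixels; callers
convert to micrometers with the stream's pixel size.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def as_vertices(path) -> np.ndarray:
    """Validate and return a polyline as a float (n, 2) array of (row, col)."""
    verts = np.asarray(path, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ConfigurationError(
            f"path must be a sequence of (row, col) points, got shape {verts.shape}"
        )
    if verts.shape[0] < 2:
        raise ConfigurationError("path must have at least 2 vertices")
    if not np.all(np.isfinite(verts)):
        raise ConfigurationError("path vertices must be finite")
    return verts


def cumulative_arclength_px(verts: np.ndarray) -> np.ndarray:
    """Cumulative arc length (pixels) at each vertex, starting at 0."""
    seg = np.hypot(np.diff(verts[:, 0]), np.diff(verts[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ConfigurationError("path has zero arc length")
    return s


def points_at_arc(verts: np.ndarray, s_px) -> np.ndarray:
    """(row, col) points at the given arc-length positions (pixels).

    Positions are clipped to the path extent; rows and columns are
    piecewise-linear in arc length so plain interpolation is exact.
    """
    s_cum = cumulative_arclength_px(verts)
    s = np.clip(np.atleast_1d(np.asarray(s_px, dtype=float)), 0.0, s_cum[-1])
    rows = np.interp(s, s_cum, verts[:, 0])
    cols = np.interp(s, s_cum, verts[:, 1])
    return np.column_stack([rows, cols])
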