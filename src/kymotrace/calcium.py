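"""GCaMP trace metrics: ΔF/F_min, peak amplitudes, total activity, baseline.

The baseline F_min is the minimum of a boxcar-smoothed trace rather than the
raw global minimum — a raw minimum is an order statistic of the noise and
biases ΔF/F upward; smoothing over ~1 s gives a stable estimator while still
tracking the darkest stretch of the recording.

Metrics:

* ``dff[i] = (F[i] - F_min) / F_min``
* ``total_activity = sum_i max(F[i] - F_min, 0) / F_min`` — the sum of
  fluorescence values above baseline divided by baseline (dimensionless).
* peaks: local maxima of ΔF/F with a minimum prominence and separation;
  ``mean_peak_amplitude_dff`` is the mean ΔF/F at those peaks.

Per-animal metrics are compared across groups after dividing by the mean of
an untreated control group (:func:`normalize_to_control`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import ConfigurationError, InvalidTraceError, NormalizationError

__all__ = [
    "CalciumTrace",
    "CalciumParams",
    "CalciumMetrics",
    "compute_metrics",
    "normalize_to_control",
    "extract_roi_trace",
]


@dataclass
class CalciumTrace:
    """A single-ROI fluorescence time series."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    frame_interval_s: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.shape != self.fluorescence.shape or self.time_s.ndim != 1:
            raise ConfigurationError("time_s and fluorescence must be equal-length 1D")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ConfigurationError("time_s must be strictly increasing")
        if np.any(self.fluorescence < 0):
            raise ConfigurationError("fluorescence must be non-negative")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be > 0")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class CalciumParams:
    baseline_smooth_window_s: float = 1.0
    peak_min_prominence_dff: float = 0.1
    peak_min_separation_s: float = 1.0

    def __post_init__(self):
        if (
            self.baseline_smooth_window_s <= 0
            or self.peak_min_prominence_dff <= 0
            or self.peak_min_separation_s <= 0
        ):
            raise ConfigurationError("all calcium parameters must be > 0")


@dataclass
class CalciumMetrics:
    """Per-trace metrics; ``mean_peak_amplitude_dff`` is None when no peaks."""

    f_min_baseline: float
    dff: np.ndarray
    mean_peak_amplitude_dff: Optional[float]
    total_activity: float
    n_peaks: int
    peak_times_s: np.ndarray
    peak_amplitudes_dff: np.ndarray


def compute_metrics(trace: CalciumTrace, params: CalciumParams = CalciumParams()):
    """Compute baseline, ΔF/F, peaks and total activity for one trace."""
    f = trace.fluorescence
    window = max(1, round(params.baseline_smooth_window_s / trace.frame_interval_s))
    if window > f.size:
        raise InvalidTraceError(
            f"trace of {f.size} samples is shorter than the {window}-sample "
            "baseline smoothing window"
        )
    smoothed = uniform_filter1d(f, size=window, mode="nearest")
    f_min = float(smoothed.min())
    if f_min <= 0:
        raise InvalidTraceError("baseline F_min must be positive")

    dff = (f - f_min) / f_min
    total_activity = float(np.clip(f - f_min, 0.0, None).sum() / f_min)

    distance = max(1, round(params.peak_min_separation_s / trace.frame_interval_s))
    peak_idx, _ = find_peaks(
        dff, prominence=params.peak_min_prominence_dff, distance=distance
    )
    amplitudes = dff[peak_idx]
    return CalciumMetrics(
        f_min_baseline=f_min,
        dff=dff,
        mean_peak_amplitude_dff=float(amplitudes.mean()) if peak_idx.size else None,
        total_activity=total_activity,
        n_peaks=int(peak_idx.size),
        peak_times_s=trace.time_s[peak_idx],
        peak_amplitudes_dff=amplitudes,
    )


def normalize_to_control(metric_values, control_values):
    """Divide both groups by the control-group mean.

    Returns ``(normalized_metric_values, normalized_control_values)`` in the
    input order; by construction the normalized control mean is exactly 1.
    """
    metric = np.asarray(metric_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise NormalizationError("control group is empty")
    mean = control.mean()
    if mean == 0 or not np.isfinite(mean):
        raise NormalizationError("control mean is zero or non-finite")
    return metric / mean, control / mean


def extract_roi_trace(stream, roi) -> CalciumTrace:
    """Mean-intensity trace over an ROI of an image stream.

    ``roi`` is either a rectangle ``(row_start, row_stop, col_start,
    col_stop)`` (half-open) or a polygon given as a sequence of (row, col)
    vertices (length != 4 outer sequence or nested pairs).
    """
    frames = np.asarray(stream.frames, dtype=float)
    roi_arr = np.asarray(roi, dtype=float)
    if roi_arr.ndim == 1 and roi_arr.size == 4:
        r0, r1, c0, c1 = (int(v) for v in roi_arr)
        if not (0 <= r0 < r1 <= frames.shape[1] and 0 <= c0 < c1 <= frames.shape[2]):
            raise ConfigurationError("rectangular ROI outside the image")
        values = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    else:
        from skimage.draw import polygon2mask

        mask = polygon2mask(frames.shape[1:], roi_arr)
        if not mask.any():
            raise ConfigurationError("polygon ROI covers no pixels")
        values = frames[:, mask].mean(axis=1)
    dt = stream.frame_interval_s
    return CalciumTrace(
        time_s=np.arange(frames.shape[0]) * dt,
        fluorescence=np.maximum(values, 0.0),
        frame_interval_s=dt,
    )
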