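"""Synthetic fluorescence-microscopy data with known ground truth.

Two generators emulate the study's acquisition regimes:

* :func:`simulate_transport_stream` — a photobleached neurite segment through
  which dim punctate vesicles (2D Gaussian spots) move bidirectionally at
  roughly constant velocity with occasional pauses, imaged continuously
  (default 50 s at 100 ms/frame).
* :func:`simulate_calcium_trace` — a somatic GCaMP6f fluorescence trace: a
  slowly drifting baseline times (1 + sparse transients), each transient a
  difference-of-exponentials kernel with fast rise and slower decay
  (default 60 s at 250 ms/frame, i.e. 240 samples).

Both return the generated data together with its ground truth so every
downstream stage (kymograph, event detection, trace metrics, statistics)
can be tested for recovery without external data. All randomness flows from
the mandatory ``seed`` field; identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import as_vertices, cumulative_arclength_px, points_at_arc
from .calcium import CalciumTrace
from .errors import ConfigurationError
from .kymograph import ImageStream

__all__ = [
    "TransportSimConfig",
    "VesicleSpec",
    "GroundTruthTrack",
    "CalciumSimConfig",
    "GroundTruthTransients",
    "simulate_transport_stream",
    "simulate_calcium_trace",
    "staggered_vesicle_specs",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


@dataclass(frozen=True)
class VesicleSpec:
    """Explicit schedule for one vesicle (overrides random generation).

    ``velocity_um_s`` is signed: positive = anterograde (away from the cell
    body). ``entry_pos_um`` defaults to the path end the vesicle enters from
    (0 for anterograde, the far end for retrograde).
    """

    entry_time_s: float
    velocity_um_s: float
    entry_pos_um: Optional[float] = None


@dataclass(frozen=True)
class TransportSimConfig:
    """Configuration of a simulated vesicle-transport image stream.

    Defaults follow the transport acquisition regime (50 s of continuous
    imaging at 100 ms/frame) with a 0.1 µm pixel. The neurite is a polyline
    of (row, col) pixel vertices whose first vertex is the cell-body end;
    the segment between ``bleach_window_um`` arc positions has its stationary
    background attenuated by ``bleach_factor``, emulating the photobleach
    that uncovers dim moving vesicles. Moving vesicles are never attenuated.
    """

    duration_s: float = 50.0
    frame_interval_s: float = 0.1
    pixel_size_um: float = 0.1
    field_shape: tuple = (16, 160)
    path: Sequence = ((8.0, 4.0), (8.0, 155.0))
    n_vesicles: int = 8
    velocity_range_um_s: tuple = (0.8, 1.6)
    direction_mix: float = 0.5
    pause_prob_per_frame: float = 0.05
    vesicle_amplitude: float = 25.0
    vesicle_sigma_um: float = 0.15
    background_level: float = 150.0
    bleach_window_um: tuple = (1.5, 13.5)
    bleach_factor: float = 0.1
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0
    # plumbing knobs, defaults leave behavior unchanged
    reversal_prob_per_frame: float = 0.0
    poisson_vesicle_count: bool = False
    vesicle_specs: Optional[tuple] = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if not (0 < self.bleach_factor <= 1):
            raise ConfigurationError("bleach_factor must be in (0, 1]")
        vmin, vmax = self.velocity_range_um_s
        if vmin <= 0 or vmax <= 0 or vmin > vmax:
            raise ConfigurationError(
                "velocity bounds must be positive with min <= max"
            )
        if not (0 <= self.direction_mix <= 1):
            raise ConfigurationError("direction_mix must be in [0, 1]")
        if not (0 <= self.pause_prob_per_frame < 1):
            raise ConfigurationError("pause_prob_per_frame must be in [0, 1)")
        if self.n_vesicles < 0:
            raise ConfigurationError("n_vesicles must be >= 0")
        if self.vesicle_sigma_um <= 0:
            raise ConfigurationError("vesicle_sigma_um must be > 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        verts = as_vertices(self.path)
        extent_um = cumulative_arclength_px(verts)[-1] * self.pixel_size_um
        b0, b1 = self.bleach_window_um
        if not (0 <= b0 <= b1 <= extent_um + 1e-9):
            raise ConfigurationError(
                f"bleach_window_um ({b0}, {b1}) outside path extent "
                f"[0, {extent_um:.3f}]"
            )

    @property
    def n_frames(self) -> int:
        return round(self.duration_s / self.frame_interval_s)

    @property
    def path_length_um(self) -> float:
        verts = as_vertices(self.path)
        return float(cumulative_arclength_px(verts)[-1] * self.pixel_size_um)


@dataclass
class GroundTruthTrack:
    """Per-frame ground truth for one simulated vesicle.

    ``positions_um`` has one entry per stream frame; NaN marks frames where
    the vesicle is not in the field (before entry or after leaving the path).
    ``mean_velocity_um_s`` is the signed instantaneous velocity while moving.
    """

    vesicle_id: int
    entry_time_s: float
    positions_um: np.ndarray
    direction: str
    mean_velocity_um_s: float
    paused_frames: int

    def displacement_um(self) -> float:
        """Signed net displacement over the frames the vesicle is in field."""
        finite = self.positions_um[np.isfinite(self.positions_um)]
        if finite.size < 2:
            return 0.0
        return float(finite[-1] - finite[0])


@dataclass(frozen=True)
class CalciumSimConfig:
    """Configuration of a simulated somatic GCaMP6f trace.

    Defaults follow the calcium acquisition regime: 60 s at 250 ms per frame
    (240 samples). Kinetic defaults (0.5 s rise, 2.5 s decay) describe the
    multi-second somatic events of a command interneuron, which the 4 Hz
    sampling resolves comfortably. ``transient_amplitude_range`` is in ΔF/F
    units; each transient kernel is scaled so its maximum equals the drawn
    amplitude.
    """

    duration_s: float = 60.0
    frame_interval_s: float = 0.25
    baseline_level: float = 100.0
    baseline_drift_amplitude: float = 5.0
    n_transients: int = 3
    transient_amplitude_range: tuple = (0.2, 1.0)
    rise_tau_s: float = 0.5
    decay_tau_s: float = 2.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.frame_interval_s <= 0:
            raise ConfigurationError("duration_s and frame_interval_s must be > 0")
        if self.baseline_level <= 0:
            raise ConfigurationError("baseline_level must be > 0")
        if not (0 < self.rise_tau_s < self.decay_tau_s):
            raise ConfigurationError("need decay_tau_s > rise_tau_s > 0")
        if self.n_transients < 0:
            raise ConfigurationError("n_transients must be >= 0")
        a0, a1 = self.transient_amplitude_range
        if a0 <= 0 or a0 > a1:
            raise ConfigurationError("transient amplitudes must be positive, min <= max")
        if self.baseline_drift_amplitude < 0:
            raise ConfigurationError("baseline_drift_amplitude must be >= 0")
        if self.baseline_drift_amplitude >= self.baseline_level:
            raise ConfigurationError("drift amplitude must stay below the baseline")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s / self.frame_interval_s)


@dataclass
class GroundTruthTransients:
    """Ground truth for a simulated calcium trace.

    ``peak_amplitudes_dff`` is the ideal ΔF/F_min of the noiseless trace at
    each transient peak — the true value of the quantity a ΔF/F_min analysis
    estimates. With a flat baseline it equals the drawn kernel amplitude;
    with drift it additionally carries the baseline elevation at peak time.
    """

    onset_times_s: np.ndarray
    peak_amplitudes_dff: np.ndarray
    true_baseline: np.ndarray


def staggered_vesicle_specs(
    k: int,
    path_length_um: float,
    speeds_um_s: Sequence[float] = (1.8, 2.0, 2.2),
    start_interval_s: float = 8.0,
    first_direction: str = ANTEROGRADE,
) -> tuple:
    """Schedules for ``k`` well-separated vesicles with alternating direction.

    Vesicle ``i`` enters at ``i * start_interval_s`` from alternating ends of
    the path, so consecutive vesicles are never simultaneously mid-segment —
    a clean scene for count/direction/velocity recovery checks.
    """
    specs = []
    flip = 0 if first_direction == ANTEROGRADE else 1
    for i in range(k):
        antero = (i + flip) % 2 == 0
        speed = float(speeds_um_s[i % len(speeds_um_s)])
        specs.append(
            VesicleSpec(
                entry_time_s=i * start_interval_s,
                velocity_um_s=speed if antero else -speed,
                entry_pos_um=0.0 if antero else path_length_um,
            )
        )
    return tuple(specs)


def _bleach_pixel_mask(config: TransportSimConfig, verts: np.ndarray) -> np.ndarray:
    """Boolean field mask of pixels whose nearest path point is bleached.

    Assigning each pixel to its nearest point on the (densely resampled) path
    partitions the field into bands perpendicular to the neurite, emulating a
    photobleach of everything flanking the chosen arc interval.
    """
    arc_len = cumulative_arclength_px(verts)[-1]
    s_dense = np.arange(0.0, arc_len + 0.25, 0.5)
    pts = points_at_arc(verts, s_dense)
    tree = cKDTree(pts)
    n_rows, n_cols = config.field_shape
    grid = np.stack(
        np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    _, nearest = tree.query(grid)
    s_um = s_dense[nearest] * config.pixel_size_um
    b0, b1 = config.bleach_window_um
    return ((s_um >= b0) & (s_um < b1)).reshape(n_rows, n_cols)


def _draw_vesicle_params(config: TransportSimConfig, rng: np.random.Generator):
    """(entry_time_s, signed velocity, entry position) for each vesicle."""
    length_um = config.path_length_um
    if config.vesicle_specs is not None:
        out = []
        for spec in config.vesicle_specs:
            pos = spec.entry_pos_um
            if pos is None:
                pos = 0.0 if spec.velocity_um_s > 0 else length_um
            out.append((float(spec.entry_time_s), float(spec.velocity_um_s), float(pos)))
        return out
    n = (
        int(rng.poisson(config.n_vesicles))
        if config.poisson_vesicle_count
        else config.n_vesicles
    )
    vmin, vmax = config.velocity_range_um_s
    out = []
    for _ in range(n):
        antero = rng.random() < config.direction_mix
        speed = rng.uniform(vmin, vmax)
        entry_t = rng.uniform(0.0, config.duration_s)
        v = speed if antero else -speed
        pos = 0.0 if antero else length_um
        out.append((entry_t, v, pos))
    return out


def _track_positions(
    config: TransportSimConfig,
    rng: np.random.Generator,
    entry_time_s: float,
    velocity_um_s: float,
    entry_pos_um: float,
):
    """Per-frame arc positions (µm) for one vesicle; NaN when out of field."""
    n_frames = config.n_frames
    dt = config.frame_interval_s
    length_um = config.path_length_um
    positions = np.full(n_frames, np.nan)
    entry_frame = int(np.ceil(entry_time_s / dt - 1e-9))
    m = n_frames - max(entry_frame, 0)
    if m <= 0:
        return positions, 0
    moving = rng.random(m) >= config.pause_prob_per_frame
    if config.reversal_prob_per_frame > 0:
        flips = rng.random(m) < config.reversal_prob_per_frame
        sign = np.cumprod(np.where(flips, -1.0, 1.0))
    else:
        sign = 1.0
    steps = velocity_um_s * dt * moving * sign
    pos = entry_pos_um + np.cumsum(steps)
    out = (pos < -1e-9) | (pos > length_um + 1e-9)
    if out.any():
        cut = int(np.argmax(out))
        pos = pos[:cut]
        moving = moving[:cut]
    positions[entry_frame : entry_frame + pos.size] = pos
    paused = int(np.count_nonzero(~moving))
    return positions, paused


def _render_tracks(
    config: TransportSimConfig, frames: np.ndarray, tracks: Sequence[GroundTruthTrack]
) -> None:
    """Add each vesicle as an analytic 2D Gaussian spot, in place.

    The Gaussian is evaluated at pixel centers around the (sub-pixel) spot
    center; it is separable, so per-frame patches are outer products.
    """
    verts = as_vertices(config.path)
    sigma_px = config.vesicle_sigma_um / config.pixel_size_um
    w = max(2, int(math.ceil(4.0 * sigma_px)))
    off = np.arange(-w, w + 1)
    n_rows, n_cols = config.field_shape
    for track in tracks:
        idx = np.nonzero(np.isfinite(track.positions_um))[0]
        if idx.size == 0:
            continue
        s_px = track.positions_um[idx] / config.pixel_size_um
        centers = points_at_arc(verts, s_px)  # (m, 2)
        r0 = np.round(centers[:, 0]).astype(int)
        c0 = np.round(centers[:, 1]).astype(int)
        pr = r0[:, None] + off[None, :]  # (m, P)
        pc = c0[:, None] + off[None, :]
        er = np.exp(-((pr - centers[:, 0][:, None]) ** 2) / (2 * sigma_px**2))
        ec = np.exp(-((pc - centers[:, 1][:, None]) ** 2) / (2 * sigma_px**2))
        er[(pr < 0) | (pr >= n_rows)] = 0.0
        ec[(pc < 0) | (pc >= n_cols)] = 0.0
        patch = config.vesicle_amplitude * np.einsum("mi,mj->mij", er, ec)
        # one patch per frame with distinct pixel coordinates -> the index
        # triples are unique within this statement, so buffered fancy-index
        # addition is exact (and much faster than np.add.at)
        frames[
            idx[:, None, None],
            np.clip(pr, 0, n_rows - 1)[:, :, None],
            np.clip(pc, 0, n_cols - 1)[:, None, :],
        ] += patch


def simulate_transport_stream(config: TransportSimConfig):
    """Simulate a photobleach-then-stream transport movie.

    Returns
    -------
    (ImageStream, list of GroundTruthTrack)
        The noisy stream and one ground-truth track per vesicle. With noise
        disabled the stream is exactly background + rendered spots; the
        stationary background inside the bleach window is multiplied by
        ``bleach_factor`` while moving vesicles are left untouched.
    """
    verts = as_vertices(config.path)
    ss = np.random.SeedSequence(config.seed)
    rng_motion, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    params = _draw_vesicle_params(config, rng_motion)
    tracks = []
    for j, (entry_t, v, entry_pos) in enumerate(params):
        positions, paused = _track_positions(config, rng_motion, entry_t, v, entry_pos)
        tracks.append(
            GroundTruthTrack(
                vesicle_id=j,
                entry_time_s=entry_t,
                positions_um=positions,
                direction=ANTEROGRADE if v > 0 else RETROGRADE,
                mean_velocity_um_s=v,
                paused_frames=paused,
            )
        )

    base = np.full(config.field_shape, float(config.background_level))
    if config.bleach_factor < 1.0:
        base[_bleach_pixel_mask(config, verts)] *= config.bleach_factor
    frames = np.broadcast_to(base, (config.n_frames, *config.field_shape)).copy()
    _render_tracks(config, frames, tracks)

    if config.shot_noise:
        frames = rng_noise.poisson(frames).astype(float)
    if config.read_noise_sd > 0:
        frames = frames + rng_noise.normal(0.0, config.read_noise_sd, frames.shape)

    stream = ImageStream(
        frames=frames,
        frame_interval_s=config.frame_interval_s,
        pixel_size_um=config.pixel_size_um,
    )
    return stream, tracks


def _transient_kernel(t: np.ndarray, onset_s: float, rise_tau: float, decay_tau: float):
    """Difference-of-exponentials kernel, normalized to unit maximum."""
    x = t - onset_s
    k = np.where(
        x >= 0, np.exp(-np.maximum(x, 0) / decay_tau) - np.exp(-np.maximum(x, 0) / rise_tau), 0.0
    )
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return k / peak


def simulate_calcium_trace(config: CalciumSimConfig):
    """Simulate a somatic GCaMP6f trace with known transients.

    The trace is ``baseline(t) * (1 + sum of transient kernels) + noise``,
    where the baseline drifts as a slow sinusoid and each kernel is scaled so
    its maximum equals the drawn ΔF/F amplitude. Onsets are stratified across
    the recording so transients stay temporally resolvable.
    """
    n = config.n_samples
    t = np.arange(n) * config.frame_interval_s
    rng = np.random.default_rng(config.seed)

    phase = rng.uniform(0, 2 * math.pi)
    baseline = config.baseline_level + config.baseline_drift_amplitude * np.sin(
        2 * math.pi * t / config.duration_s + phase
    )

    k = config.n_transients
    if k > 0:
        edges = np.linspace(0.03 * config.duration_s, 0.97 * config.duration_s, k + 1)
        onsets = edges[:-1] + rng.uniform(0.1, 0.6, size=k) * np.diff(edges)
        a0, a1 = config.transient_amplitude_range
        amplitudes = rng.uniform(a0, a1, size=k)
    else:
        onsets = np.empty(0)
        amplitudes = np.empty(0)

    signal = np.zeros(n)
    for onset, amp in zip(onsets, amplitudes):
        signal += amp * _transient_kernel(t, onset, config.rise_tau_s, config.decay_tau_s)

    fluor = baseline * (1.0 + signal)
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.noise_sd, n)
    fluor = np.maximum(fluor, 0.0)

    # ideal ΔF/F_min at each kernel peak: the true value of the estimand
    tau_r, tau_d = config.rise_tau_s, config.decay_tau_s
    t_peak_offset = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    b_min = baseline.min()
    baseline_at_peak = config.baseline_level + config.baseline_drift_amplitude * np.sin(
        2 * math.pi * (onsets + t_peak_offset) / config.duration_s + phase
    )
    true_dff_amplitudes = (baseline_at_peak * (1.0 + amplitudes) - b_min) / b_min

    trace = CalciumTrace(
        time_s=t, fluorescence=fluor, frame_interval_s=config.frame_interval_s
    )
    truth = GroundTruthTransients(
        onset_times_s=onsets,
        peak_amplitudes_dff=true_dff_amplitudes,
        true_baseline=baseline,
    )
    return trace, truth
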