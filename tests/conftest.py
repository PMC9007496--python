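import numpy as np
import pytest

import kymotrace as kt


@pytest.fixture
def straight_path_cfg():
    """Transport config with a straight horizontal neurite, noise off."""
    return kt.TransportSimConfig(
        duration_s=10.0,
        field_shape=(16, 160),
        path=((8.0, 4.0), (8.0, 155.0)),
        n_vesicles=0,
        bleach_factor=1.0,
        shot_noise=False,
        read_noise_sd=0.0,
        background_level=10.0,
        seed=0,
    )


def run_detection(cfg: kt.TransportSimConfig, params: kt.EventParams = None):
    """Simulate a scene and run the kymograph -> event-detection pipeline."""
    stream, tracks = kt.simulate_transport_stream(cfg)
    path = kt.NeuritePath(np.asarray(cfg.path, dtype=float))
    kymo = kt.build_kymograph(stream, path)
    restrict = (
        kt.bleach_mask(kymo, cfg.bleach_window_um) if cfg.bleach_factor < 1 else None
    )
    events = kt.detect_events(kymo, params or kt.EventParams(), restrict_to=restrict)
    return stream, tracks, kymo, events


def match_event_to_track(event, tracks, frame_interval_s):
    """Ground-truth track with the largest temporal overlap with an event."""
    best, best_overlap = None, 0.0
    for track in tracks:
        finite = np.nonzero(np.isfinite(track.positions_um))[0]
        if finite.size < 2:
            continue
        t0, t1 = finite[0] * frame_interval_s, finite[-1] * frame_interval_s
        overlap = min(event.t_end_s, t1) - max(event.t_start_s, t0)
        if overlap > best_overlap:
            best, best_overlap = track, overlap
    return best
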