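"""Reading and writing the pipeline's on-disk formats.

Streams are multi-page 16-bit grayscale TIFFs with a JSON sidecar carrying
the frame interval and pixel size; kymographs go out as 16-bit TIFF, an
8-bit PNG for display (time downward, position rightward) and a CSV of the
raw matrix; tables (ground truth, events, traces, metrics) are plain CSV and
summaries are JSON. Nothing binary beyond TIFF/PNG is ever written.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calcium import CalciumTrace
from .events import TransportEvent, TransportSummary
from .kymograph import ImageStream, Kymograph


def _to_uint16(array: np.ndarray) -> np.ndarray:
    return np.clip(np.round(array), 0, 65535).astype(np.uint16)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stream(stream: ImageStream, path) -> Path:
    """Write a stream as multi-page uint16 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    meta = {
        "frame_interval_s": stream.frame_interval_s,
        "pixel_size_um": stream.pixel_size_um,
        "n_frames": stream.n_frames,
    }
    tifffile.imwrite(path, _to_uint16(stream.frames), description=json.dumps(meta))
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_stream(path) -> ImageStream:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        with tifffile.TiffFile(path) as tif:
            meta = json.loads(tif.pages[0].description)
    return ImageStream(
        frames=frames.astype(float),
        frame_interval_s=meta["frame_interval_s"],
        pixel_size_um=meta["pixel_size_um"],
    )


def tracks_to_table(tracks, frame_interval_s: float) -> pd.DataFrame:
    """Ground-truth tracks as one row per vesicle per in-field frame."""
    records = []
    for track in tracks:
        for frame, pos in enumerate(track.positions_um):
            if np.isfinite(pos):
                records.append(
                    {"vesicle_id": track.vesicle_id, "frame": frame,
                     "time_s": frame * frame_interval_s, "position_um": pos}
                )
    return pd.DataFrame.from_records(
        records, columns=["vesicle_id", "frame", "time_s", "position_um"]
    )


def save_ground_truth(tracks, frame_interval_s: float, csv_path, json_path=None):
    csv_path = Path(csv_path)
    tracks_to_table(tracks, frame_interval_s).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = [
            {
                "vesicle_id": t.vesicle_id,
                "entry_time_s": t.entry_time_s,
                "direction": t.direction,
                "mean_velocity_um_s": t.mean_velocity_um_s,
                "paused_frames": t.paused_frames,
                "displacement_um": t.displacement_um(),
            }
            for t in tracks
        ]
        Path(json_path).write_text(json.dumps(summary, indent=2))
    return csv_path


def save_trace(trace: CalciumTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "fluorescence": trace.fluorescence}).to_csv(
        path, index=False
    )
    return path


def load_trace(path, frame_interval_s=None) -> CalciumTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if frame_interval_s is None:
        frame_interval_s = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return CalciumTrace(
        time_s=t,
        fluorescence=df["fluorescence"].to_numpy(),
        frame_interval_s=frame_interval_s,
    )


def save_kymograph(kymo: Kymograph, base_path) -> dict:
    """Write TIFF + display PNG + CSV for a kymograph; returns the paths.

    The PNG is min-max scaled to 8 bit with time downward and position
    rightward, the orientation used in transport figures.
    """
    base = Path(base_path)
    paths = {
        "tiff": base.with_suffix(".tif"),
        "png": base.with_suffix(".png"),
        "csv": base.with_suffix(".csv"),
        "meta": base.with_suffix(".json"),
    }
    tifffile.imwrite(paths["tiff"], _to_uint16(kymo.matrix))
    m = np.asarray(kymo.matrix, dtype=float)
    span = m.max() - m.min()
    display = (m - m.min()) / span if span > 0 else np.zeros_like(m)
    iio.imwrite(paths["png"], (display * 255).astype(np.uint8))
    np.savetxt(paths["csv"], kymo.matrix, delimiter=",")
    paths["meta"].write_text(
        json.dumps(
            {
                "frame_interval_s": kymo.frame_interval_s,
                "position_step_um": kymo.position_step_um,
                "t0_s": kymo.t0_s,
                "path_origin": kymo.path_origin,
            },
            indent=2,
        )
    )
    return paths


def load_kymograph(path, meta_path=None) -> Kymograph:
    """Load a kymograph from CSV or TIFF, with its JSON calibration sidecar."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        matrix = tifffile.imread(path).astype(float)
    else:
        matrix = np.loadtxt(path, delimiter=",")
    return Kymograph(
        matrix=matrix,
        frame_interval_s=meta["frame_interval_s"],
        position_step_um=meta["position_step_um"],
        t0_s=meta.get("t0_s", 0.0),
        path_origin=meta.get("path_origin", "cell-body end"),
    )


def events_to_table(events) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [dataclasses.asdict(e) for e in events],
        columns=[f.name for f in dataclasses.fields(TransportEvent)],
    )


def save_events(events, summary: TransportSummary, csv_path, json_path=None):
    csv_path = Path(csv_path)
    events_to_table(events).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(dataclasses.asdict(summary), indent=2))
    return csv_path
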