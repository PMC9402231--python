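"""File formats: wide recording CSV + JSON sidecar, raster CSV, events TSV,
section TIFF + geometry JSON. Floats are written with fixed precision so
identical runs produce byte-identical files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import dump_json, load_json
from .events import NetworkEvent
from .simulate import GroundTruth, Recording, SectionGeometry

FLOAT_FORMAT = "%.6f"


def _cols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1:04d}" for i in range(n)]


def write_recording(out_dir: str | Path, recording: Recording,
                    ground_truth: GroundTruth | None = None,
                    stem: str = "recording") -> Path:
    """Write rec CSV (frame, cell_*, surround_*) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = recording.n_cells
    df = pd.DataFrame({"frame": np.arange(recording.n_frames)})
    for name, col in zip(_cols("cell", n), recording.cell_traces):
        df[name] = col
    for name, col in zip(_cols("surround", n), recording.surround_traces):
        df[name] = col
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)

    sidecar = {
        "frame_rate_hz": recording.frame_rate_hz,
        "n_cells": n,
        "n_frames": recording.n_frames,
        "labels": (recording.labels.astype(int).tolist()
                   if recording.labels is not None else None),
        "seed": ground_truth.seed if ground_truth is not None else None,
    }
    dump_json(sidecar, out_dir / f"{stem}.json")
    if ground_truth is not None:
        dump_json(ground_truth_to_dict(ground_truth),
                  out_dir / f"{stem}_ground_truth.json")
    return csv_path


def read_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    sidecar = load_json(csv_path.with_suffix(".json"))
    df = pd.read_csv(csv_path)
    n = int(sidecar["n_cells"])
    cell = df[_cols("cell", n)].to_numpy().T
    surround = df[_cols("surround", n)].to_numpy().T
    labels = sidecar.get("labels")
    return Recording(cell_traces=cell, surround_traces=surround,
                     frame_rate_hz=float(sidecar["frame_rate_hz"]),
                     labels=np.asarray(labels, dtype=bool)
                     if labels is not None else None)


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "seed": truth.seed,
        "true_r": truth.true_r.tolist(),
        "events": [{
            "onset_frame": e.onset_frame,
            "offset_frame": e.offset_frame,
            "drive_onset_s": e.drive_onset_s,
            "drive_offset_s": e.drive_offset_s,
            "event_class": e.event_class,
            "participation": e.participation,
            "participants": np.asarray(e.participants).tolist(),
        } for e in truth.events],
    }


def write_raster(path: str | Path, raster: np.ndarray,
                 frame_rate_hz: float) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(raster, dtype=int).T,
                      columns=_cols("cell", raster.shape[0]))
    df.insert(0, "frame", np.arange(raster.shape[1]))
    df.to_csv(path, index=False)
    dump_json({"frame_rate_hz": frame_rate_hz,
               "n_cells": int(raster.shape[0])},
              path.with_suffix(".json"))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    sidecar = load_json(path.with_suffix(".json"))
    df = pd.read_csv(path)
    raster = df[_cols("cell", int(sidecar["n_cells"]))].to_numpy().T.astype(bool)
    return raster, float(sidecar["frame_rate_hz"])


def write_events(path: str | Path, events: list[NetworkEvent],
                 frame_rate_hz: float) -> Path:
    from .events import events_to_frame

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events_to_frame(events, frame_rate_hz).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_section_with_geometry(out_dir: str | Path, image: np.ndarray,
                                geometry: SectionGeometry,
                                stem: str = "section") -> Path:
    from .histology import write_section

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{stem}.tif"
    write_section(tif_path, image)
    dump_json(dataclasses.asdict(geometry), out_dir / f"{stem}_geometry.json")
    return tif_path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
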