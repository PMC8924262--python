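"""File interfaces.

Sweeps live in HDF5 with a documented layout::

    /sweeps/<id>/time       float64, s
    /sweeps/<id>/current    float64, pA
    /sweeps/<id>/stimulus   float64, µm or mmHg
    attrs: sampling_khz, holding_mV, stimulus_onset_index,
           stimulus_end_index, metadata (JSON blob incl. ground truth)

TIRF movies are multi-page 16-bit TIFF stacks; track tables (ground truth
or detected) are CSV with columns ``track_id, frame, x_um, y_um``; counts
and neurite tables are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .sweep import Sweep
from .tirf import Track

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_sweeps(path: str | Path, sweeps: dict[str, Sweep] | list[Sweep]) -> None:
    """Write sweeps to the HDF5 layout; list input gets ids "000", "001", ..."""
    if isinstance(sweeps, list):
        sweeps = {f"{k:03d}": s for k, s in enumerate(sweeps)}
    with h5py.File(path, "w") as f:
        root = f.create_group("sweeps")
        for sid, sweep in sweeps.items():
            g = root.create_group(str(sid))
            g.create_dataset("time", data=sweep.time)
            g.create_dataset("current", data=sweep.current)
            g.create_dataset("stimulus", data=sweep.stimulus)
            g.attrs["sampling_khz"] = sweep.sampling_rate
            g.attrs["holding_mV"] = sweep.holding_potential
            g.attrs["stimulus_onset_index"] = sweep.stimulus_onset_index
            g.attrs["stimulus_end_index"] = sweep.stimulus_end_index
            g.attrs["metadata"] = json.dumps(_jsonable(sweep.metadata))


def load_sweeps(path: str | Path) -> dict[str, Sweep]:
    """Read sweeps back from the HDF5 layout."""
    out: dict[str, Sweep] = {}
    with h5py.File(path, "r") as f:
        for sid, g in f["sweeps"].items():
            out[sid] = Sweep(
                time=g["time"][:],
                current=g["current"][:],
                stimulus=g["stimulus"][:],
                sampling_rate=float(g.attrs["sampling_khz"]),
                holding_potential=float(g.attrs["holding_mV"]),
                stimulus_onset_index=int(g.attrs["stimulus_onset_index"]),
                stimulus_end_index=int(g.attrs["stimulus_end_index"]),
                metadata=json.loads(g.attrs["metadata"]),
            )
    return out


def save_movie(path: str | Path, stack: np.ndarray) -> None:
    """Write a movie as a multi-page 16-bit TIFF (frames x H x W)."""
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.uint16), photometric="minisblack"
    )


def load_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Detected tracks as a long-format table (track_id, frame, x_um, y_um)."""
    rows = [
        (t.id, f, x, y)
        for t in tracks
        for f, x, y in zip(t.frames, t.x, t.y)
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def save_tracks(path: str | Path, tracks: list[Track] | pd.DataFrame) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else tracks_to_frame(tracks)
    df.to_csv(path, index=False)


def load_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns {missing}")
    return df
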