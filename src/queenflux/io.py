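"""Readers and writers for the pipeline's standard on-disk formats.

Traces travel as tidy CSV (one row per cell per frame); image stacks as
OME-TIFF with explicit axes; label masks as single-channel TIFF; ground truth
and reports as JSON.  All CSV output uses a fixed float format so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .traces import AggregationTrace, ChannelTraces, RatioTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_agg_csv",
    "read_agg_csv",
    "write_channels_csv",
    "read_channels_csv",
    "write_queen_stack",
    "read_queen_stack",
    "write_mask",
    "read_mask",
    "write_json",
]

_FLOAT_FMT = "%.9g"


def write_traces_csv(traces: list[RatioTrace], path) -> None:
    df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces_csv(path) -> list[RatioTrace]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        dt = float(np.diff(grp["time_min"].to_numpy()).mean()) if len(grp) > 1 else 1.0
        atp = grp["atp_mM"].to_numpy()
        out.append(
            RatioTrace(
                cell_id=str(cid),
                ratio=grp["ratio"].to_numpy(),
                frame_interval=dt,
                atp=None if np.all(np.isnan(atp)) else atp,
                corrected_frames=tuple(grp.loc[grp["corrected"], "frame"].astype(int)),
            )
        )
    return out


def write_agg_csv(traces: list[AggregationTrace], path) -> None:
    df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_agg_csv(path) -> list[AggregationTrace]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        dt = float(np.diff(grp["time_min"].to_numpy()).mean()) if len(grp) > 1 else 1.0
        out.append(
            AggregationTrace(
                cell_id=str(cid),
                mean_intensity=grp["reporter_mean"].to_numpy(),
                frame_interval=dt,
            )
        )
    return out


def write_channels_csv(channels: list[ChannelTraces], path) -> None:
    frames = []
    for ch in channels:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": ch.cell_id,
                    "frame": np.arange(ch.n_frames),
                    "time_min": ch.time,
                    "ex410": ch.ex410,
                    "ex490": ch.ex490,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_channels_csv(path) -> list[ChannelTraces]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        dt = float(np.diff(grp["time_min"].to_numpy()).mean()) if len(grp) > 1 else 1.0
        out.append(
            ChannelTraces(
                cell_id=str(cid),
                ex410=grp["ex410"].to_numpy(),
                ex490=grp["ex490"].to_numpy(),
                frame_interval=dt,
            )
        )
    return out


def write_queen_stack(stack: np.ndarray, path, as_uint16: bool = True) -> None:
    """Write a (T, C, Y, X) sensor stack as OME-TIFF (16-bit by default)."""
    arr = np.asarray(stack)
    if arr.ndim != 4:
        raise ValueError("queen stack must be (T, C, Y, X)")
    if as_uint16:
        arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, ome=True, metadata={"axes": "TCYX"})


def read_queen_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 4:
        raise ValueError(f"expected a (T, C, Y, X) stack in {path}, got shape {arr.shape}")
    return arr


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
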