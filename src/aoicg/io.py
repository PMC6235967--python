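"""Disk formats: multi-page TIFF stacks with CSV/YAML sidecars, tables, configs.

A stack on disk is ``<stem>.tif`` (frames as pages, float32) plus
``<stem>_frames.csv`` (frame index, time_s, valid) plus ``<stem>.yaml``
(channel, pixel scale, and any extra metadata).  Centroid tables are CSV with
``y_um, x_um`` columns and an optional modality tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .preprocess import FrameStack, Rect, RegisteredStack

__all__ = [
    "save_stack",
    "load_stack",
    "save_registered",
    "load_registered",
    "write_centroids",
    "read_centroids",
    "write_trace",
    "write_json",
]


def save_stack(path: str | Path, stack: FrameStack, **extra_meta) -> None:
    """Write a stack as multi-page TIFF + frame-table CSV + YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path.with_suffix(".tif"), stack.pixels.astype(np.float32))
    pd.DataFrame(
        {"frame": np.arange(stack.n_frames), "time_s": stack.times, "valid": stack.valid}
    ).to_csv(path.with_suffix("").parent / f"{path.stem}_frames.csv", index=False)
    meta = {"channel": stack.channel, "pixel_scale_um": float(stack.pixel_scale)}
    meta.update(extra_meta)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    pixels = tifffile.imread(path.with_suffix(".tif")).astype(float)
    frames = pd.read_csv(path.parent / f"{path.stem}_frames.csv")
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return FrameStack(
        pixels=pixels,
        channel=meta["channel"],
        times=frames["time_s"].to_numpy(),
        pixel_scale=meta["pixel_scale_um"],
        valid=frames["valid"].to_numpy(dtype=bool),
    )


def save_registered(path: str | Path, rs: RegisteredStack) -> None:
    roi = rs.roi
    save_stack(
        path,
        rs,
        reference_index=int(rs.reference_index),
        roi=[int(roi.y0), int(roi.y1), int(roi.x0), int(roi.x1)],
    )
    path = Path(path)
    pd.DataFrame(
        {
            "frame": np.arange(rs.n_frames),
            "dy_px": rs.shifts[:, 0],
            "dx_px": rs.shifts[:, 1],
            "valid": rs.valid,
        }
    ).to_csv(path.parent / f"{path.stem}_shifts.csv", index=False)


def load_registered(path: str | Path) -> RegisteredStack:
    path = Path(path)
    base = load_stack(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    shifts = pd.read_csv(path.parent / f"{path.stem}_shifts.csv")
    return RegisteredStack(
        pixels=base.pixels,
        channel=base.channel,
        times=base.times,
        pixel_scale=base.pixel_scale,
        valid=base.valid,
        shifts=shifts[["dy_px", "dx_px"]].to_numpy(),
        reference_index=meta["reference_index"],
        roi=Rect(*meta["roi"]),
    )


def write_centroids(path: str | Path, points_um: np.ndarray, modality: str = "") -> None:
    df = pd.DataFrame(points_um, columns=["y_um", "x_um"])
    if modality:
        df["modality"] = modality
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_centroids(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["y_um", "x_um"]].to_numpy(dtype=float)


def write_trace(path: str | Path, times, values, valid, factors=None) -> None:
    df = pd.DataFrame({"time_s": times, "value": values, "valid": valid})
    if factors is not None:
        df["factor"] = factors
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
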