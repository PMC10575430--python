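"""Readers and writers for stacks, traces and detection boxes.

Stacks travel as 8-bit grayscale multi-page TIFF with a JSON sidecar of
focal z positions (``<stem>.z.json``), or as a directory of per-plane
TIFF/PNG files plus the same sidecar.  Resistance traces are CSV with the
header ``time_s,resistance_mohm``; detection boxes are JSON lists or CSV
with columns ``x0,y0,x1,y1,z_um,score``.  Round trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .neuronfuse import Box2D, Box3D
from .contactflow import ResistanceTrace
from .stacks import ZStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "read_boxes",
    "write_boxes",
    "provenance_block",
]

_PLANE_SUFFIXES = (".tif", ".tiff", ".png")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".z.json") if path.is_dir() else Path(
        str(path).rsplit(".", 1)[0] + ".z.json"
    )


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a multi-page 8-bit TIFF plus its z sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.uint8))
    _sidecar_path(path).write_text(json.dumps({"z_um": stack.z_um.tolist()}))


def read_stack(path: str | Path) -> ZStack:
    """Read a stack from a multi-page TIFF or a directory of planes.

    Both forms need the ``*.z.json`` sidecar listing the focal position of
    every plane in order.
    """
    path = Path(path)
    if path.is_dir():
        planes = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _PLANE_SUFFIXES
        )
        if not planes:
            raise FormatError(f"no image planes found in {path}")
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(p)) for p in planes]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent plane shapes in {path}: {shapes}")
        frames = np.stack(frames)
        sidecar = path / "z.json"
    else:
        if not path.exists():
            raise FormatError(f"no such stack file: {path}")
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing z-position sidecar: expected {sidecar}")
    z_um = json.loads(sidecar.read_text())["z_um"]
    return ZStack(frames=frames, z_um=np.asarray(z_um, dtype=float))


def write_trace(trace: ResistanceTrace, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": trace.times, "resistance_mohm": trace.resistance}
    ).to_csv(path, index=False)


def read_trace(path: str | Path) -> ResistanceTrace:
    """Read a ``time_s,resistance_mohm`` CSV into a ResistanceTrace."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"unreadable trace CSV {path}: {exc}") from exc
    if list(df.columns[:2]) != ["time_s", "resistance_mohm"]:
        raise FormatError(
            f"{path}: expected header 'time_s,resistance_mohm', got {list(df.columns)}"
        )
    bad = df[df[["time_s", "resistance_mohm"]].isna().any(axis=1)]
    if len(bad):
        raise FormatError(f"{path}: malformed row at line {bad.index[0] + 2}")
    try:
        return ResistanceTrace(
            times=df["time_s"].to_numpy(float),
            resistance=df["resistance_mohm"].to_numpy(float),
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_boxes(boxes: list[Box2D | Box3D], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for b in boxes:
        if isinstance(b, Box3D):
            records.append(
                {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1,
                 "z_min_um": b.z_min, "z_max_um": b.z_max,
                 "member_count": b.member_count, "optimal_z_um": b.optimal_z}
            )
        else:
            records.append(
                {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1,
                 "z_um": b.z, "score": b.score}
            )
    path.write_text(json.dumps(records, indent=1))


def read_boxes(path: str | Path) -> list[Box2D]:
    """Read per-plane detections from a JSON list or a CSV table."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        needed = {"x0", "y0", "x1", "y1", "z_um"}
        if not needed.issubset(df.columns):
            raise FormatError(f"{path}: CSV needs columns {sorted(needed)}")
        records = df.to_dict("records")
    else:
        try:
            records = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    boxes = []
    for i, r in enumerate(records):
        try:
            boxes.append(
                Box2D(x0=float(r["x0"]), y0=float(r["y0"]), x1=float(r["x1"]),
                      y1=float(r["y1"]), z=float(r["z_um"]),
                      score=float(r.get("score", 1.0)))
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"{path}: bad box record {i}: {exc}") from exc
    return boxes


def provenance_block(seed: int | None, config: dict | None = None) -> dict:
    """Machine-readable provenance attached to every CLI output."""
    from . import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "patchcontact",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
    }
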