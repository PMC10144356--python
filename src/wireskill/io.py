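"""Readers and writers for the artifact's file formats.

Frames travel as zero-padded PNG sequences or multi-page TIFFs with an
optional JSON sidecar carrying the capture rate; traces and tables are plain
CSV; reports and ground truth are JSON.  Pixel coordinates are 0-based with
origin top-left (x = column, y = row), times are seconds, forces newtons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .metrics import ForceTrace
from .tracking import FrameSequence, TipTrajectory

__all__ = [
    "FormatError",
    "TrialRecord",
    "read_frames",
    "write_frames",
    "read_force_csv",
    "write_force_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_metrics_csv",
    "load_manifest",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class TrialRecord:
    """One manifest entry: where a trial's streams live on disk."""

    trial_id: str
    group: str
    surgeon_id: str
    task: str
    repetition: int
    frames_path: str
    force_path: str
    speed_path: str | None = None
    seed_hint: tuple | None = None
    truth_path: str | None = None


def _sidecar_fps(path: Path, default: float) -> float:
    for candidate in (path / "meta.json" if path.is_dir() else path.with_suffix(".json"),):
        if candidate.exists():
            with open(candidate) as fh:
                return float(json.load(fh).get("fps", default))
    return default


def read_frames(path, fps: float = 20.0) -> FrameSequence:
    """Read a PNG-sequence directory or a multi-page TIFF.

    PNG frames are ordered by (zero-padded) filename; the capture rate comes
    from a JSON sidecar (``meta.json`` in the directory, or ``<stem>.json``
    next to a TIFF) and defaults to 20 fps.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FormatError(f"no PNG frames in {path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise FormatError(f"{path}: expected grayscale pages, got shape {stack.shape}")
    else:
        raise FormatError(f"unsupported frame container: {path}")
    if stack.size == 0:
        raise FormatError(f"{path}: empty frame stack")
    if stack.dtype != np.uint8:
        stack = np.clip(stack, 0, 255).astype(np.uint8)
    return FrameSequence(frames=stack, fps=_sidecar_fps(path, fps))


def write_frames(frames: FrameSequence, path, fmt: str = "tiff") -> Path:
    """Write frames as a multi-page TIFF (``fmt="tiff"``) or a zero-padded
    PNG sequence directory (``fmt="png"``), plus the fps sidecar."""
    path = Path(path)
    if fmt == "tiff":
        path = path if path.suffix else path.with_suffix(".tif")
        tifffile.imwrite(path, frames.frames)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"fps": frames.fps}, fh)
    elif fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames.frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
        with open(path / "meta.json", "w") as fh:
            json.dump({"fps": frames.fps}, fh)
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    return path


_FORCE_ALIASES = {"t": "t", "time": "t", "t_s": "t",
                  "fx": "fx", "fy": "fy", "fz": "fz",
                  "fx_n": "fx", "fy_n": "fy", "fz_n": "fz"}


def read_force_csv(path) -> ForceTrace:
    """Parse a force CSV with header t, Fx, Fy, Fz (torque columns ignored).

    Non-numeric cells and non-monotone time raise :class:`FormatError` naming
    the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _FORCE_ALIASES:
            rename[col] = _FORCE_ALIASES[key]
    df = df.rename(columns=rename)
    missing = {"t", "fx", "fy", "fz"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing force columns {sorted(missing)}")
    data = {}
    for col in ("t", "fx", "fy", "fz"):
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna() & df[col].notna()]
        if series.isna().any():
            row = int((series.isna()).idxmax()) + 1
            raise FormatError(f"{path}: non-numeric {col!r} value at data row {row}")
        data[col] = series.to_numpy(dtype=float)
    dt = np.diff(data["t"])
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise FormatError(f"{path}: time not increasing at data row {row}")
    return ForceTrace(t=data["t"], fx=data["fx"], fy=data["fy"], fz=data["fz"])


def write_force_csv(force: ForceTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t": force.t, "Fx": force.fx, "Fy": force.fy, "Fz": force.fz}).to_csv(
        path, index=False
    )
    return path


def write_trajectory_csv(observations, fps: float, path) -> Path:
    """Trajectory CSV with header (frame, t_s, x_px, y_px, valid, source)."""
    rows = [
        {
            "frame": o.frame_index,
            "t_s": o.frame_index / fps,
            "x_px": o.tip[0],
            "y_px": o.tip[1],
            "valid": int(o.valid),
            "source": o.tip_source,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_trajectory_csv(path) -> TipTrajectory:
    df = pd.read_csv(path)
    for col in ("t_s", "x_px", "y_px"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return TipTrajectory(t=df["t_s"].to_numpy(), x=df["x_px"].to_numpy(),
                         y=df["y_px"].to_numpy())


def write_metrics_csv(metric_table: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """One CSV row per trial plus a JSON provenance block alongside."""
    path = Path(path)
    metric_table.to_csv(path, index=False)
    if provenance is not None:
        with open(path.with_suffix(".provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
    return path


def load_manifest(path) -> tuple:
    """Load a cohort manifest: ``{"fps": .., "trials": [...]}``.

    Referenced frame/force files must exist.  Returns (records, fps).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    base = path.parent
    records = []
    seen = set()
    for entry in doc["trials"]:
        rec = TrialRecord(
            trial_id=entry["trial_id"],
            group=entry["group"],
            surgeon_id=entry.get("surgeon_id", ""),
            task=entry["task"],
            repetition=int(entry.get("repetition", 1)),
            frames_path=str(base / entry["frames"]),
            force_path=str(base / entry["force"]),
            speed_path=str(base / entry["speed"]) if entry.get("speed") else None,
            seed_hint=tuple(entry["seed_hint"]) if entry.get("seed_hint") else None,
            truth_path=str(base / entry["truth"]) if entry.get("truth") else None,
        )
        if rec.trial_id in seen:
            raise FormatError(f"duplicate trial_id {rec.trial_id!r} in manifest")
        seen.add(rec.trial_id)
        for p in (rec.frames_path, rec.force_path):
            if not Path(p).exists():
                raise FormatError(f"{rec.trial_id}: missing file {p}")
        records.append(rec)
    return records, float(doc.get("fps", 20.0))
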