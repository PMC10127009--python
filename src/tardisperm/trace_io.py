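"""Reading and writing midline traces, mid-piece tracks and run configs.

File formats are plain delimited text (comma-separated, UTF-8, header row),
the portable equivalent of the point tables exchanged by tracking software:

* trace:  ``frame_index, time_s, part, arclength_um, x_um, y_um`` — one row
  per midline point, parts ``head`` and ``tail``, points ordered from the
  base (mid-piece junction) outward by ``arclength_um``;
* track:  ``frame_index, time_s, x_um, y_um`` — one row per frame;
* config: YAML or JSON mapping of :class:`RunConfig` fields.

All coordinates are micrometres and times seconds; floats are written with
10 significant digits, so read(write(x)) is the identity within float
round-trip precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_sperm import GroundTruth, MidlineTrace, MidpieceTrack

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_track",
    "write_track",
    "load_config",
    "save_config",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger("tardisperm.trace_io")

TRACE_COLUMNS = ["frame_index", "time_s", "part", "arclength_um", "x_um", "y_um"]
TRACK_COLUMNS = ["frame_index", "time_s", "x_um", "y_um"]
FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Analysis-run parameters (defaults follow the study conditions)."""

    species_label: str = "Paramacrobiotus"
    station_spacing: float = 1.0
    window_frames: int = 10
    beat_station: float = 5.0
    alpha: float = 0.01
    turn_threshold: float = 90.0
    fps: float = 150.0
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beat_station <= 0:
            raise ValueError("beat_station must be > 0")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**known)
    logger.info("loaded config from %s: %s", path, asdict(cfg))
    return cfg


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8")
    return path


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite coordinates; refusing to write")


def write_trace(trace: MidlineTrace, path) -> Path:
    """Write a midline trace as CSV (one row per point)."""
    rows = []
    for f in range(trace.n_frames):
        t = trace.times[f]
        for part in ("head", "tail"):
            pts = np.asarray(trace.part(part)[f], dtype=float)
            _check_finite(pts, f"frame {f} part {part}")
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            rows.append(
                pd.DataFrame(
                    {
                        "frame_index": f,
                        "time_s": t,
                        "part": part,
                        "arclength_um": arc,
                        "x_um": pts[:, 0],
                        "y_um": pts[:, 1],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    logger.info("wrote trace: %d frames, %d rows -> %s", trace.n_frames, len(df), path)
    return path


def read_trace(path) -> MidlineTrace:
    """Read a midline trace written by :func:`write_trace`.

    Rows may appear in any order; they are sorted by (frame, part,
    arclength).  Malformed rows and schema violations raise ``ValueError``
    naming the offending record.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no frames")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[TRACE_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    unknown_parts = set(df["part"].unique()) - {"head", "tail"}
    if unknown_parts:
        raise ValueError(f"{path}: unknown part labels {sorted(unknown_parts)}")
    if df.duplicated(["frame_index", "part", "arclength_um"]).any():
        dup = df[df.duplicated(["frame_index", "part", "arclength_um"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (frame, part, arclength) record: "
            f"frame {dup.frame_index}, {dup.part}, {dup.arclength_um}"
        )
    df = df.sort_values(["frame_index", "part", "arclength_um"], kind="mergesort")
    frame_times = df.groupby("frame_index")["time_s"].agg(["min", "max"])
    if not np.allclose(frame_times["min"], frame_times["max"], rtol=0, atol=1e-9):
        raise ValueError(f"{path}: inconsistent time stamps within a frame")
    times = frame_times["min"].to_numpy()
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: non-monotone frame times")
    fps = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    head, tail = [], []
    for _, frame_df in df.groupby("frame_index", sort=True):
        for part, dest in (("head", head), ("tail", tail)):
            pts = frame_df[frame_df["part"] == part][["x_um", "y_um"]].to_numpy(float)
            dest.append(pts)
    logger.info("read trace: %d frames (fps=%.6g) <- %s", len(times), fps, path)
    return MidlineTrace(times=times, head=head, tail=tail, fps=fps)


def write_track(track: MidpieceTrack, path) -> Path:
    """Write a mid-piece track as CSV (one row per frame)."""
    pos = np.asarray(track.positions, dtype=float)
    _check_finite(pos, "track")
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(pos)),
            "time_s": track.times,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_track(path) -> MidpieceTrack:
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no frames")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[TRACK_COLUMNS].isna().any(axis=1).any():
        raise ValueError(f"{path}: malformed rows (NaN fields)")
    df = df.sort_values("frame_index", kind="mergesort")
    times = df["time_s"].to_numpy(float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: non-monotone frame times")
    fps = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    return MidpieceTrack(
        positions=df[["x_um", "y_um"]].to_numpy(float), fps=fps, times=times
    )


def write_truth(truth: GroundTruth, path) -> Path:
    """Write a generator ground-truth sidecar (JSON)."""
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True),
                    encoding="utf-8")
    return path


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
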