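"""Arc-length station resampling, waveform normalization, and curvature.

The analysis samples each filament (head or tail) at fixed arc-length
*stations* — 1 um, 2 um, ... from the base (junction with the mid-piece) —
in every video frame.  At each interior station the signed curvature is
estimated from the turn angle between consecutive unit secants divided by
the station spacing; this three-point estimator is exact in the circle
limit (the turn angle between chords of equal arcs equals the subtended
arc angle).  Sign convention: counter-clockwise turning in the (x, y)
plane is positive, with mathematical y (up), so reflection negates the
sign and rigid motions leave it unchanged.

Station 0 (the base itself) is kept as a reference point but is not a
statistic site; the tip station only admits a one-sided estimate and is
flagged as a boundary, and boundary stations are excluded from curvature
series used in significance testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_sperm import MidlineTrace, SpermMorphology

__all__ = [
    "StationFrame",
    "StationCurvatureSeries",
    "NormalizedWaveform",
    "resample_stations",
    "normalize_waveform",
    "curvature_profile",
    "collect_series",
    "split_head_regions",
]

logger = logging.getLogger("tardisperm.waveform")


@dataclass
class StationFrame:
    """One frame of one part resampled onto the uniform station grid.

    ``stations[k]`` is the arc length (um) of station k+1 from the base;
    ``points[k]`` the interpolated coordinates there.  ``base_point`` is
    station 0.  ``boundary`` flags stations whose curvature estimate is
    one-sided (the tip).
    """

    part: str
    spacing: float
    base_point: np.ndarray  # (2,)
    stations: np.ndarray  # (N,) arc lengths: spacing, 2*spacing, ...
    points: np.ndarray  # (N, 2)
    tangent_angle: np.ndarray  # (N,) radians
    curvature: np.ndarray  # (N,) 1/um, signed
    boundary: np.ndarray  # (N,) bool

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def all_points(self) -> np.ndarray:
        """Base point followed by the station points, shape (N+1, 2)."""
        return np.vstack([self.base_point, self.points])


@dataclass
class NormalizedWaveform:
    """Station points in the body frame: base at the origin, base tangent
    along +x.  Optionally rescaled by total filament length."""

    part: str
    spacing: float
    points: np.ndarray  # (N, 2), station points (base excluded, at origin)
    length_rescaled: bool = False


@dataclass
class StationCurvatureSeries:
    """Signed curvature samples: stations x frames within one window."""

    part: str
    stations: np.ndarray  # (S,) um
    samples: np.ndarray  # (S, W)
    window_frames: int
    condition_label: str = ""

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def restrict(self, stations: np.ndarray) -> "StationCurvatureSeries":
        """Subset of the series at the given stations (order preserved)."""
        idx = np.searchsorted(self.stations, stations)
        if not np.allclose(self.stations[idx], stations):
            raise ValueError("requested stations not present in series")
        return StationCurvatureSeries(
            part=self.part,
            stations=self.stations[idx],
            samples=self.samples[idx],
            window_frames=self.window_frames,
            condition_label=self.condition_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        s, f = np.meshgrid(self.stations, np.arange(self.samples.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "part": self.part,
                "station_um": s.ravel(),
                "frame_index": f.ravel(),
                "curvature_per_um": self.samples.ravel(),
            }
        )


def _signed_turn(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle (rad) from vectors u to v, CCW positive; rowwise."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    return np.arctan2(cross, dot)


def _curvature_from_points(all_points: np.ndarray, spacing: float):
    """Turn-angle curvature at stations 1..N given points at 0..N."""
    seg = np.diff(all_points, axis=0)  # (N, 2): secant into each station
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seglen == 0):
        raise ValueError("coincident station points: degenerate polyline")
    turns = _signed_turn(seg[:-1], seg[1:])  # (N-1,) turn at stations 1..N-1
    n = len(seg)
    curvature = np.empty(n)
    curvature[: n - 1] = turns / spacing
    # tip: one-sided estimate (repeat the last interior turn)
    curvature[n - 1] = curvature[n - 2] if n >= 2 else 0.0
    boundary = np.zeros(n, dtype=bool)
    boundary[n - 1] = True
    tangent = np.arctan2(seg[:, 1], seg[:, 0])
    return curvature, boundary, tangent


def resample_stations(
    frame_points: np.ndarray, spacing: float = 1.0, part: str = "tail"
) -> StationFrame:
    """Resample a midline polyline onto the uniform arc-length station grid.

    Linear interpolation along the cumulative chord length; stations at
    ``spacing, 2*spacing, ...`` up to the largest multiple not exceeding
    the total polyline length.

    Raises
    ------
    ValueError
        If the polyline is degenerate (repeated points) or shorter than
        two station spacings.
    """
    pts = np.asarray(frame_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("frame_points must be an (n, 2) array with n >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("degenerate polyline: repeated consecutive points")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < 2 * spacing:
        raise ValueError(
            f"polyline length {total:.3f} um too short for spacing {spacing} um "
            "(need at least two stations)"
        )
    n_stations = int(np.floor(total / spacing + 1e-9))
    stations = spacing * np.arange(1, n_stations + 1)
    x = np.interp(stations, cum, pts[:, 0])
    y = np.interp(stations, cum, pts[:, 1])
    points = np.column_stack([x, y])
    all_points = np.vstack([pts[0], points])
    curvature, boundary, tangent = _curvature_from_points(all_points, spacing)
    return StationFrame(
        part=part,
        spacing=spacing,
        base_point=pts[0].copy(),
        stations=stations,
        points=points,
        tangent_angle=tangent,
        curvature=curvature,
        boundary=boundary,
    )


def normalize_waveform(
    station_frame: StationFrame, rescale_by_length: bool = False
) -> NormalizedWaveform:
    """Rigidly register a station frame into the body frame.

    Translate the base to the origin and rotate so the base tangent (the
    secant from station 0 to station 1) lies along +x.  With
    ``rescale_by_length`` the coordinates are additionally divided by the
    total filament length (dimensionless waveform).
    """
    if station_frame.n_stations < 3:
        raise ValueError("need at least 3 stations to normalize a waveform")
    rel = station_frame.points - station_frame.base_point
    ang = np.arctan2(rel[0, 1], rel[0, 0])
    c, s = np.cos(-ang), np.sin(-ang)
    rot = np.array([[c, -s], [s, c]])
    pts = rel @ rot.T
    if rescale_by_length:
        pts = pts / station_frame.stations[-1]
    return NormalizedWaveform(
        part=station_frame.part,
        spacing=station_frame.spacing,
        points=pts,
        length_rescaled=rescale_by_length,
    )


def curvature_profile(station_frame: StationFrame) -> np.ndarray:
    """Signed curvature (1/um) at each station of a frame.

    Recomputed from the station points (turn angle between consecutive
    secants over the spacing); identical to ``station_frame.curvature``.
    """
    if station_frame.n_stations < 3:
        raise ValueError("need at least 3 stations for a curvature profile")
    curvature, _, _ = _curvature_from_points(
        station_frame.all_points(), station_frame.spacing
    )
    return curvature


def collect_series(
    trace: MidlineTrace,
    part: str,
    start_frame: int = 0,
    window_frames: int = 10,
    spacing: float = 1.0,
    condition_label: str = "",
    include_boundary: bool = False,
) -> StationCurvatureSeries:
    """Per-station signed curvature across a window of sequential frames.

    Stations are restricted to those valid in **every** frame of the
    window (filament chord length fluctuates under noise) and, by default,
    to interior stations (boundary one-sided estimates are biased).
    """
    if start_frame < 0 or start_frame + window_frames > trace.n_frames:
        raise ValueError(
            f"window [{start_frame}, {start_frame + window_frames}) exceeds "
            f"trace with {trace.n_frames} frames"
        )
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    frames = [
        resample_stations(trace.part(part)[f], spacing, part=part)
        for f in range(start_frame, start_frame + window_frames)
    ]
    n_common = min(sf.n_stations for sf in frames)
    if not include_boundary:
        n_common -= 1  # drop the tip (one-sided estimate)
    if n_common < 1:
        raise ValueError("no common interior stations across the window")
    stations = frames[0].stations[:n_common]
    samples = np.column_stack([sf.curvature[:n_common] for sf in frames])
    return StationCurvatureSeries(
        part=part,
        stations=stations,
        samples=samples,
        window_frames=window_frames,
        condition_label=condition_label,
    )


def split_head_regions(
    series: StationCurvatureSeries, morphology: SpermMorphology
):
    """Split a head curvature series into nucleus and acrosome series.

    Stations with arc length <= ``nucleus_length`` belong to the coiled
    nucleus; the remainder to the acrosome.
    """
    if series.part != "head":
        raise ValueError(f"split_head_regions requires a head series, got {series.part!r}")
    mask = series.stations <= morphology.nucleus_length + 1e-9
    nucleus = StationCurvatureSeries(
        part="head",
        stations=series.stations[mask],
        samples=series.samples[mask],
        window_frames=series.window_frames,
        condition_label=(series.condition_label + ":nucleus").lstrip(":"),
    )
    acrosome = StationCurvatureSeries(
        part="head",
        stations=series.stations[~mask],
        samples=series.samples[~mask],
        window_frames=series.window_frames,
        condition_label=(series.condition_label + ":acrosome").lstrip(":"),
    )
    if acrosome.n_stations == 0:
        logger.warning(
            "head series ends at %.1f um, inside the nucleus (boundary %.1f um); "
            "acrosome station set is empty",
            series.stations[-1] if series.n_stations else float("nan"),
            morphology.nucleus_length,
        )
    return nucleus, acrosome
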