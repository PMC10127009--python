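"""Synthetic tardigrade-spermatozoon kinematics with known ground truth.

Tardigrade spermatozoa carry an elongated head (acrosome + coiled nucleus)
and a tail, joined at a mid-piece; the cell swims mid-piece first.  This
module generates planar midline traces of such a cell under a prescribed
kinematic model so that every downstream estimate (curvilinear velocity,
beat frequency, per-station curvature variance) can be checked against a
known truth:

* **Beat** — a travelling signed-curvature wave along each filament,
  ``kappa(s, t) = A(s) * sin(2*pi*s/wavelength - 2*pi*frequency*t + phase0)``,
  with arc length ``s`` measured from the mid-piece junction.  The head is
  stiffer than the tail: its wave amplitude is ``head_amplitude_factor``
  times the tail amplitude.
* **Swimming** — the mid-piece is carried along a path of constant
  curvilinear speed whose heading changes at a constant rate (zero for a
  straight swimmer); body orientation follows the path heading.  Swimming
  is imposed, not emergent: no hydrodynamics is modelled because only
  kinematics is measured.
* **Sampling** — frames at ``fps`` (default 150) spanning exactly
  ``duration`` seconds (endpoint included), with optional i.i.d. isotropic
  coordinate noise.

Filament shape is obtained by integrating the curvature field to a tangent
angle and the tangent to coordinates (cumulative trapezoid at 0.1 um
internal resolution), then placing the body rigidly on the swimming path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SpermMorphology",
    "BeatParameters",
    "SwimParameters",
    "GroundTruth",
    "MidlineTrace",
    "MidpieceTrack",
    "simulate_sperm",
    "make_species_presets",
    "species_preset",
    "DEFAULT_PHASE0",
    "INTERNAL_RESOLUTION_UM",
]

#: Internal arc-length integration step (um); well below the 1-um station
#: grid so that station resampling is not limited by generator resolution.
INTERNAL_RESOLUTION_UM = 0.1

#: Default initial wave phase.  With the default 20-um wavelength this puts
#: the first crest seen at the 5-um tail station a third of a beat cycle
#: into the record, so crest counts are never truncated at the record
#: endpoints and the exactly-3-samples-per-cycle case (50 Hz at 150 fps)
#: has no tied samples.
DEFAULT_PHASE0 = 2.0 * math.pi / 3.0


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter {name!r}: {msg}")


@dataclass(frozen=True)
class SpermMorphology:
    """Filament lengths of one species, in micrometres.

    ``nucleus_length`` is the arc-length boundary between the coiled
    nucleus (proximal, 0..nucleus_length from the head base) and the
    acrosome (the remainder of the head).
    """

    species_label: str
    head_length: float
    tail_length: float
    nucleus_length: float
    station_spacing: float = 1.0

    def __post_init__(self) -> None:
        _require(self.head_length > 0, "head_length", "must be > 0")
        _require(self.tail_length > 0, "tail_length", "must be > 0")
        _require(
            0 < self.nucleus_length < self.head_length,
            "nucleus_length",
            "must satisfy 0 < nucleus_length < head_length",
        )
        _require(self.station_spacing > 0, "station_spacing", "must be > 0")


@dataclass(frozen=True)
class BeatParameters:
    """Travelling curvature-wave parameters.

    ``tail_amplitude`` is the peak signed curvature (1/um) of the wave on
    the tail; the head carries ``head_amplitude_factor`` times that
    amplitude (heads tremble less than tails).  ``amplitude_envelope``
    selects a constant amplitude along each filament or a linear ramp from
    zero at the base to the full amplitude at the tip.  ``noise_sd`` is the
    standard deviation (um) of isotropic Gaussian noise added to every
    exported coordinate.
    """

    frequency: float
    wavelength: float = 20.0
    tail_amplitude: float = 0.15
    head_amplitude_factor: float = 0.3
    amplitude_envelope: str = "constant"
    phase0: float = DEFAULT_PHASE0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(self.frequency >= 0, "frequency", "must be >= 0")
        _require(self.wavelength > 0, "wavelength", "must be > 0")
        _require(self.tail_amplitude >= 0, "tail_amplitude", "must be >= 0")
        _require(
            0 <= self.head_amplitude_factor <= 1,
            "head_amplitude_factor",
            "must lie in [0, 1]",
        )
        _require(
            self.amplitude_envelope in ("constant", "linear_ramp"),
            "amplitude_envelope",
            "must be 'constant' or 'linear_ramp'",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class SwimParameters:
    """Rigid-body swimming parameters.

    ``speed`` is the curvilinear speed (um/s) of the mid-piece along its
    path; ``heading_rate`` (deg/s) is the constant rate of heading change
    (0 = straight swimmer).  Frames are sampled at ``fps`` over exactly
    ``duration`` seconds, endpoints included.
    """

    speed: float
    heading_rate: float = 0.0
    duration: float = 1.0
    fps: float = 150.0
    seed: int = 0
    heading0: float = 0.0

    def __post_init__(self) -> None:
        _require(self.speed >= 0, "speed", "must be >= 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.fps > 0, "fps", "must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Complete generator parameter set; the recovery tests' bookkeeping."""

    morphology: SpermMorphology
    beat: BeatParameters
    swim: SwimParameters

    def __post_init__(self) -> None:
        # Nyquist: the frame rate must resolve the beat.
        _require(
            self.swim.fps > 2.0 * self.beat.frequency,
            "fps",
            f"fps={self.swim.fps} must exceed twice the beat frequency "
            f"({self.beat.frequency} Hz) to avoid aliasing",
        )

    def to_dict(self) -> dict:
        return {
            "morphology": vars(self.morphology).copy(),
            "beat": vars(self.beat).copy(),
            "swim": vars(self.swim).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            morphology=SpermMorphology(**d["morphology"]),
            beat=BeatParameters(**d["beat"]),
            swim=SwimParameters(**d["swim"]),
        )


@dataclass
class MidlineTrace:
    """Per-frame midline polylines of one spermatozoon.

    ``head[i]`` and ``tail[i]`` are (n_points, 2) arrays in um, ordered
    from the mid-piece junction (base) outward to the tip of the part.
    """

    times: np.ndarray
    head: list
    tail: list
    fps: float

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def part(self, name: str) -> list:
        if name == "head":
            return self.head
        if name == "tail":
            return self.tail
        raise ValueError(f"unknown part {name!r}; expected 'head' or 'tail'")


@dataclass
class MidpieceTrack:
    """Mid-piece positions (um) over time; source of VCL and motion labels."""

    positions: np.ndarray  # (n_frames, 2)
    fps: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times is None:
            self.times = np.arange(len(self.positions)) / self.fps

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def _arc_grid(length: float, resolution: float) -> np.ndarray:
    """Uniform arc-length grid from 0 to `length` with step <= resolution."""
    n_seg = max(1, int(math.ceil(length / resolution - 1e-12)))
    return np.linspace(0.0, length, n_seg + 1)


def _amplitude(
    s: np.ndarray, length: float, peak: float, envelope: str
) -> np.ndarray:
    if envelope == "constant":
        return np.full_like(s, peak)
    # linear_ramp: zero at the base, full amplitude at the tip
    return peak * s / length


def _body_filament(
    s: np.ndarray,
    amplitude: np.ndarray,
    wavelength: float,
    frequency: float,
    phase0: float,
    times: np.ndarray,
    base_angle: float,
) -> np.ndarray:
    """Integrate the curvature field to body-frame points, shape (F, n_s, 2)."""
    phase = (
        2.0 * math.pi * s[None, :] / wavelength
        - 2.0 * math.pi * frequency * times[:, None]
        + phase0
    )
    kappa = amplitude[None, :] * np.sin(phase)  # (F, n_s)
    theta = base_angle + cumulative_trapezoid(kappa, s, axis=1, initial=0.0)
    x = cumulative_trapezoid(np.cos(theta), s, axis=1, initial=0.0)
    y = cumulative_trapezoid(np.sin(theta), s, axis=1, initial=0.0)
    return np.stack([x, y], axis=-1)


def _swim_path(swim: SwimParameters, times: np.ndarray):
    """Mid-piece positions (F, 2) and headings (F,) along the swimming path."""
    psi0 = math.radians(swim.heading0)
    omega = math.radians(swim.heading_rate)
    psi = psi0 + omega * times
    if abs(omega) < 1e-12:
        pos = swim.speed * times[:, None] * np.array([math.cos(psi0), math.sin(psi0)])
    else:
        # constant-speed circular arc, integrated analytically
        r = swim.speed / omega
        pos = np.stack(
            [r * (np.sin(psi) - math.sin(psi0)), -r * (np.cos(psi) - math.cos(psi0))],
            axis=-1,
        )
    return pos, psi


def simulate_sperm(truth: GroundTruth, export_spacing: float = INTERNAL_RESOLUTION_UM):
    """Simulate one swimming spermatozoon.

    Returns ``(MidlineTrace, MidpieceTrack)`` with
    ``round(duration * fps) + 1`` frames at times ``0, 1/fps, ..., duration``
    so that the elapsed time of the record equals ``duration`` exactly.

    Parameters
    ----------
    truth:
        Full generator parameter set (morphology, beat, swimming).
    export_spacing:
        Arc-length spacing (um) of the exported polylines; must be >=
        the internal 0.1-um integration resolution.
    """
    morph, beat, swim = truth.morphology, truth.beat, truth.swim
    _require(
        export_spacing >= INTERNAL_RESOLUTION_UM - 1e-12,
        "export_spacing",
        f"must be >= internal resolution {INTERNAL_RESOLUTION_UM}",
    )

    n_frames = int(round(swim.duration * swim.fps)) + 1
    times = np.arange(n_frames) / swim.fps

    parts = {}
    for part, length, base_angle, factor in (
        ("head", morph.head_length, 0.0, beat.head_amplitude_factor),
        ("tail", morph.tail_length, math.pi, 1.0),
    ):
        s = _arc_grid(length, INTERNAL_RESOLUTION_UM)
        amp = _amplitude(s, length, factor * beat.tail_amplitude, beat.amplitude_envelope)
        body = _body_filament(
            s, amp, beat.wavelength, beat.frequency, beat.phase0, times, base_angle
        )
        if export_spacing > INTERNAL_RESOLUTION_UM + 1e-12:
            s_out = _arc_grid(length, export_spacing)
            idx = np.searchsorted(s, s_out)
            idx = np.clip(idx, 0, len(s) - 1)
            body = body[:, idx, :]
        parts[part] = body

    base_pos, psi = _swim_path(swim, times)
    cosp, sinp = np.cos(psi), np.sin(psi)
    rot = np.empty((n_frames, 2, 2))
    rot[:, 0, 0] = cosp
    rot[:, 0, 1] = -sinp
    rot[:, 1, 0] = sinp
    rot[:, 1, 1] = cosp

    rng = np.random.default_rng(swim.seed)
    placed = {}
    for part in ("head", "tail"):
        pts = np.einsum("fij,fsj->fsi", rot, parts[part]) + base_pos[:, None, :]
        if beat.noise_sd > 0:
            pts = pts + rng.normal(0.0, beat.noise_sd, size=pts.shape)
        placed[part] = pts

    track_pos = base_pos.copy()
    if beat.noise_sd > 0:
        track_pos = track_pos + rng.normal(0.0, beat.noise_sd, size=track_pos.shape)

    trace = MidlineTrace(
        times=times,
        head=[placed["head"][f] for f in range(n_frames)],
        tail=[placed["tail"][f] for f in range(n_frames)],
        fps=swim.fps,
    )
    track = MidpieceTrack(positions=track_pos, fps=swim.fps, times=times)
    return trace, track


# Default morphologies.  Nucleus boundaries (21 and 11 um from the head
# base) follow the published morphometry of the two species; head/tail
# lengths are set so the interior 1-um station counts match the reported
# per-position comparison totals (59 head / 31 tail stations for
# Paramacrobiotus sp., whose head positions extend past 48 um; 13 / 21 for
# M. shonaicus).
_PRESETS = {
    "Paramacrobiotus": SpermMorphology(
        species_label="Paramacrobiotus sp.",
        head_length=60.5,
        tail_length=32.5,
        nucleus_length=21.0,
    ),
    "M. shonaicus": SpermMorphology(
        species_label="Macrobiotus shonaicus",
        head_length=14.5,
        tail_length=22.5,
        nucleus_length=11.0,
    ),
}


def make_species_presets() -> dict:
    """Mapping of species label to its default :class:`SpermMorphology`."""
    return dict(_PRESETS)


def species_preset(label: str) -> SpermMorphology:
    """Look up a species morphology preset by label."""
    try:
        return _PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown species {label!r}; available presets: "
            f"{sorted(_PRESETS)}"
        ) from None


def with_seed(truth: GroundTruth, seed: int) -> GroundTruth:
    """Copy of `truth` with the swim seed replaced."""
    return replace(truth, swim=replace(truth.swim, seed=seed))
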