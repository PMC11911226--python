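"""Ergometer session data model, file I/O and shared signal primitives.

A dual-roller wheelchair ergometer records, at nominally 100 Hz, the
tangential torque at each wheel and the linear wheel velocity on each side.
This module defines the in-memory containers for those sessions
(:class:`ErgometerTrace`, :class:`WheelGeometry`, :class:`AthleteProfile`,
:class:`BreathRecord`), the plain-text trace dialect used on disk, and the
signal primitives every analyzer shares:

* zero-phase low-pass Butterworth conditioning (:func:`filter_trace`),
* effective rim force from torque, ``F = M / r_r`` (:func:`force_trace`),
* power from torque and wheel velocity, ``PO = M * v_w / r_w``
  (:func:`power_trace`),
* fully-populated rolling means (:func:`rolling_mean`).

Side-combination conventions are encoded once here and reused everywhere:
force and velocity are *averaged* over left and right, power is the *sum*
of both arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from . import constants

__all__ = [
    "TraceLoadError",
    "AnalysisError",
    "WheelGeometry",
    "AthleteProfile",
    "BreathRecord",
    "ErgometerTrace",
    "ForceSeries",
    "PowerSeries",
    "read_trace",
    "write_trace",
    "read_sidecar",
    "write_sidecar",
    "read_breaths",
    "write_breaths",
    "filter_trace",
    "force_trace",
    "power_trace",
    "combined_velocity",
    "rim_velocity",
    "window_samples",
    "rolling_mean",
    "max_rolling_mean",
]

TRACE_COLUMNS = ("time", "torque_left", "torque_right", "velocity_left", "velocity_right")
BREATH_COLUMNS = ("time", "vo2", "rer", "hr")

SPORTS = ("rugby", "basketball", "tennis", "racing")
SEXES = ("male", "female")


class TraceLoadError(ValueError):
    """A trace or breath file is malformed (bad header, gap, non-monotone time)."""


class AnalysisError(RuntimeError):
    """An analyzer precondition is violated (trace too short, inconsistent timing)."""


@dataclass(frozen=True)
class WheelGeometry:
    """Wheel and handrim radii of one wheelchair (metres).

    The rim radius converts torque to effective push force; the wheel radius
    converts torque and wheel velocity to power. ``0 < rim_radius <=
    wheel_radius`` is required.
    """

    wheel_radius: float
    rim_radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.wheel_radius) and math.isfinite(self.rim_radius)):
            raise ValueError("wheel geometry radii must be finite")
        if not 0.0 < self.rim_radius <= self.wheel_radius:
            raise ValueError(
                f"require 0 < rim_radius <= wheel_radius, "
                f"got rim={self.rim_radius!r}, wheel={self.wheel_radius!r}"
            )

    @property
    def rim_over_wheel(self) -> float:
        return self.rim_radius / self.wheel_radius


@dataclass(frozen=True)
class AthleteProfile:
    """Athlete metadata driving normalization, prediction and validity rules.

    Masses are in kg, ages and durations in years, training volume in hours
    per week.  ``sport`` must be one of rugby / basketball / tennis / racing.
    ``lesion_above_T5`` marks a spinal lesion level with impaired sympathetic
    cardiac drive, which excludes the heart-rate maximality criterion.
    """

    mass_user: float
    mass_wheelchair: float
    sex: str
    age: float
    sport: str
    time_since_injury: float = 0.0
    sport_experience: float = 0.0
    training_hours_per_week: float = 0.0
    lesion_above_T5: bool = False

    def __post_init__(self) -> None:
        if self.mass_user <= 0 or self.mass_wheelchair <= 0:
            raise ValueError("masses must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sport not in SPORTS:
            raise ValueError(f"sport must be one of {SPORTS}, got {self.sport!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def mass_total(self) -> float:
        """Combined athlete + wheelchair mass (kg)."""
        return self.mass_user + self.mass_wheelchair


@dataclass(frozen=True)
class BreathRecord:
    """One breath-by-breath sample: time (s), V̇O2 (mL/min), RER (-), HR (bpm)."""

    time: float
    vo2: float
    rer: float
    hr: float

    def __post_init__(self) -> None:
        if self.vo2 < 0:
            raise ValueError("vo2 must be non-negative")
        if self.rer <= 0 or self.hr <= 0:
            raise ValueError("rer and hr must be positive")


@dataclass
class ErgometerTrace:
    """Time-aligned left/right torque and wheel-velocity samples.

    ``time`` is in seconds, strictly increasing and uniform at
    ``sample_rate`` within a 1% jitter tolerance; torque is in N·m at the
    wheel, velocity in m/s in the wheel frame.  Gaps and non-uniform
    sampling are rejected at construction — resampling is deliberately not
    attempted.
    """

    time: np.ndarray
    torque_left: np.ndarray
    torque_right: np.ndarray
    velocity_left: np.ndarray
    velocity_right: np.ndarray
    geometry: WheelGeometry
    sample_rate: float = constants.SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        for name in ("time", "torque_left", "torque_right", "velocity_left", "velocity_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        for name in TRACE_COLUMNS[1:]:
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length != time length")
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"channel {name!r} contains non-finite samples")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("time contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise ValueError(f"time is not strictly increasing at sample {idx + 1}")
        jitter = np.max(np.abs(dt * self.sample_rate - 1.0))
        if jitter > constants.MAX_TIME_JITTER:
            raise ValueError(
                f"non-uniform sampling: worst spacing deviates {jitter:.3%} "
                f"from 1/sample_rate (tolerance {constants.MAX_TIME_JITTER:.0%})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (last minus first time stamp)."""
        return float(self.time[-1] - self.time[0])

    def crop(self, start: float, stop: float | None = None, rebase: bool = True) -> "ErgometerTrace":
        """Return the sub-trace with ``start <= t < stop``; time rebased to 0."""
        t = self.time
        mask = t >= start if stop is None else (t >= start) & (t < stop)
        if int(mask.sum()) < 2:
            raise ValueError("crop would leave fewer than 2 samples")
        new_time = t[mask]
        if rebase:
            new_time = new_time - new_time[0]
        return replace(
            self,
            time=new_time,
            torque_left=self.torque_left[mask],
            torque_right=self.torque_right[mask],
            velocity_left=self.velocity_left[mask],
            velocity_right=self.velocity_right[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name in TRACE_COLUMNS}
        )


class ForceSeries(NamedTuple):
    """Per-side effective rim force (N) and the left/right average."""

    left: np.ndarray
    right: np.ndarray
    combined: np.ndarray


class PowerSeries(NamedTuple):
    """Per-side power (W) and the two-arm sum."""

    left: np.ndarray
    right: np.ndarray
    total: np.ndarray


# ---------------------------------------------------------------------------
# file I/O


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_sidecar(path: str | Path, geometry: WheelGeometry,
                  sample_rate: float = constants.SAMPLE_RATE_HZ) -> Path:
    """Write the YAML sidecar holding geometry and sample rate for a trace file."""
    sidecar = _sidecar_path(Path(path))
    sidecar.write_text(
        yaml.safe_dump(
            {
                "wheel_radius": float(geometry.wheel_radius),
                "rim_radius": float(geometry.rim_radius),
                "sample_rate": float(sample_rate),
            },
            sort_keys=True,
        )
    )
    return sidecar


def read_sidecar(path: str | Path) -> tuple[WheelGeometry, float]:
    """Read geometry and sample rate from a trace file's YAML sidecar."""
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise TraceLoadError(f"sidecar config not found: {sidecar}")
    raw = yaml.safe_load(sidecar.read_text())
    try:
        geometry = WheelGeometry(float(raw["wheel_radius"]), float(raw["rim_radius"]))
        rate = float(raw["sample_rate"])
    except (KeyError, TypeError, ValueError) as exc:
        raise TraceLoadError(f"malformed sidecar {sidecar}: {exc}") from exc
    return geometry, rate


def read_trace(path: str | Path, geometry: WheelGeometry | None = None,
               sample_rate: float | None = None) -> ErgometerTrace:
    """Load a delimited-text trace file into a validated :class:`ErgometerTrace`.

    The dialect is UTF-8 comma-separated text with the exact header
    ``time,torque_left,torque_right,velocity_left,velocity_right``, SI units
    and one sample per row.  If ``geometry`` or ``sample_rate`` is omitted,
    both are read from the ``<file>.meta.yaml`` sidecar.  Time is rebased to
    start at 0.  Malformed files raise :class:`TraceLoadError` naming the
    offending row or field; the row count includes the header line.
    """
    path = Path(path)
    if not path.exists():
        raise TraceLoadError(f"trace file not found: {path}")
    if geometry is None or sample_rate is None:
        side_geom, side_rate = read_sidecar(path)
        geometry = geometry or side_geom
        sample_rate = sample_rate or side_rate
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise TraceLoadError(f"cannot parse {path}: {exc}") from exc
    if tuple(frame.columns) != TRACE_COLUMNS:
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        raise TraceLoadError(
            f"{path}: bad header {list(frame.columns)}; "
            + (f"missing channel(s) {missing}" if missing else "column order must match dialect")
        )
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        row = int(frame[frame[col].isna()].index[0]) + 2  # +1 header, +1 one-based
        raise TraceLoadError(f"{path}: missing value in field {col!r} at row {row}")
    t = frame["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 3  # offending sample, one-based incl. header
        raise TraceLoadError(f"{path}: time not strictly increasing at row {row}")
    try:
        return ErgometerTrace(
            time=t - t[0],
            torque_left=frame["torque_left"].to_numpy(dtype=float),
            torque_right=frame["torque_right"].to_numpy(dtype=float),
            velocity_left=frame["velocity_left"].to_numpy(dtype=float),
            velocity_right=frame["velocity_right"].to_numpy(dtype=float),
            geometry=geometry,
            sample_rate=float(sample_rate),
        )
    except ValueError as exc:
        raise TraceLoadError(f"{path}: {exc}") from exc


def write_trace(trace: ErgometerTrace, path: str | Path,
                sidecar: bool = True) -> Path:
    """Serialize a trace to the canonical dialect (lossless float round-trip)."""
    path = Path(path)
    lines = [",".join(TRACE_COLUMNS)]
    cols = [getattr(trace, name) for name in TRACE_COLUMNS]
    for row in zip(*cols):
        lines.append(",".join(repr(float(x)) for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if sidecar:
        write_sidecar(path, trace.geometry, trace.sample_rate)
    return path


def read_breaths(path: str | Path) -> list[BreathRecord]:
    """Load breath-by-breath records from ``time,vo2,rer,hr`` delimited text."""
    path = Path(path)
    if not path.exists():
        raise TraceLoadError(f"breath file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != BREATH_COLUMNS:
        raise TraceLoadError(f"{path}: bad header {list(frame.columns)}, expected {list(BREATH_COLUMNS)}")
    if frame.isna().any().any():
        raise TraceLoadError(f"{path}: missing values in breath data")
    try:
        return [
            BreathRecord(float(r.time), float(r.vo2), float(r.rer), float(r.hr))
            for r in frame.itertuples()
        ]
    except ValueError as exc:
        raise TraceLoadError(f"{path}: {exc}") from exc


def write_breaths(breaths: Sequence[BreathRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = [",".join(BREATH_COLUMNS)]
    for b in breaths:
        lines.append(",".join(repr(float(x)) for x in (b.time, b.vo2, b.rer, b.hr)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# signal primitives


def filter_trace(trace: ErgometerTrace, cutoff: float = constants.BUTTER_CUTOFF_HZ,
                 order: int = constants.BUTTER_ORDER) -> ErgometerTrace:
    """Zero-phase low-pass Butterworth filter applied to all four channels.

    The filter runs forward and backward (``sosfiltfilt``) so peak locations
    are not lagged; the effective magnitude response is the squared one-pass
    Butterworth response.  Length and time base are unchanged.
    """
    nyquist = trace.sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyquist} Hz), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sample_rate, output="sos")
    filtered = {
        name: signal.sosfiltfilt(sos, getattr(trace, name))
        for name in TRACE_COLUMNS[1:]
    }
    return replace(trace, **filtered)


def force_trace(trace: ErgometerTrace) -> ForceSeries:
    """Effective tangential rim force per side, ``F = M / r_r`` (N).

    The combined series is the mean of left and right, the convention used
    for the isometric strength outcome.
    """
    r_r = trace.geometry.rim_radius
    left = trace.torque_left / r_r
    right = trace.torque_right / r_r
    return ForceSeries(left, right, 0.5 * (left + right))


def power_trace(trace: ErgometerTrace) -> PowerSeries:
    """Power per side, ``PO = M * v_w / r_w`` (W); total is the two-arm sum."""
    r_w = trace.geometry.wheel_radius
    left = trace.torque_left * trace.velocity_left / r_w
    right = trace.torque_right * trace.velocity_right / r_w
    return PowerSeries(left, right, left + right)


def combined_velocity(trace: ErgometerTrace) -> np.ndarray:
    """Left/right-averaged wheel velocity (m/s)."""
    return 0.5 * (trace.velocity_left + trace.velocity_right)


def rim_velocity(trace: ErgometerTrace) -> np.ndarray:
    """Left/right-averaged velocity converted to the handrim frame (m/s)."""
    return combined_velocity(trace) * trace.geometry.rim_over_wheel


def window_samples(window_s: float, sample_rate: float) -> int:
    """Window length in samples: ``round(window * rate)``, ties rounding half up."""
    w = int(math.floor(window_s * sample_rate + 0.5))
    if w < 1:
        raise ValueError(f"window of {window_s} s is shorter than one sample")
    return w


def rolling_mean(series: np.ndarray, window_s: float, sample_rate: float) -> np.ndarray:
    """Arithmetic means over all fully populated sliding windows.

    Returns an array of length ``n - w + 1`` where ``w`` is the window length
    in samples; partial windows at the edges are never produced, so a max
    over the result only ever considers complete windows.
    """
    x = np.asarray(series, dtype=float)
    w = window_samples(window_s, sample_rate)
    if w > x.size:
        raise ValueError(
            f"window of {window_s} s ({w} samples) exceeds series length {x.size}"
        )
    return np.lib.stride_tricks.sliding_window_view(x, w).mean(axis=1)


def max_rolling_mean(series: np.ndarray, window_s: float,
                     sample_rate: float) -> tuple[float, int]:
    """Highest fully-populated rolling mean and the start index of its window."""
    means = rolling_mean(series, window_s, sample_rate)
    idx = int(np.argmax(means))
    return float(means[idx]), idx
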