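"""Outcome extraction and validity gating for the four-test battery.

Each analyzer turns one or more :class:`~ergocap.trace.ErgometerTrace`
recordings into the scalar outcomes of the standardized protocol:

* isometric strength test — highest 3-s rolling mean of the left/right
  averaged rim force (F_iso), with a saturation heuristic flagging possible
  ergometer force-limit clipping;
* 10-s sprint test — mean/peak power (two-arm sum) and velocity
  (side average) over the first 10 s of the best trial (highest v_max);
* 30-s Wingate test — P30, P5 (highest 5-s rolling mean), single-sample
  peak power, and peak rim velocity; valid only if the peak rim velocity
  stays strictly below 3 m/s;
* graded exercise test — highest 30-s mean power inside the final one-minute
  stage block (PO_peak), test duration against the 8–12 min validity window,
  and peak gas-exchange / heart-rate / perceived-exertion outcomes with the
  two-of-three secondary maximality criteria.

From-standstill tests (sprint, Wingate) are first trimmed to the moment the
summed power exceeds 2% of its trace-wide peak, removing idle lead-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import constants
from .trace import (
    AnalysisError,
    AthleteProfile,
    BreathRecord,
    ErgometerTrace,
    combined_velocity,
    force_trace,
    max_rolling_mean,
    power_trace,
    rim_velocity,
    rolling_mean,
    window_samples,
)
from .protocol import GxtStage

__all__ = [
    "IsometricResult",
    "SprintResult",
    "WingateResult",
    "GxtResult",
    "SecondaryCriteria",
    "trim_to_start",
    "analyze_isometric",
    "analyze_sprint",
    "analyze_wingate",
    "analyze_gxt",
    "detect_termination",
    "check_secondary_criteria",
    "result_record",
]


@dataclass(frozen=True)
class IsometricResult:
    f_iso: float
    f_iso_per_kg: float
    saturation_flag: bool
    best_trial: int

    def __post_init__(self) -> None:
        if self.f_iso < 0:
            raise ValueError("f_iso must be non-negative")


@dataclass(frozen=True)
class SprintResult:
    po_mean: float
    po_max: float
    v_mean: float
    v_max: float
    best_trial: int

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.po_max))
        vtol = 1e-9 * max(1.0, abs(self.v_max))
        if not (self.po_max >= self.po_mean - tol and self.po_mean >= -tol
                and self.v_max >= self.v_mean - vtol and self.v_mean >= -vtol):
            raise ValueError("sprint outcomes must satisfy max >= mean >= 0")


@dataclass(frozen=True)
class WingateResult:
    p30: float
    p5: float
    po_max: float
    v_max_rim: float
    valid: bool

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.po_max))
        if not (self.po_max >= self.p5 - tol and self.p5 >= self.p30 - tol
                and self.p30 >= -tol):
            raise ValueError("require po_max >= p5 >= p30 >= 0")
        if self.valid != (self.v_max_rim < constants.RIM_VELOCITY_LIMIT):
            raise ValueError("valid flag inconsistent with v_max_rim limit")


@dataclass(frozen=True)
class SecondaryCriteria:
    """Two-of-three maximality check (RER, HR, RPE) with HR exclusion detail."""

    met: bool
    rer_met: bool
    hr_met: bool | None      # None when excluded for a lesion above T5
    rpe_met: bool
    hr_threshold: float


@dataclass(frozen=True)
class GxtResult:
    po_peak: float
    duration: float          # minutes, fractional
    vo2peak: float | None    # mL/min/kg, None without breath data
    rer_peak: float | None
    hr_peak: float | None
    rpe_overall: float | None
    duration_valid: bool
    secondary_criteria_met: bool
    secondary: SecondaryCriteria
    final_block: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def trim_to_start(trace: ErgometerTrace,
                  fraction: float = constants.START_TRIM_FRACTION) -> ErgometerTrace:
    """Crop a from-standstill recording to its actual start.

    The start is the first sample whose summed power exceeds ``fraction`` of
    the trace-wide peak; leading idle is discarded and time rebased to 0.
    A trace with no supra-threshold sample is returned unchanged.
    """
    total = power_trace(trace).total
    peak = float(np.max(total))
    if peak <= 0:
        return trace
    above = np.flatnonzero(total > fraction * peak)
    if above.size == 0 or above[0] == 0:
        return trace
    return trace.crop(trace.time[above[0]])


def analyze_isometric(trials: Sequence[ErgometerTrace], profile: AthleteProfile,
                      window_s: float = constants.ISO_WINDOW_S) -> IsometricResult:
    """Extract F_iso: highest 3-s rolling mean of the side-averaged force.

    The best window over all trials wins.  The saturation flag is raised when
    the force signal sits within 0.5% of its own maximum for more than half
    of the winning window — a heuristic for ergometer force-limit clipping,
    reported but never used to reject the trial.
    """
    if not trials:
        raise AnalysisError("need at least one isometric trial")
    best = -math.inf
    best_trial = -1
    saturated = False
    for i, trial in enumerate(trials):
        if trial.duration < window_s:
            raise AnalysisError(
                f"isometric trial {i + 1} lasts {trial.duration:.2f} s < {window_s} s window"
            )
        force = force_trace(trial).combined
        value, start = max_rolling_mean(force, window_s, trial.sample_rate)
        if value > best:
            best, best_trial = value, i
            w = window_samples(window_s, trial.sample_rate)
            segment = force[start:start + w]
            ceiling = float(np.max(force))
            near_max = segment >= (1.0 - constants.SATURATION_REL_TOL) * ceiling
            saturated = bool(np.mean(near_max) > constants.SATURATION_FRACTION)
    f_iso = max(best, 0.0)
    return IsometricResult(f_iso, f_iso / profile.mass_user, saturated, best_trial)


def analyze_sprint(trials: Sequence[ErgometerTrace],
                   duration_s: float = constants.SPRINT_DURATION_S,
                   trim: bool = True) -> SprintResult:
    """Sprint outcomes over the first 10 s; the trial with the highest v_max wins."""
    if not trials:
        raise AnalysisError("need at least one sprint trial")
    best: SprintResult | None = None
    for i, trial in enumerate(trials):
        tr = trim_to_start(trial) if trim else trial
        if tr.duration < duration_s:
            raise AnalysisError(
                f"sprint trial {i + 1} lasts {tr.duration:.2f} s < {duration_s} s after start trim"
            )
        n = window_samples(duration_s, tr.sample_rate)
        power = power_trace(tr).total[:n]
        velocity = combined_velocity(tr)[:n]
        candidate = SprintResult(
            po_mean=float(np.mean(power)),
            po_max=float(np.max(power)),
            v_mean=float(np.mean(velocity)),
            v_max=float(np.max(velocity)),
            best_trial=i,
        )
        if best is None or candidate.v_max > best.v_max:
            best = candidate
    assert best is not None
    return best


def analyze_wingate(trace: ErgometerTrace,
                    duration_s: float = constants.WINGATE_DURATION_S,
                    p5_window_s: float = constants.P5_WINDOW_S,
                    trim: bool = True) -> WingateResult:
    """Wingate outcomes over the 30-s effort plus the rim-velocity validity gate."""
    tr = trim_to_start(trace) if trim else trace
    if tr.duration < duration_s:
        raise AnalysisError(
            f"Wingate trace lasts {tr.duration:.2f} s < {duration_s} s after start trim"
        )
    n = window_samples(duration_s, tr.sample_rate)
    power = power_trace(tr).total[:n]
    v_rim = rim_velocity(tr)[:n]
    p30 = float(np.mean(power))
    p5 = float(np.max(rolling_mean(power, p5_window_s, tr.sample_rate)))
    po_max = float(np.max(power))
    v_max_rim = float(np.max(v_rim))
    return WingateResult(p30, p5, po_max, v_max_rim,
                         valid=v_max_rim < constants.RIM_VELOCITY_LIMIT)


def detect_termination(trace: ErgometerTrace, target_velocity: float,
                       dwell: float = constants.TERMINATION_DWELL_S,
                       margin: float = constants.TERMINATION_MARGIN) -> float:
    """Time at which the athlete can no longer hold the target velocity.

    Returns the first time the side-averaged velocity drops more than
    ``margin`` below ``target_velocity`` and stays there continuously for
    ``dwell`` seconds (the reported time is the start of that dwell window,
    i.e. the moment the velocity was lost).  Falls back to the end of the
    trace when the target is held throughout.
    """
    if target_velocity <= 0:
        raise ValueError("target_velocity must be positive")
    below = combined_velocity(trace) < (target_velocity - margin)
    w = window_samples(dwell, trace.sample_rate)
    if w > below.size:
        return float(trace.time[-1])
    counts = np.convolve(below.astype(int), np.ones(w, dtype=int), mode="valid")
    hits = np.flatnonzero(counts == w)
    if hits.size == 0:
        return float(trace.time[-1])
    return float(trace.time[hits[0]])


def check_secondary_criteria(rer_peak: float | None, hr_peak: float | None,
                             rpe_overall: float | None, age: float,
                             lesion_above_T5: bool = False) -> SecondaryCriteria:
    """Evaluate the maximal-effort criteria: RER >= 1.10, HR >= 95% of
    (200 - age), overall RPE >= 8.

    Overall the effort counts as maximal when at least two of the three
    criteria hold.  For athletes with a lesion above T5 the heart-rate
    criterion is excluded (impaired sympathetic cardiac drive) and both
    remaining criteria must hold.  Missing inputs count as not satisfied.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    hr_threshold = constants.HR_CRITERION_FRACTION * (constants.HR_PRED_INTERCEPT - age)
    rer_met = rer_peak is not None and rer_peak >= constants.RER_CRITERION
    rpe_met = rpe_overall is not None and rpe_overall >= constants.RPE_CRITERION
    if lesion_above_T5:
        return SecondaryCriteria(rer_met and rpe_met, rer_met, None, rpe_met, hr_threshold)
    hr_met = hr_peak is not None and hr_peak >= hr_threshold
    met = (int(rer_met) + int(hr_met) + int(rpe_met)) >= 2
    return SecondaryCriteria(met, rer_met, hr_met, rpe_met, hr_threshold)


def _round_half_up(value: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(value * factor + 0.5) / factor


def _breath_rolling_max(times: np.ndarray, values: np.ndarray, window_s: float) -> float:
    """Highest trailing time-window mean of irregularly sampled breath data."""
    best = -math.inf
    t0 = times[0]
    for i in range(times.size):
        if times[i] - t0 < window_s:
            continue
        j = int(np.searchsorted(times, times[i] - window_s, side="right"))
        best = max(best, float(np.mean(values[j:i + 1])))
    if not math.isfinite(best):  # recording shorter than one window: use all of it
        best = float(np.mean(values))
    return best


def analyze_gxt(trace: ErgometerTrace, stages: Sequence[GxtStage],
                profile: AthleteProfile,
                breaths: Sequence[BreathRecord] = (),
                rpe_peripheral: float | None = None,
                rpe_central: float | None = None,
                target_velocity: float | None = None,
                window_s: float = constants.PO_PEAK_WINDOW_S,
                stage_duration_s: float = constants.GXT_STAGE_DURATION_S) -> GxtResult:
    """Graded-exercise-test outcomes and validity gating.

    ``stages`` is the staircase actually programmed (stage k spans
    ``[(k-1)*60, k*60)`` seconds from the start of the recording).  When
    ``target_velocity`` is given, the test duration is the velocity-loss
    termination time; otherwise the recording is assumed to end at
    termination.  PO_peak is the highest 30-s rolling mean of summed power
    over windows lying fully inside the final one-minute block that was
    entered; if fewer than 30 s of that block were completed, the last fully
    completed stage is used instead.  Duration validity uses the inclusive
    8–12 min window, evaluated on the duration rounded to 0.1 min (the
    protocol's reporting precision).
    """
    if not stages:
        raise AnalysisError("need at least one GXT stage")
    if trace.duration < stage_duration_s:
        raise AnalysisError("GXT trace does not cover one full stage")
    t_term = (detect_termination(trace, target_velocity)
              if target_velocity is not None else float(trace.time[-1]))
    duration_min = t_term / 60.0
    n_stages = len(stages)
    entered = min(int(t_term // stage_duration_s) + 1, n_stages)
    block = entered
    if t_term - (entered - 1) * stage_duration_s < window_s and entered > 1:
        block = entered - 1
    b0 = (block - 1) * stage_duration_s
    b1 = min(b0 + stage_duration_s, t_term)
    if b1 - b0 < window_s:
        raise AnalysisError(
            f"final block {block} holds only {b1 - b0:.1f} s of data, "
            f"cannot fit a {window_s:.0f} s window"
        )
    power = power_trace(trace).total
    in_block = (trace.time >= b0) & (trace.time < b1 + 0.5 / trace.sample_rate)
    po_peak = float(np.max(rolling_mean(power[in_block], window_s, trace.sample_rate)))

    vo2peak = rer_peak = hr_peak = None
    if breaths:
        recs = [b for b in breaths if b.time <= t_term]
        if recs:
            bt = np.array([b.time for b in recs])
            vo2peak = _breath_rolling_max(bt, np.array([b.vo2 for b in recs]), window_s)
            vo2peak /= profile.mass_user
            rer_peak = _breath_rolling_max(bt, np.array([b.rer for b in recs]), window_s)
            hr_peak = float(np.max([b.hr for b in recs]))

    rpe_overall = None
    if rpe_peripheral is not None and rpe_central is not None:
        rpe_overall = 0.5 * (rpe_peripheral + rpe_central)

    reported = _round_half_up(duration_min, constants.GXT_DURATION_DECIMALS)
    duration_valid = constants.GXT_MIN_DURATION_MIN <= reported <= constants.GXT_MAX_DURATION_MIN
    secondary = check_secondary_criteria(
        rer_peak, hr_peak, rpe_overall, profile.age, profile.lesion_above_T5
    )
    return GxtResult(
        po_peak=po_peak,
        duration=duration_min,
        vo2peak=vo2peak,
        rer_peak=rer_peak,
        hr_peak=hr_peak,
        rpe_overall=rpe_overall,
        duration_valid=duration_valid,
        secondary_criteria_met=secondary.met,
        secondary=secondary,
        final_block=block,
    )


def result_record(isometric: IsometricResult | None = None,
                  sprint: SprintResult | None = None,
                  wingate: WingateResult | None = None,
                  gxt: GxtResult | None = None) -> dict:
    """Flatten analyzer results into one record with the protocol's labels."""
    record: dict[str, object] = {}
    if isometric is not None:
        record.update(F_iso=isometric.f_iso, F_iso_per_kg=isometric.f_iso_per_kg,
                      F_iso_saturated=isometric.saturation_flag)
    if sprint is not None:
        record.update(PO_mean=sprint.po_mean, PO_max=sprint.po_max,
                      v_mean=sprint.v_mean, v_max=sprint.v_max)
    if wingate is not None:
        record.update(P30=wingate.p30, P5=wingate.p5, PO_max_wingate=wingate.po_max,
                      v_max_rim=wingate.v_max_rim, wingate_valid=wingate.valid)
    if gxt is not None:
        record.update(PO_peak=gxt.po_peak, duration_min=gxt.duration,
                      VO2peak=gxt.vo2peak, RER_peak=gxt.rer_peak, HR_peak=gxt.hr_peak,
                      RPE_overall=gxt.rpe_overall, gxt_duration_valid=gxt.duration_valid,
                      secondary_criteria_met=gxt.secondary_criteria_met)
    return record
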