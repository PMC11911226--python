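"""Synthetic ergometer sessions and cohorts with known ground truth.

Every analyzer, protocol designer and regression routine in this package is
testable against traces generated here, without any recorded data.  The
generators emulate the four tests of the battery:

* isometric trials — ramp / plateau / release force profiles at the
  athlete's true strength, with optional force-limit clipping;
* sprint — forward integration of ``m_total * dv/dt = F_prop - mu*m*g``
  under half-sine push pulses, amplitude calibrated to a target mean power;
* Wingate — the same dynamics under the individualized resistance, with the
  athlete modelled as a power source tracking a linearly fatiguing envelope
  (default start/end power ratio 1.6) delivered in push pulses;
* graded exercise test — target velocity held while the stage demand stays
  within the athlete's true peak aerobic power, collapse upon entering the
  first over-capacity stage, plus first-order V̇O2 kinetics, RER drift and
  heart-rate response in the breath channel;
* cohorts — per-sport anthropometrics and sprint velocities drawn from the
  published group means/SDs, anaerobic and aerobic power derived from the
  sport-aware prediction equations with Gaussian noise calibrated to a
  target R².

All stochastic behaviour flows from the explicit ``seed`` argument; the
ground-truth parameters never depend on the seed.  Left and right sides are
symmetric by default; an ``asymmetry`` parameter exists to exercise the
side-combination conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .protocol import EQUATIONS, GxtPlan, PredictionEquation
from .trace import AthleteProfile, BreathRecord, ErgometerTrace, WheelGeometry

__all__ = [
    "DEFAULT_GEOMETRY",
    "SPORT_STATS",
    "AthleteGroundTruth",
    "sample_ground_truth",
    "synth_isometric_trials",
    "synth_sprint_trace",
    "synth_wingate_trace",
    "synth_gxt_session",
    "synth_cohort",
]

#: A typical court wheelchair: 0.31 m tire radius, 0.26 m handrim radius.
DEFAULT_GEOMETRY = WheelGeometry(wheel_radius=0.31, rim_radius=0.26)

#: Per-sport population parameters (mean, SD) used by the cohort generator:
#: body mass (kg), age (yr), sprint v_mean (m/s), isometric strength (N),
#: time since injury (yr), sport experience (yr), weekly training hours,
#: plus the male fraction and a typical sports-chair mass (kg).
SPORT_STATS: dict[str, dict] = {
    "rugby": dict(mass=(74, 9), age=(26, 5), v_mean=(3.0, 0.4), f_iso=(267, 69),
                  tsi=(20, 10), experience=(6, 4), training=(18, 5),
                  male_frac=1.0, chair_mass=(14, 2), cadence=1.0),
    "basketball": dict(mass=(67, 14), age=(26, 6), v_mean=(3.2, 0.4), f_iso=(250, 53),
                       tsi=(18, 8), experience=(8, 4), training=(19, 4),
                       male_frac=3 / 9, chair_mass=(13, 2), cadence=1.0),
    "tennis": dict(mass=(64, 13), age=(26, 8), v_mean=(3.4, 0.4), f_iso=(275, 59),
                   tsi=(22, 11), experience=(13, 8), training=(21, 6),
                   male_frac=6 / 12, chair_mass=(12, 2), cadence=1.0),
    "racing": dict(mass=(63, 9), age=(27, 10), v_mean=(4.6, 0.9), f_iso=(253, 93),
                   tsi=(23, 7), experience=(5, 5), training=(13, 5),
                   male_frac=8 / 11, chair_mass=(9, 1), cadence=1.5),
}

#: Default cohort composition (rugby, basketball, tennis, racing athletes).
DEFAULT_SPORT_MIX = {"rugby": 11 / 43, "basketball": 9 / 43, "tennis": 12 / 43,
                     "racing": 11 / 43}

#: Realism guards for truncated-normal sampling (not protocol values).
_BOUNDS = dict(mass=(35.0, 120.0), v_mean=(1.5, 7.0), f_iso=(50.0, 450.0),
               age=(16.0, 60.0), chair_mass=(6.0, 25.0), tsi=(1.0, 40.0),
               experience=(0.5, 30.0), training=(2.0, 35.0))


@dataclass(frozen=True)
class AthleteGroundTruth:
    """Latent quantities of one simulated athlete.

    ``true_f_iso`` (N), ``true_p30`` (W) and ``true_po_peak`` (W) are the
    quantities the tests try to measure; ``push_cadence`` (Hz) sets the push
    pulse frequency, ``noise_level`` the relative amplitude noise.
    """

    profile: AthleteProfile
    true_f_iso: float
    true_p30: float
    true_po_peak: float
    push_cadence: float = 1.0
    noise_level: float = 0.03
    true_sprint_v_mean: float | None = None
    true_vo2peak_per_kg: float = 38.0
    geometry: WheelGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if min(self.true_f_iso, self.true_p30, self.true_po_peak,
               self.push_cadence) <= 0:
            raise ValueError("ground-truth quantities must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, high)


def sample_ground_truth(sport: str, seed: int = 0,
                        geometry: WheelGeometry = DEFAULT_GEOMETRY) -> AthleteGroundTruth:
    """Draw one internally consistent athlete of the given sport.

    Mass, age and sprint velocity come from the per-sport population
    parameters; the true anaerobic and aerobic powers follow the sport-aware
    prediction equations with small individual departures, and the true
    strength is back-computed through the legacy strength equation so that
    all latent quantities are mutually consistent.
    """
    stats = SPORT_STATS[sport]
    rng = np.random.default_rng(seed)
    mass = float(_trunc_normal(rng, *stats["mass"], *_BOUNDS["mass"], 1)[0])
    chair = float(_trunc_normal(rng, *stats["chair_mass"], *_BOUNDS["chair_mass"], 1)[0])
    age = float(_trunc_normal(rng, *stats["age"], *_BOUNDS["age"], 1)[0])
    sex = "male" if rng.random() < stats["male_frac"] else "female"
    v_mean = float(_trunc_normal(rng, *stats["v_mean"], *_BOUNDS["v_mean"], 1)[0])
    profile = AthleteProfile(
        mass_user=mass, mass_wheelchair=chair, sex=sex, age=age, sport=sport,
        time_since_injury=float(_trunc_normal(rng, *stats["tsi"], *_BOUNDS["tsi"], 1)[0]),
        sport_experience=float(_trunc_normal(rng, *stats["experience"],
                                             *_BOUNDS["experience"], 1)[0]),
        training_hours_per_week=float(_trunc_normal(rng, *stats["training"],
                                                    *_BOUNDS["training"], 1)[0]),
    )
    p30_kg = EQUATIONS["sprint"].per_kg(sport=sport, sprint_v_mean=v_mean)
    p30_kg = max(p30_kg * (1.0 + 0.08 * rng.standard_normal()), 0.3)
    po_peak_kg = EQUATIONS["wingate"].per_kg(sport=sport, p30_per_kg=p30_kg)
    po_peak_kg = max(po_peak_kg * (1.0 + 0.08 * rng.standard_normal()), 0.2)
    f_iso_kg = (p30_kg + 0.18) / 0.51 * (1.0 + 0.10 * rng.standard_normal())
    return AthleteGroundTruth(
        profile=profile,
        true_f_iso=max(f_iso_kg, 0.8) * mass,
        true_p30=p30_kg * mass,
        true_po_peak=po_peak_kg * mass,
        push_cadence=stats["cadence"],
        true_sprint_v_mean=v_mean,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# trace generators


def _make_trace(gt: AthleteGroundTruth, time: np.ndarray, torque_total: np.ndarray,
                velocity: np.ndarray, sample_rate: float,
                asymmetry: float = 0.0) -> ErgometerTrace:
    """Split total torque into sides; ``asymmetry`` shifts load to the left arm."""
    left = torque_total * 0.5 * (1.0 + asymmetry)
    right = torque_total * 0.5 * (1.0 - asymmetry)
    return ErgometerTrace(
        time=time, torque_left=left, torque_right=right,
        velocity_left=velocity.copy(), velocity_right=velocity.copy(),
        geometry=gt.geometry, sample_rate=sample_rate,
    )


def synth_isometric_trials(gt: AthleteGroundTruth, seed: int = 0,
                           n_trials: int = 3,
                           sample_rate: float = constants.SAMPLE_RATE_HZ,
                           plateau_s: float = 5.0, ramp_s: float = 1.0,
                           idle_s: float = 0.5,
                           noise: float | None = None,
                           force_limit: float | None = None,
                           asymmetry: float = 0.0) -> list[ErgometerTrace]:
    """Three maximal 5-s isometric efforts: ramp, plateau at F_iso, release.

    The best trial plateaus exactly at ``true_f_iso`` (the others a few
    percent lower), with multiplicative sample noise.  ``force_limit``
    clips the force, emulating an ergometer whose brakes saturate below the
    athlete's strength; wheels are (near) stationary throughout.
    """
    rng = np.random.default_rng(seed)
    noise = gt.noise_level if noise is None else noise
    total_s = idle_s + ramp_s + plateau_s + idle_s
    n = int(round(total_s * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    trials = []
    deficits = [0.0] + list(rng.uniform(0.01, 0.05, n_trials - 1))
    rng.shuffle(deficits)
    for deficit in deficits:
        amp = gt.true_f_iso * (1.0 - deficit)
        profile = np.interp(
            time,
            [0.0, idle_s, idle_s + ramp_s, idle_s + ramp_s + plateau_s,
             idle_s + ramp_s + plateau_s + 0.3, total_s],
            [0.0, 0.0, amp, amp, 0.0, 0.0],
        )
        force = profile * (1.0 + noise * rng.standard_normal(n) * (profile > 0))
        if force_limit is not None:
            force = np.minimum(force, force_limit)
        torque_total = 2.0 * force * gt.geometry.rim_radius  # F is the side average
        velocity = 1e-4 * rng.standard_normal(n)
        trials.append(_make_trace(gt, time, torque_total, velocity, sample_rate,
                                  asymmetry))
    return trials


def _integrate_pushes(time: np.ndarray, demand_force: np.ndarray, m_total: float,
                      mu: float, sample_rate: float, v0: float = 0.0,
                      substeps: int = 5) -> np.ndarray:
    """Integrate m*dv/dt = F_prop - mu*m*g with sub-sample Euler steps.

    ``demand_force`` is the propulsive force at the roller contact, held
    constant within each recorded sample.  Rolling friction acts only while
    moving; velocity never goes negative.
    """
    dt = 1.0 / (sample_rate * substeps)
    friction = mu * m_total * constants.G
    v = np.empty_like(time)
    cur = v0
    for i, f in enumerate(demand_force):
        v[i] = cur
        for _ in range(substeps):
            drag = friction if cur > 0 else min(f, friction)
            cur = max(cur + (f - drag) / m_total * dt, 0.0)
    return v


def synth_sprint_trace(gt: AthleteGroundTruth, mu: float = constants.COURT_MU,
                       seed: int = 0, duration_s: float = 12.0,
                       sample_rate: float = constants.SAMPLE_RATE_HZ,
                       target_mean_power: float | None = None,
                       idle_s: float = 0.5, cadence: float | None = None,
                       noise: float | None = None,
                       asymmetry: float = 0.0) -> ErgometerTrace:
    """A from-standstill 10-s sprint at court resistance (mu = 0.012).

    The athlete applies half-sine rim-force pulses at the push cadence; the
    amplitude is calibrated (by repeated cheap forward simulation) so the
    mean delivered power over the 10-s analysis window approximates
    ``target_mean_power`` (default 0.9 x true P30, the typical ratio of
    sprint to Wingate mean power).  With a zero target the wheels never
    move.
    """
    rng = np.random.default_rng(seed)
    noise = gt.noise_level if noise is None else noise
    cadence = gt.push_cadence if cadence is None else cadence
    target = 0.9 * gt.true_p30 if target_mean_power is None else target_mean_power
    m = gt.profile.mass_total
    geom = gt.geometry
    n = int(round(duration_s * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    active = time >= idle_s
    pulse = np.where(active, np.maximum(np.sin(2 * np.pi * cadence * (time - idle_s)), 0.0), 0.0)
    pulse = pulse * (1.0 + noise * rng.standard_normal(n))
    pulse = np.maximum(pulse, 0.0)
    window = active & (time < idle_s + constants.SPRINT_DURATION_S)

    def run(amplitude: float) -> tuple[np.ndarray, np.ndarray]:
        f_rim = amplitude * pulse
        f_prop = f_rim * geom.rim_radius / geom.wheel_radius
        v = _integrate_pushes(time, f_prop, m, mu, sample_rate)
        return f_prop, v

    amp = 0.0
    if target > 0:
        # delivered power grows faster than quadratically with pulse amplitude
        # (force and the velocity it builds both scale up), so calibrate with a
        # damped log-space secant instead of naive proportional updates
        amp = 4.0 * target / 3.0
        prev: tuple[float, float] | None = None
        for _ in range(12):
            f_prop, v = run(amp)
            measured = float(np.mean((f_prop * v)[window]))
            if measured <= 1e-9:
                amp *= 2.0
                continue
            if abs(measured - target) <= 1e-3 * target:
                break
            slope = 2.0
            if prev is not None and abs(math.log(amp / prev[0])) > 1e-12:
                est = math.log(measured / prev[1]) / math.log(amp / prev[0])
                if math.isfinite(est):
                    slope = min(max(est, 1.0), 4.0)
            prev = (amp, measured)
            amp *= (target / measured) ** (1.0 / slope)
    f_prop, v = run(amp)
    torque_total = f_prop * geom.wheel_radius  # = F_rim * r_r
    return _make_trace(gt, time, torque_total, v, sample_rate, asymmetry)


def synth_wingate_trace(gt: AthleteGroundTruth, mu: float, seed: int = 0,
                        duration_s: float = 32.0,
                        sample_rate: float = constants.SAMPLE_RATE_HZ,
                        decay_ratio: float = 1.6,
                        cadence: float | None = None,
                        noise: float | None = None,
                        initial_velocity: float = 0.0,
                        v_floor: float = 0.15,
                        force_cap: float | None = None,
                        asymmetry: float = 0.0) -> ErgometerTrace:
    """A 30-s all-out effort against the individualized resistance ``mu``.

    The athlete is modelled as a power source: delivered power tracks a
    linearly decaying fatigue envelope with mean ``true_p30`` and
    start/end ratio ``decay_ratio`` (default 1.6, so the highest 5-s mean
    clearly exceeds the 30-s mean), shaped into half-sine push pulses whose
    per-cycle average equals the envelope.  Below ``v_floor`` (or above the
    force cap, ~2.5 x isometric strength) force control takes over, which
    reproduces the brief spin-up from standstill.  ``initial_velocity``
    starts the simulation pre-rolled, giving steady-state propulsion from
    the first sample.
    """
    rng = np.random.default_rng(seed)
    noise = gt.noise_level if noise is None else noise
    cadence = gt.push_cadence if cadence is None else cadence
    m = gt.profile.mass_total
    geom = gt.geometry
    if force_cap is None:
        force_cap = 2.5 * gt.true_f_iso * geom.rim_over_wheel
    n = int(round(duration_s * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    top = 2.0 * decay_ratio / (1.0 + decay_ratio) * gt.true_p30
    bottom = 2.0 / (1.0 + decay_ratio) * gt.true_p30
    envelope = top + (bottom - top) * time / constants.WINGATE_DURATION_S
    envelope = np.maximum(envelope, 0.0)
    shape = np.pi * np.maximum(np.sin(2 * np.pi * cadence * time), 0.0)
    demand = envelope * shape * np.maximum(1.0 + noise * rng.standard_normal(n), 0.0)

    dt = 1.0 / sample_rate
    friction = mu * m * constants.G
    v = np.empty(n)
    f_prop = np.empty(n)
    cur = initial_velocity
    for i in range(n):
        v[i] = cur
        f = min(demand[i] / max(cur, v_floor), force_cap)
        f_prop[i] = f
        drag = friction if cur > 0 else min(f, friction)
        cur = max(cur + (f - drag) / m * dt, 0.0)
    torque_total = f_prop * geom.wheel_radius
    return _make_trace(gt, time, torque_total, v, sample_rate, asymmetry)


def synth_gxt_session(gt: AthleteGroundTruth, plan: GxtPlan, seed: int = 0,
                      sample_rate: float = constants.SAMPLE_RATE_HZ,
                      tail_s: float = 8.0, breath_interval_s: float = 2.0,
                      ripple: float = 0.15, velocity_noise: float = 0.01,
                      hr_fraction: float = 0.97, vo2_tau_s: float = 25.0,
                      noise: float | None = None,
                      asymmetry: float = 0.0) -> tuple[ErgometerTrace, list[BreathRecord]]:
    """One graded exercise test to exhaustion under the given staircase.

    The athlete holds the plan's target (wheel-frame) velocity through every
    stage whose power demand stays within ``true_po_peak``; upon entering
    the first over-capacity stage the output collapses and velocity decays,
    which the termination rule picks up within a fraction of a second of the
    stage boundary.  Breath-by-breath V̇O2 follows first-order kinetics
    toward a plateau at the athlete's implied V̇O2peak, RER drifts above
    1.10 near exhaustion, and heart rate approaches ``hr_fraction`` of the
    age-predicted maximum (200 - age).
    """
    rng = np.random.default_rng(seed)
    noise = gt.noise_level if noise is None else noise
    profile = gt.profile
    m = profile.mass_total
    geom = gt.geometry
    stage_s = constants.GXT_STAGE_DURATION_S
    sustainable = [s for s in plan.stages if s.power <= gt.true_po_peak * (1.0 + 1e-9)]
    if not sustainable:
        raise ValueError("first stage already exceeds the athlete's capacity")
    k_max = max(s.index for s in sustainable)
    t_fail = k_max * stage_s
    t_end = t_fail + tail_s
    n = int(round(t_end * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    v_t = plan.target_velocity
    cadence = gt.push_cadence

    stage_idx = np.minimum((time // stage_s).astype(int), len(plan.stages) - 1)
    stage_mu = np.array([s.mu for s in plan.stages])[stage_idx]
    collapse = np.exp(-np.maximum(time - t_fail, 0.0) / 0.6)
    velocity = v_t * (1.0 + 0.02 * np.sin(2 * np.pi * cadence * time)) * collapse
    velocity += velocity_noise * rng.standard_normal(n) * collapse
    velocity = np.maximum(velocity, 0.0)
    pulse = 1.0 + ripple * np.cos(2 * np.pi * cadence * time) \
        + noise * rng.standard_normal(n)
    torque_total = geom.wheel_radius * stage_mu * m * constants.G \
        * np.maximum(pulse, 0.0) * collapse
    trace = _make_trace(gt, time, torque_total, velocity, sample_rate, asymmetry)

    # breath channel: first-order V̇O2 response to the staircase demand
    vo2_rest = 300.0  # mL/min, resting uptake
    vo2_max = gt.true_vo2peak_per_kg * profile.mass_user
    hr_rest = 65.0
    hr_peak = hr_fraction * (constants.HR_PRED_INTERCEPT - profile.age)
    if profile.lesion_above_T5:
        hr_peak = 0.75 * (constants.HR_PRED_INTERCEPT - profile.age)
    breaths: list[BreathRecord] = []
    t = 0.0
    vo2 = vo2_rest
    prev_t = 0.0
    stage_powers = np.array([s.power for s in plan.stages])
    while t < t_end:
        k = min(int(t // stage_s), len(plan.stages) - 1)
        frac = min(stage_powers[k] / gt.true_po_peak, 1.0)
        if t > t_fail:
            frac *= math.exp(-(t - t_fail) / 10.0)
        target_vo2 = vo2_rest + (vo2_max - vo2_rest) * frac
        vo2 += (target_vo2 - vo2) * (t - prev_t) / vo2_tau_s
        rer = 0.80 + 0.35 * (max(vo2 - vo2_rest, 0.0) / (vo2_max - vo2_rest)) ** 1.5
        rer += 0.01 * rng.standard_normal()
        hr = hr_rest + (hr_peak - hr_rest) * (max(vo2 - vo2_rest, 0.0)
                                              / (vo2_max - vo2_rest))
        hr += 1.5 * rng.standard_normal()
        breaths.append(BreathRecord(time=t, vo2=max(vo2, 0.0),
                                    rer=max(rer, 0.7), hr=max(hr, 40.0)))
        prev_t = t
        t += breath_interval_s * (1.0 + 0.15 * (rng.random() - 0.5))
    return trace, breaths


# ---------------------------------------------------------------------------
# cohort generator


def synth_cohort(n: int = 43, seed: int = 0,
                 p30_equation: PredictionEquation = EQUATIONS["sprint"],
                 po_peak_equation: PredictionEquation = EQUATIONS["wingate"],
                 sport_mix: dict[str, float] | None = None,
                 r2_p30: float = 0.84, r2_po_peak: float = 0.78,
                 f_iso_rho: float = 0.8,
                 missing_rate: float = 0.0) -> tuple[pd.DataFrame, dict]:
    """Simulate a tested cohort with known generating equations.

    Sport, body mass, demographics and sprint v_mean are drawn per sport
    from the published group means/SDs (truncated at physiologic bounds);
    ``p30_per_kg`` follows the sprint equation plus Gaussian noise whose SD
    is calibrated against the realized linear-predictor variance so the
    population R² equals ``r2_p30`` (``r2=1`` gives exact interpolation),
    and ``po_peak_per_kg`` likewise from the Wingate equation.  Isometric
    strength is drawn from the per-sport norms but correlated (``f_iso_rho``)
    with the athlete's within-sport anaerobic-power score, so strength
    remains an informative—but weaker—predictor, as observed in testing.
    Sprint and Wingate outcome families are internally collinear (|r| > 0.8)
    by construction.

    Returns the cohort table and a ground-truth dict (equations and the
    calibrated noise SDs).
    """
    if n < 10:
        raise ValueError("cohort generator needs n >= 10")
    if set(p30_equation.required_inputs) - {"sprint_v_mean"}:
        raise ValueError("p30 generating equation must use sprint_v_mean")
    if set(po_peak_equation.required_inputs) - {"p30_per_kg"}:
        raise ValueError("po_peak generating equation must use p30_per_kg")
    rng = np.random.default_rng(seed)
    mix = DEFAULT_SPORT_MIX if sport_mix is None else sport_mix
    sports_all = list(mix)
    probs = np.array([mix[s] for s in sports_all], dtype=float)
    probs /= probs.sum()
    # fixed cohort composition (largest-remainder rounding), as in a planned
    # study sample; the athletes themselves are random
    quota = probs * n
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1
    sport = np.repeat(sports_all, counts)
    rng.shuffle(sport)

    cols: dict[str, np.ndarray] = {c: np.empty(n) for c in (
        "age", "mass_user", "mass_wheelchair", "time_since_injury",
        "sport_experience", "training_hours_per_week", "sprint_v_mean")}
    male = np.zeros(n, dtype=bool)
    lesion = np.zeros(n, dtype=bool)
    for sp in sports_all:
        mask = sport == sp
        k = int(mask.sum())
        if k == 0:
            continue
        st = SPORT_STATS[sp]
        cols["mass_user"][mask] = _trunc_normal(rng, *st["mass"], *_BOUNDS["mass"], k)
        cols["mass_wheelchair"][mask] = _trunc_normal(rng, *st["chair_mass"],
                                                      *_BOUNDS["chair_mass"], k)
        cols["age"][mask] = _trunc_normal(rng, *st["age"], *_BOUNDS["age"], k)
        cols["time_since_injury"][mask] = _trunc_normal(rng, *st["tsi"], *_BOUNDS["tsi"], k)
        cols["sport_experience"][mask] = _trunc_normal(rng, *st["experience"],
                                                       *_BOUNDS["experience"], k)
        cols["training_hours_per_week"][mask] = _trunc_normal(rng, *st["training"],
                                                              *_BOUNDS["training"], k)
        male[mask] = rng.random(k) < st["male_frac"]
        lesion[mask] = rng.random(k) < (0.4 if sp == "rugby" else 0.05)
        # mild sex effect on sprint velocity, centred and variance-absorbed so
        # the per-sport mean and SD still match the published values
        p = st["male_frac"]
        offset = 0.45 * (male[mask].astype(float) - p)
        resid_sd = math.sqrt(max(st["v_mean"][1] ** 2 - 0.45 ** 2 * p * (1 - p), 0.04))
        cols["sprint_v_mean"][mask] = _trunc_normal(
            rng, st["v_mean"][0], resid_sd, *_BOUNDS["v_mean"], k) + offset

    v_mean = np.clip(cols["sprint_v_mean"], *_BOUNDS["v_mean"])
    lin_p30 = np.array([
        p30_equation.per_kg(sport=s, sprint_v_mean=v) for s, v in zip(sport, v_mean)
    ])
    sigma_p30 = float(np.std(lin_p30)) * math.sqrt(max(1.0 - r2_p30, 0.0) / r2_p30)
    p30 = np.maximum(lin_p30 + sigma_p30 * rng.standard_normal(n), 0.1)

    lin_pp = np.array([
        po_peak_equation.per_kg(sport=s, p30_per_kg=p) for s, p in zip(sport, p30)
    ])
    sigma_pp = float(np.std(lin_pp)) * math.sqrt(max(1.0 - r2_po_peak, 0.0) / r2_po_peak)
    po_peak = np.maximum(lin_pp + sigma_pp * rng.standard_normal(n), 0.1)

    # strength: per-sport norms, correlated with the within-sport P30 score
    f_iso = np.empty(n)
    for sp in sports_all:
        mask = sport == sp
        k = int(mask.sum())
        if k == 0:
            continue
        scores = p30[mask]
        z = np.zeros(k) if k < 2 or scores.std() == 0 else (scores - scores.mean()) / scores.std()
        mixed = f_iso_rho * z + math.sqrt(1 - f_iso_rho ** 2) * rng.standard_normal(k)
        mean, sd = SPORT_STATS[sp]["f_iso"]
        f_iso[mask] = np.clip(mean + sd * mixed, *_BOUNDS["f_iso"])

    frame = pd.DataFrame({
        "sport": sport,
        "sex": np.where(male, "male", "female"),
        "male": male.astype(float),
        "age": cols["age"],
        "mass_user": cols["mass_user"],
        "mass_wheelchair": cols["mass_wheelchair"],
        "time_since_injury": cols["time_since_injury"],
        "sport_experience": cols["sport_experience"],
        "training_hours_per_week": cols["training_hours_per_week"],
        "lesion_above_T5": lesion,
        "f_iso": f_iso,
        "f_iso_per_kg": f_iso / cols["mass_user"],
        "sprint_v_mean": v_mean,
        "sprint_v_max": v_mean * 1.30 + rng.normal(0.0, 0.15, n),
        "sprint_po_mean_per_kg": 0.514 * v_mean * (1.0 + rng.normal(0.0, 0.08, n)),
        "sprint_po_max_per_kg": 3.48 * v_mean * (1.0 + rng.normal(0.0, 0.12, n)),
        "p30_per_kg": p30,
        "p5_per_kg": 1.33 * p30 * (1.0 + rng.normal(0.0, 0.05, n)),
        "wingate_po_max_per_kg": 2.2 * p30 * (1.0 + rng.normal(0.0, 0.08, n)),
        "po_peak_per_kg": po_peak,
    })
    if missing_rate > 0:
        for col in ("f_iso_per_kg", "sprint_v_mean", "p30_per_kg", "po_peak_per_kg"):
            frame.loc[rng.random(n) < missing_rate, col] = np.nan
    info = {
        "p30_equation": p30_equation,
        "po_peak_equation": po_peak_equation,
        "p30_noise_sd": sigma_p30,
        "po_peak_noise_sd": sigma_pp,
    }
    return frame, info
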