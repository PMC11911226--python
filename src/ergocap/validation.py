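"""End-to-end protocol validation experiments.

These helpers wire the generators, designers and analyzers into the
closed-loop checks the protocol is built on: does the individualized
Wingate resistance actually deliver the predicted power at the intended rim
velocity, does the graded-exercise staircase place exhaustion inside the
8–12 min validity window for athletes whose true capacity is near the
prediction, and does refitting recover the generating prediction equation
from simulated cohorts.  They are used by the test suite and by the
acceptance script, and are handy for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import constants
from .outcomes import GxtResult, analyze_gxt, analyze_wingate, trim_to_start
from .protocol import EQUATIONS, design_gxt, design_wingate
from .regression import SPORT_TERM, backward_eliminate
from .simulate import (
    DEFAULT_GEOMETRY,
    AthleteGroundTruth,
    synth_cohort,
    synth_gxt_session,
    synth_wingate_trace,
)
from .trace import AthleteProfile, rim_velocity

__all__ = [
    "reference_athlete",
    "wingate_roundtrip",
    "gxt_session_for_ratio",
    "sprint_model_recovery",
]


def reference_athlete(sport: str = "tennis", mass_user: float = 67.0,
                      mass_wheelchair: float = 13.0, age: float = 26.0,
                      f_iso: float = 262.0) -> AthleteGroundTruth:
    """A deterministic mid-cohort athlete used by the worked examples.

    Body mass, age and strength sit at the whole-group means; the true
    anaerobic power is exactly the legacy strength-based prediction, so
    design round-trips close by construction.
    """
    profile = AthleteProfile(mass_user=mass_user, mass_wheelchair=mass_wheelchair,
                             sex="male", age=age, sport=sport)
    p30_kg = EQUATIONS["legacy_strength"].per_kg(f_iso_per_kg=f_iso / mass_user)
    po_peak_kg = EQUATIONS["legacy_wingate"].per_kg(p30_per_kg=p30_kg)
    return AthleteGroundTruth(
        profile=profile,
        true_f_iso=f_iso,
        true_p30=p30_kg * mass_user,
        true_po_peak=po_peak_kg * mass_user,
    )


@dataclass(frozen=True)
class WingateRoundtrip:
    """Closed-loop check of the individualized Wingate resistance."""

    p30_pred: float
    mu: float
    algebraic_power: float        # mu * m * g * v_wheel at the design velocity
    algebraic_rel_error: float
    measured_p30: float           # analyzer output on the simulated test
    dynamic_rel_error: float
    mean_rim_velocity: float


def wingate_roundtrip(gt: AthleteGroundTruth | None = None, seed: int = 0,
                      equation: str = "legacy_strength",
                      steady_start: bool = False,
                      noise: float | None = None) -> WingateRoundtrip:
    """Design the Wingate resistance for an athlete whose true P30 equals the
    prediction, simulate the test, and measure what comes back.

    With ``steady_start`` the simulation starts pre-rolled at the design
    velocity with a flat power envelope (pure steady-state propulsion);
    otherwise it is the default from-standstill test with the fatiguing
    envelope, where a few percent of the energy budget ends up as kinetic
    energy instead of rolling friction.
    """
    gt = reference_athlete() if gt is None else gt
    geom = gt.geometry
    plan = design_wingate(gt.profile, geom, equation=equation,
                          f_iso_per_kg=gt.true_f_iso / gt.profile.mass_user)
    gt = replace(gt, true_p30=plan.p30_pred)
    from .protocol import power_from_resistance, rim_to_wheel_velocity
    v_wheel = rim_to_wheel_velocity(plan.target_rim_velocity, geom)
    algebraic = power_from_resistance(plan.mu, v_wheel, gt.profile.mass_total)
    if steady_start:
        trace = synth_wingate_trace(gt, plan.mu, seed=seed, decay_ratio=1.0,
                                    initial_velocity=v_wheel, noise=noise)
    else:
        trace = synth_wingate_trace(gt, plan.mu, seed=seed, noise=noise)
    result = analyze_wingate(trace)
    tr = trim_to_start(trace)
    n = int(round(constants.WINGATE_DURATION_S * tr.sample_rate))
    mean_rim = float(np.mean(rim_velocity(tr)[:n]))
    return WingateRoundtrip(
        p30_pred=plan.p30_pred,
        mu=plan.mu,
        algebraic_power=algebraic,
        algebraic_rel_error=abs(algebraic - plan.p30_pred) / plan.p30_pred,
        measured_p30=result.p30,
        dynamic_rel_error=abs(result.p30 - plan.p30_pred) / plan.p30_pred,
        mean_rim_velocity=mean_rim,
    )


def gxt_session_for_ratio(ratio: float, seed: int = 0,
                          gt: AthleteGroundTruth | None = None,
                          target_velocity: float = 2.0,
                          p30_meas_per_kg: float | None = None) -> GxtResult:
    """Simulate a GXT for an athlete whose true peak aerobic power is
    ``ratio`` times the predicted one, and analyze it.

    The staircase is designed from the measured P30 through the Wingate-based
    equation; the athlete's true capacity is then set to ``ratio`` x the
    prediction, so ``ratio`` directly probes the duration validity window.
    """
    gt = reference_athlete() if gt is None else gt
    p30_kg = (gt.true_p30 / gt.profile.mass_user
              if p30_meas_per_kg is None else p30_meas_per_kg)
    plan = design_gxt(gt.profile, chosen_velocity=target_velocity,
                      equation="wingate", p30_per_kg=p30_kg)
    gt = replace(gt, true_po_peak=ratio * plan.po_peak_pred)
    trace, breaths = synth_gxt_session(gt, plan, seed=seed)
    return analyze_gxt(trace, plan.stages, gt.profile, breaths=breaths,
                       rpe_peripheral=9.0, rpe_central=8.0,
                       target_velocity=target_velocity)


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery experiment over replicated simulated cohorts."""

    n_replicates: int
    retention_rate: float               # fraction keeping v_mean + sport block
    coverage: dict                      # per-coefficient |est-true| <= 2 SE rate
    min_coverage: float
    r2_values: tuple
    r2_in_range_rate: float


def sprint_model_recovery(n_replicates: int = 200, n: int = 43, seed: int = 0,
                          r2: float = 0.84,
                          r2_range: tuple[float, float] = (0.74, 0.92)) -> RecoveryReport:
    """Refit the sprint-based anaerobic-power equation on simulated cohorts.

    Each replicate draws a cohort of ``n`` athletes whose ``p30_per_kg``
    follows the sport-aware sprint equation with noise calibrated to the
    target R², then runs backward elimination on the screened predictor set
    (sprint v_mean plus the sport dummy block).  Reports how often both
    terms survive, the per-coefficient rate at which the generating value
    lies within two standard errors of the estimate, and the refitted R²
    distribution.
    """
    truth = dict(EQUATIONS["sprint"].coefficients)
    truth["const"] = EQUATIONS["sprint"].intercept
    hits = {k: 0 for k in truth}
    totals = {k: 0 for k in truth}
    retained = 0
    r2_values = []
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cohort, _ = synth_cohort(n=n, seed=int(rng.integers(2 ** 31)), r2_p30=r2)
        model = backward_eliminate(cohort, "p30_per_kg",
                                   ["sprint_v_mean", SPORT_TERM])
        r2_values.append(model.r_squared)
        if not ("sprint_v_mean" in model.terms and SPORT_TERM in model.terms):
            continue
        retained += 1
        for name, true_val in truth.items():
            coef = (model.intercept if name == "const"
                    else model.coefficients.get(name))
            if coef is None:
                continue
            totals[name] += 1
            if abs(coef.estimate - true_val) <= 2.0 * coef.se:
                hits[name] += 1
    coverage = {k: (hits[k] / totals[k] if totals[k] else float("nan"))
                for k in truth}
    r2_arr = np.asarray(r2_values)
    in_range = float(np.mean((r2_arr >= r2_range[0]) & (r2_arr <= r2_range[1])))
    return RecoveryReport(
        n_replicates=n_replicates,
        retention_rate=retained / n_replicates,
        coverage=coverage,
        min_coverage=min(coverage.values()),
        r2_values=tuple(r2_values),
        r2_in_range_rate=in_range,
    )
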