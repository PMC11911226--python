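"""Individualized resistance settings for the Wingate and graded exercise tests.

The protocol chain works in two prediction steps.  Measured strength or
sprint performance predicts the athlete's 30-s anaerobic power (P30), which
fixes the Wingate rolling-resistance coefficient so the predicted power is
dissipated at a mean rim velocity of 2 m/s.  The measured P30 then predicts
peak aerobic power (PO_peak), which fixes the graded exercise test (GXT)
staircase: the first stage loads 20% of the predicted peak and every minute
adds 10% of the gap between start load and predicted peak, so a correct
prediction exhausts the athlete around minute 10.

All published equations live in the :data:`EQUATIONS` registry.  The
"legacy" pair is the original strength-based P30 equation and the P30-based
PO_peak equation; the remaining entries are the sport-aware refits on elite
wheelchair athletes (sport enters as three dummies with tennis as the
reference).  Per-kg predictions are converted to absolute watts with the
athlete's body mass (wheelchair mass enters only through the resistance
coefficient, which is normalized by total supported weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import constants
from .trace import AthleteProfile, WheelGeometry

__all__ = [
    "PredictionEquation",
    "Prediction",
    "GxtStage",
    "WingatePlan",
    "GxtPlan",
    "ProtocolPlan",
    "EQUATIONS",
    "DUMMY_SPORTS",
    "predict_p30",
    "predict_po_peak",
    "rim_to_wheel_velocity",
    "wheel_to_rim_velocity",
    "resistance_coefficient",
    "power_from_resistance",
    "design_wingate",
    "design_gxt",
]

#: Sport dummy variables; tennis is the reference category (all zeros).
DUMMY_SPORTS = ("racing", "basketball", "rugby")


@dataclass(frozen=True)
class PredictionEquation:
    """An affine per-kg prediction equation with optional sport dummies.

    ``coefficients`` maps predictor names (e.g. ``"sprint_v_mean"``,
    ``"f_iso_per_kg"``, ``"p30_per_kg"``) or dummy names (``"racing"``,
    ``"basketball"``, ``"rugby"``) to weights.  ``intercept`` and the result
    are in W/kg; force predictors are in N/kg, velocities in m/s.
    """

    name: str
    response: str
    intercept: float
    coefficients: Mapping[str, float]
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def required_inputs(self) -> tuple[str, ...]:
        """Continuous predictors the caller must supply (dummies come from sport)."""
        return tuple(k for k in self.coefficients if k not in DUMMY_SPORTS)

    @property
    def uses_sport(self) -> bool:
        return any(k in DUMMY_SPORTS for k in self.coefficients)

    def per_kg(self, sport: str | None = None, **inputs: float) -> float:
        """Evaluate the equation; returns the per-kg prediction (W/kg)."""
        value = self.intercept
        for name, coef in self.coefficients.items():
            if name in DUMMY_SPORTS:
                if sport is None:
                    raise ValueError(f"equation {self.name!r} needs the athlete's sport")
                if sport not in ("tennis",) + DUMMY_SPORTS:
                    raise ValueError(f"unknown sport {sport!r}")
                value += coef * (1.0 if sport == name else 0.0)
            else:
                if name not in inputs or inputs[name] is None:
                    raise ValueError(f"equation {self.name!r} requires predictor {name!r}")
                value += coef * float(inputs[name])
        return value


#: Registry of the published prediction equations, keyed by the test that
#: supplies the predictor.  ``legacy_*`` entries are the original equations;
#: the others are the sport-aware refits (tennis reference).
EQUATIONS: dict[str, PredictionEquation] = {
    "legacy_strength": PredictionEquation(
        "legacy_strength", "p30_per_kg", -0.18, {"f_iso_per_kg": 0.51}, 0.75
    ),
    "strength": PredictionEquation(
        "strength", "p30_per_kg", 0.11,
        {"f_iso_per_kg": 0.50, "racing": 0.70, "basketball": -0.22, "rugby": -0.22},
        0.74,
    ),
    "sprint": PredictionEquation(
        "sprint", "p30_per_kg", -1.19,
        {"sprint_v_mean": 1.02, "racing": -0.59, "basketball": -0.26, "rugby": -0.15},
        0.84,
    ),
    "legacy_wingate": PredictionEquation(
        "legacy_wingate", "po_peak_per_kg", 0.11, {"p30_per_kg": 0.67}, 0.81
    ),
    "wingate": PredictionEquation(
        "wingate", "po_peak_per_kg", 0.56,
        {"p30_per_kg": 0.47, "racing": -0.35, "basketball": -0.01, "rugby": -0.37},
        0.78,
    ),
    "strength_aerobic": PredictionEquation(
        "strength_aerobic", "po_peak_per_kg", 0.47,
        {"f_iso_per_kg": 0.27, "racing": -0.01, "basketball": -0.10, "rugby": -0.45},
        0.71,
    ),
    "sprint_aerobic": PredictionEquation(
        "sprint_aerobic", "po_peak_per_kg", 0.38,
        {"sprint_v_mean": 0.38, "racing": -0.62, "basketball": -0.20, "rugby": -0.52},
        0.64,
    ),
}


class Prediction(dict):
    """Tiny result container: ``per_kg`` (W/kg) and ``watts`` (W)."""

    def __init__(self, per_kg: float, watts: float):
        super().__init__(per_kg=per_kg, watts=watts)
        self.per_kg = per_kg
        self.watts = watts


def _resolve(equation: str | PredictionEquation) -> PredictionEquation:
    if isinstance(equation, PredictionEquation):
        return equation
    try:
        return EQUATIONS[equation]
    except KeyError:
        raise ValueError(f"unknown equation {equation!r}; registry has {sorted(EQUATIONS)}")


def predict_p30(profile: AthleteProfile, equation: str | PredictionEquation = "sprint",
                **inputs: float) -> Prediction:
    """Predict 30-s anaerobic power from strength or sprint inputs.

    Supply ``f_iso_per_kg`` (N/kg) for the strength equations or
    ``sprint_v_mean`` (m/s) for the sprint equation.  Returns the per-kg
    prediction and the absolute wattage (per-kg times body mass).
    """
    eq = _resolve(equation)
    per_kg = eq.per_kg(sport=profile.sport, **inputs)
    return Prediction(per_kg, per_kg * profile.mass_user)


def predict_po_peak(profile: AthleteProfile, equation: str | PredictionEquation = "wingate",
                    **inputs: float) -> Prediction:
    """Predict peak aerobic power from P30, strength or sprint inputs."""
    eq = _resolve(equation)
    per_kg = eq.per_kg(sport=profile.sport, **inputs)
    return Prediction(per_kg, per_kg * profile.mass_user)


def rim_to_wheel_velocity(v_rim: float, geometry: WheelGeometry) -> float:
    """Convert a handrim-frame velocity to the wheel (tire) frame."""
    return v_rim * geometry.wheel_radius / geometry.rim_radius


def wheel_to_rim_velocity(v_wheel: float, geometry: WheelGeometry) -> float:
    """Convert a wheel-frame velocity to the handrim frame."""
    return v_wheel * geometry.rim_radius / geometry.wheel_radius


def resistance_coefficient(power: float, v_wheel: float, mass_total: float) -> float:
    """Rolling-resistance coefficient dissipating ``power`` at ``v_wheel``.

    ``mu = P / (v_wheel * m_total * g)``: the dimensionless ratio of
    resistive force to the supported weight ``m_total * g``.
    """
    if power <= 0 or v_wheel <= 0 or mass_total <= 0:
        raise ValueError("power, v_wheel and mass_total must all be positive")
    return power / (v_wheel * mass_total * constants.G)


def power_from_resistance(mu: float, v_wheel: float, mass_total: float) -> float:
    """Power dissipated against rolling resistance ``mu`` at ``v_wheel`` (W)."""
    if mu <= 0 or v_wheel <= 0 or mass_total <= 0:
        raise ValueError("mu, v_wheel and mass_total must all be positive")
    return mu * mass_total * constants.G * v_wheel


@dataclass(frozen=True)
class GxtStage:
    """One minute of the GXT staircase: 1-based index, power (W), resistance."""

    index: int
    power: float
    mu: float


@dataclass(frozen=True)
class WingatePlan:
    """Predicted P30 and the Wingate resistance achieving it at 2 m/s rim."""

    p30_pred: float
    p30_pred_per_kg: float
    mu: float
    target_rim_velocity: float
    equation: str


@dataclass(frozen=True)
class GxtPlan:
    """Predicted PO_peak and the per-stage GXT resistance staircase."""

    po_peak_pred: float
    po_peak_pred_per_kg: float
    target_velocity: float
    stages: tuple[GxtStage, ...]
    equation: str

    def __post_init__(self) -> None:
        powers = [s.power for s in self.stages]
        if any(b <= a for a, b in zip(powers, powers[1:])):
            raise ValueError("stage powers must be strictly increasing")


@dataclass(frozen=True)
class ProtocolPlan:
    """Combined individualized plan for one athlete."""

    wingate: WingatePlan | None = None
    gxt: GxtPlan | None = None


def design_wingate(profile: AthleteProfile, geometry: WheelGeometry,
                   equation: str | PredictionEquation = "sprint",
                   target_rim_velocity: float = constants.WINGATE_TARGET_RIM_VELOCITY,
                   **inputs: float) -> WingatePlan:
    """Choose the Wingate resistance from a strength or sprint prediction.

    The coefficient is set so that the predicted P30 is dissipated at a mean
    rim velocity of ``target_rim_velocity`` (default 2 m/s, keeping peak hand
    speed below the 3 m/s coordination limit).
    """
    eq = _resolve(equation)
    pred = predict_p30(profile, eq, **inputs)
    v_wheel = rim_to_wheel_velocity(target_rim_velocity, geometry)
    mu = resistance_coefficient(pred.watts, v_wheel, profile.mass_total)
    return WingatePlan(pred.watts, pred.per_kg, mu, target_rim_velocity, eq.name)


def design_gxt(profile: AthleteProfile, chosen_velocity: float,
               equation: str | PredictionEquation = "wingate",
               n_stages: int = 15,
               start_fraction: float = constants.GXT_START_FRACTION,
               increment_fraction: float = constants.GXT_INCREMENT_FRACTION,
               **inputs: float) -> GxtPlan:
    """Build the GXT staircase from a PO_peak prediction.

    Stage ``k`` (1-based, one minute each) loads
    ``P * (start + (k-1) * increment * (1 - start))`` watts, i.e. 20% of the
    predicted peak plus 8% per completed stage with the default fractions;
    the per-stage resistance dissipates that power at the athlete's chosen
    (wheel-frame) velocity.  ``inputs`` feeds the prediction equation, e.g.
    ``p30_per_kg=...`` for the Wingate-based equation.
    """
    if chosen_velocity <= 0:
        raise ValueError("chosen_velocity must be positive")
    eq = _resolve(equation)
    pred = predict_po_peak(profile, eq, **inputs)
    if pred.watts <= 0:
        raise ValueError("predicted PO_peak must be positive to design a staircase")
    step = increment_fraction * (1.0 - start_fraction)
    stages = []
    for k in range(1, n_stages + 1):
        power = pred.watts * (start_fraction + step * (k - 1))
        mu = resistance_coefficient(power, chosen_velocity, profile.mass_total)
        stages.append(GxtStage(k, power, mu))
    return GxtPlan(pred.watts, pred.per_kg, chosen_velocity, tuple(stages), eq.name)
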