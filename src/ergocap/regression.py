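"""Model construction and prediction-evaluation machinery.

Rebuilds the procedure used to derive the sport-aware prediction equations
from a tested cohort:

1. :func:`univariate_screen` — keep candidate predictors with a univariate
   association at p < 0.10 (practiced sport enters as a block of three
   dummies, tennis reference, tested jointly), ranked by R²;
2. :func:`collinearity_prune` — within a declared family of near-duplicate
   measures (the sprint outcomes; the Wingate outcomes) with pairwise
   |r| > 0.8, keep only the member with the highest univariate R²;
3. :func:`backward_eliminate` — drop the least significant term until every
   unprotected term satisfies p < 0.05; the sport dummy block is kept or
   dropped as one unit via its joint F-test.

Plus the predicted-vs-measured machinery: Shapiro–Wilk-gated paired t /
Wilcoxon comparison (:func:`compare_pred_meas`), mean percent difference,
and ±20% deviation boundaries around the line of identity
(:func:`deviation_bounds`, :func:`plot_identity_scatter`).

The cohort is an ordinary :class:`pandas.DataFrame`, one row per athlete,
with force/power variables expressed per kilogram body mass and a ``sport``
column; missing values are handled complete-case per model with the used n
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .protocol import DUMMY_SPORTS, PredictionEquation

__all__ = [
    "ScreenResult",
    "Coefficient",
    "FittedModel",
    "PairedComparison",
    "DeviationBounds",
    "SPORT_TERM",
    "sport_dummies",
    "univariate_screen",
    "collinearity_prune",
    "backward_eliminate",
    "compare_pred_meas",
    "percent_difference",
    "deviation_bounds",
    "classify_deviations",
    "plot_identity_scatter",
]

#: Name under which the categorical sport block is referred to in term lists.
SPORT_TERM = "sport"


def sport_dummies(sport: pd.Series) -> pd.DataFrame:
    """Dummy-code practiced sport with tennis as the reference category."""
    return pd.DataFrame(
        {name: (sport == name).astype(float) for name in DUMMY_SPORTS},
        index=sport.index,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Univariate association of one candidate with the response."""

    name: str
    r_squared: float
    p_value: float
    n_used: int
    kept: bool
    note: str = ""


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    p_value: float


@dataclass(frozen=True)
class FittedModel:
    """Final multivariable fit: terms, per-coefficient stats, R², n."""

    response: str
    terms: tuple[str, ...]
    intercept: Coefficient
    coefficients: Mapping[str, Coefficient]
    r_squared: float
    n_used: int
    sport_block_p: float | None = None

    def to_equation(self, name: str) -> PredictionEquation:
        """Package the fit as a usable per-kg prediction equation."""
        return PredictionEquation(
            name=name,
            response=self.response,
            intercept=self.intercept.estimate,
            coefficients={k: c.estimate for k, c in self.coefficients.items()},
            r_squared=min(max(self.r_squared, 0.0), 1.0),
        )

    def report(self) -> str:
        """Human-readable equation report (coefficients, p-values, R², n)."""
        lines = [f"{self.response} ="]
        lines.append(f"  {self.intercept.estimate:+.3f}"
                     f"    (p = {self.intercept.p_value:.3g})")
        for term, coef in self.coefficients.items():
            lines.append(f"  {coef.estimate:+.3f} x {term}"
                         f"    (p = {coef.p_value:.3g})")
        if self.sport_block_p is not None:
            lines.append(f"  sport block joint p = {self.sport_block_p:.3g}")
        lines.append(f"  cumulative R^2 = {self.r_squared:.2f}, n = {self.n_used}")
        return "\n".join(lines)


def _design_columns(cohort: pd.DataFrame, term: str) -> pd.DataFrame:
    if term == SPORT_TERM:
        return sport_dummies(cohort[SPORT_TERM])
    col = cohort[term]
    if col.dtype == bool:
        col = col.astype(float)
    return col.to_frame(term).astype(float)


def _fit_ols(cohort: pd.DataFrame, response: str, terms: Sequence[str]):
    """Complete-case OLS fit; returns (results, X, n_used)."""
    pieces = [_design_columns(cohort, t) for t in terms]
    frame = pd.concat([cohort[response].astype(float).rename(response), *pieces], axis=1)
    frame = frame.dropna()
    y = frame[response]
    X = sm.add_constant(frame.drop(columns=[response]), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    return sm.OLS(y, X).fit(), X, len(frame)


def _find_aliased(X: pd.DataFrame) -> list[str]:
    kept: list[str] = []
    aliased: list[str] = []
    arr = X.to_numpy()
    cols: list[np.ndarray] = []
    for i, name in enumerate(X.columns):
        trial = cols + [arr[:, i]]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial):
            cols.append(arr[:, i])
            kept.append(name)
        else:
            aliased.append(name)
    return aliased


def _term_p_value(res, term: str) -> float:
    if term == SPORT_TERM:
        names = [d for d in DUMMY_SPORTS if d in res.params.index]
        R = np.zeros((len(names), len(res.params)))
        for i, name in enumerate(names):
            R[i, list(res.params.index).index(name)] = 1.0
        return float(res.f_test(R).pvalue)
    return float(res.pvalues[term])


def univariate_screen(cohort: pd.DataFrame, response: str,
                      candidates: Sequence[str],
                      alpha_in: float = 0.10) -> list[ScreenResult]:
    """Simple linear fit of the response on each candidate separately.

    Sport is tested as a joint three-dummy block.  Candidates with p <
    ``alpha_in`` are marked kept; constant (degenerate) candidates are
    excluded with a warning note.  Results come back ranked by R²
    (descending), which is also the priority order for collinearity pruning.
    """
    results = []
    for cand in candidates:
        cols = _design_columns(cohort, cand)
        paired = pd.concat([cohort[response].astype(float), cols], axis=1).dropna()
        n = len(paired)
        if n < 3:
            results.append(ScreenResult(cand, float("nan"), float("nan"), n, False,
                                        "fewer than 3 complete pairs"))
            continue
        if float(paired.iloc[:, 1:].to_numpy().std()) == 0.0:
            results.append(ScreenResult(cand, 0.0, 1.0, n, False, "degenerate (constant)"))
            continue
        res, _, n_used = _fit_ols(cohort, response, [cand])
        p = _term_p_value(res, cand)
        results.append(ScreenResult(cand, float(res.rsquared), p, n_used, p < alpha_in))
    return sorted(results, key=lambda r: (-(r.r_squared if math.isfinite(r.r_squared) else -1.0)))


def collinearity_prune(cohort: pd.DataFrame, screened: Sequence[ScreenResult],
                       families: Mapping[str, Sequence[str]],
                       threshold: float = 0.8) -> list[str]:
    """Drop near-duplicate family members, keeping the best-associated one.

    Within each declared family (e.g. the sprint outcomes, the Wingate
    outcomes), members whose pairwise |r| with an already-kept family member
    exceeds ``threshold`` are dropped; priority follows univariate R².
    Candidates outside any family pass through untouched.
    """
    kept_names: list[str] = []
    member_of = {m: fam for fam, members in families.items() for m in members}
    ranked = [s for s in screened if s.kept]
    for result in ranked:  # already R²-descending
        fam = member_of.get(result.name)
        if fam is None:
            kept_names.append(result.name)
            continue
        clash = False
        for other in kept_names:
            if member_of.get(other) != fam:
                continue
            pair = cohort[[result.name, other]].dropna()
            r = float(pair[result.name].corr(pair[other]))
            if abs(r) > threshold:
                clash = True
                break
        if not clash:
            kept_names.append(result.name)
    return kept_names


def backward_eliminate(cohort: pd.DataFrame, response: str,
                       predictors: Sequence[str],
                       alpha_out: float = 0.05,
                       protected: Iterable[str] = ()) -> FittedModel:
    """Backward elimination until all unprotected terms have p < ``alpha_out``.

    The sport block is treated as a single term: its joint F-test p-value
    decides whether the whole block stays or goes.  Protected terms are
    never dropped.  Raises on a rank-deficient design, naming the aliased
    columns.
    """
    terms = list(dict.fromkeys(predictors))
    protected = set(protected)
    if not terms:
        raise ValueError("need at least one predictor")
    while True:
        res, X, n_used = _fit_ols(cohort, response, terms)
        p_values = {t: _term_p_value(res, t) for t in terms}
        droppable = {t: p for t, p in p_values.items()
                     if t not in protected and p >= alpha_out}
        if not droppable or len(terms) == 1:
            break
        worst = max(droppable, key=droppable.get)
        terms.remove(worst)
    coefs: dict[str, Coefficient] = {}
    for term in terms:
        names = DUMMY_SPORTS if term == SPORT_TERM else (term,)
        for name in names:
            coefs[name] = Coefficient(
                float(res.params[name]), float(res.bse[name]), float(res.pvalues[name])
            )
    return FittedModel(
        response=response,
        terms=tuple(terms),
        intercept=Coefficient(float(res.params["const"]), float(res.bse["const"]),
                              float(res.pvalues["const"])),
        coefficients=coefs,
        r_squared=float(res.rsquared),
        n_used=n_used,
        sport_block_p=p_values.get(SPORT_TERM),
    )


# ---------------------------------------------------------------------------
# predicted vs measured


@dataclass(frozen=True)
class PairedComparison:
    test: str                 # "paired_t", "wilcoxon" or "identity"
    statistic: float
    p_value: float
    mean_percent_diff: float
    shapiro_p: float | None


def percent_difference(pred: np.ndarray, meas: np.ndarray,
                       denominator: np.ndarray | None = None) -> np.ndarray:
    """Per-athlete percent difference ``100 * (pred - meas) / denominator``.

    The denominator defaults to the measured value; passing it explicitly
    makes the quantity antisymmetric under swapping pred and meas.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    denom = meas if denominator is None else np.asarray(denominator, dtype=float)
    return 100.0 * (pred - meas) / denom


def compare_pred_meas(pred: Sequence[float], meas: Sequence[float],
                      alpha: float = 0.05) -> PairedComparison:
    """Systematic-difference test between predicted and measured values.

    The paired differences are checked for normality with Shapiro–Wilk at
    ``alpha``; normal differences use a paired t-test, otherwise a Wilcoxon
    signed-rank test.  Also reports the mean percent difference (measured
    value as denominator).  Identical inputs short-circuit to an identity
    report with no test.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape or pred.size < 3:
        raise ValueError("pred and meas must have equal length >= 3")
    diffs = pred - meas
    pct = float(np.mean(percent_difference(pred, meas)))
    if np.all(diffs == 0.0):
        return PairedComparison("identity", 0.0, 1.0, 0.0, None)
    shapiro_p = float(stats.shapiro(diffs).pvalue)
    if shapiro_p >= alpha:
        t = stats.ttest_rel(pred, meas)
        return PairedComparison("paired_t", float(t.statistic), float(t.pvalue), pct, shapiro_p)
    w = stats.wilcoxon(pred, meas)
    return PairedComparison("wilcoxon", float(w.statistic), float(w.pvalue), pct, shapiro_p)


@dataclass(frozen=True)
class DeviationBounds:
    """±tolerance band around one predicted value."""

    pred: float
    lower: float
    upper: float

    def classify(self, meas: float) -> str:
        if meas > self.upper:
            return "above"
        if meas < self.lower:
            return "below"
        return "within"


def deviation_bounds(pred: float, tolerance: float = 0.20) -> DeviationBounds:
    """Deviation boundaries ``pred * (1 ± tolerance)`` around the identity line."""
    if pred <= 0:
        raise ValueError("pred must be positive")
    return DeviationBounds(pred, pred * (1.0 - tolerance), pred * (1.0 + tolerance))


def classify_deviations(pred: Sequence[float], meas: Sequence[float],
                        tolerance: float = 0.20) -> list[str]:
    """Classify each measured value against its prediction's ±tolerance band."""
    return [deviation_bounds(p, tolerance).classify(m) for p, m in zip(pred, meas)]


def plot_identity_scatter(pred: Sequence[float], meas: Sequence[float],
                          tolerance: float = 0.20, ax=None,
                          xlabel: str = "predicted (W)",
                          ylabel: str = "measured (W)",
                          path=None):
    """Predicted-vs-measured scatter with identity line and ±tolerance bounds."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pred, meas, s=18, alpha=0.8, edgecolor="none")
    hi = 1.05 * max(float(pred.max()), float(meas.max()))
    line = np.array([0.0, hi])
    ax.plot(line, line, ls=":", c="k", lw=1, label="identity")
    ax.plot(line, (1 + tolerance) * line, c="0.4", lw=1, label=f"±{tolerance:.0%}")
    ax.plot(line, (1 - tolerance) * line, c="0.4", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_xlim(0, hi)
    ax.set_ylim(0, hi)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
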