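# Methods

This note documents the models, conventions and numerical choices behind
`ergocap`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signals and conventions

An ergometer session is a time-aligned record of per-side wheel torque
(N·m) and wheel velocity (m/s), nominally uniform at 100 Hz.  Loading
rejects gaps, non-monotone time and spacing jitter beyond 1% of the sample
interval rather than resampling: a resampling policy would silently change
rolling-window outcomes, and malformed recordings are better surfaced than
repaired.  Side combination is fixed package-wide: force and velocity are
the mean of left and right, power is the sum of both arms.

Conditioning uses a 4th-order low-pass Butterworth filter with a 10 Hz
cutoff, applied forward and backward (`sosfiltfilt`).  The zero-phase
choice matters because several outcomes are peak *locations* (single-sample
power and velocity peaks, window placement); a causal filter would lag them
by tens of milliseconds.  The price is that the effective magnitude
response is the squared one-pass response, which the filter tests assert
explicitly.

Rolling means use windows of `round(window · rate)` samples (ties round
half up) and only fully populated windows are eligible for maxima, so a
3-s maximum can never be produced by a partially covered window at an edge.

From-standstill tests (sprint, WAnT) are trimmed to the first sample whose
summed power exceeds 2% of the trace-wide peak.  Real recordings include an
idle lead-in of arbitrary length; anchoring t = 0 at the effective start
makes the 10-s and 30-s analysis windows comparable across sessions.  The
threshold is configurable; 2% sits well below any plausible push power and
well above sensor noise.

## Outcome definitions and validity gating

* **Isometric strength** — highest 3-s rolling mean of the side-averaged
  rim force over up to three 5-s trials.  A saturation heuristic flags the
  result when the force signal sits within 0.5% of its own maximum for more
  than half of the winning window, the signature of an ergometer brake
  limit being hit rather than a human force plateau.  The flag annotates,
  never rejects: an athlete clipped by the hardware still gets a (known to
  be underestimated) strength value, which is what the downstream
  resistance design has to work with.
* **Sprint** — mean and single-sample peak power and velocity over the
  first 10 s; of the two trials, the one with the higher peak velocity is
  reported.
* **WAnT** — P30 (30-s mean power), P5 (highest 5-s rolling mean),
  single-sample peak power, and peak rim velocity
  (side-averaged wheel velocity scaled by `r_r / r_w`).  Valid iff the peak
  rim velocity stays strictly below 3.0 m/s; exactly 3.0 is invalid.
* **GXT** — duration to the termination point, defined as the first moment
  the side-averaged velocity drops more than 0.28 m/s below the target
  velocity and stays there for a dwell time (3 s default; the dwell guards
  against a single slow push registering as exhaustion, and the reported
  time is the start of the dwell, not its end).  PO_peak is the highest
  30-s rolling mean of summed power over windows lying fully inside the
  final one-minute stage block that was entered; if fewer than 30 s of that
  block were recorded, the last completed stage is used instead.  V̇O2peak
  and RER_peak are the highest trailing 30-s means of the breath-by-breath
  channel (V̇O2 normalized by body mass only, not chair mass); HR_peak is a
  single-sample maximum; overall RPE is the mean of the peripheral and
  central ratings.

Duration validity uses the inclusive 8–12 min window evaluated on the
duration rounded to 0.1 min, the protocol's reporting precision.  The
rounding is deliberate: termination is detected a fraction of a second
*after* the velocity is lost, so an athlete who exactly completes stage 12
would otherwise be flagged invalid at 12.002 min.  At reporting precision
the boundaries behave as intended: 8.0 and 12.0 are valid, 7.9 and 12.1 are
not.

Secondary maximality criteria: RER ≥ 1.10, HR ≥ 0.95·(200 − age), overall
RPE ≥ 8; met overall when two of three hold.  For lesions above T5 the HR
criterion is excluded (impaired sympathetic cardiac drive caps heart rate)
and both remaining criteria must hold.  The RPE criterion is evaluated on
the overall (mean) score; evaluating it on either sub-score alone would be
a defensible alternative reading, and the choice is isolated in
`check_secondary_criteria`.

## Protocol design

Predictions are affine per-kg equations (see `README.md`), kept at full
precision internally; rounding to whole watts happens only in reports.
Sport enters as three dummies with tennis as the reference.  The default
equation set is the sport-aware pair (sprint → P30, Wingate → PO_peak); the
legacy strength-based and P30-based equations remain selectable for
comparison work.

The resistance coefficient resolves a dimensional subtlety: μ is the ratio
of resistive force to supported *weight*, so
`mu = P / (v_wheel · m_total · g)` with g = 9.80665 m/s².  This is
consistent with the quoted court coefficient μ = 0.012 being a standard
rolling-resistance number.  Total mass is athlete plus wheelchair, both
required inputs.  The GXT staircase loads
`P_pred · (0.20 + 0.08·(k − 1))` W at stage k; stage 1 lasts a full minute
before the first increment, and stage power first reaches the prediction at
stage 11.  The chosen GXT velocity is a free input in the wheel frame
(court athletes typically 1.4–2.5 m/s, racing athletes far higher) and the
per-stage μ dissipates the stage power at exactly that velocity.

## Regression toolkit

Model construction mirrors the protocol's build procedure on a cohort
table (one row per athlete, force/power per kg body mass):

1. univariate screen at p < 0.10, sport tested as a joint three-dummy
   block; degenerate candidates are excluded with a note;
2. collinearity pruning inside declared families (sprint outcomes; WAnT
   outcomes): among members with pairwise |r| > 0.8, only the highest
   univariate R² survives;
3. backward elimination at p < 0.05.  The sport block is kept or dropped
   as one unit via its joint F-test — this is why individually
   non-significant dummies can legitimately appear in a final equation.
   Protected terms are never dropped.  Rank-deficient designs raise an
   error naming the aliased columns.

Missing values are handled complete-case per model with the used n
reported.  Predicted-vs-measured comparison gates a paired t-test on a
Shapiro–Wilk normality check of the paired differences (Wilcoxon
signed-rank otherwise) and reports the mean percent difference with the
*measured* value as denominator — the denominator convention is explicit
because the quantity is only antisymmetric under swapping prediction and
measurement when the denominator is held fixed.  Deviation boundaries are
`pred · (1 ± 0.20)`, the band implied by the 10 ± 2 min target duration.

## Synthetic data

The generator emulates the study conditions, not arbitrary signals; its
defaults are the conditions the analyzers are validated under.

* **Isometric trials**: ramp–plateau–release force profiles; the best of
  three trials plateaus exactly at the true strength, the others 1–5%
  lower; multiplicative noise (3% default).  An optional force limit clips
  the plateau, reproducing brake saturation for the saturation-flag tests.
* **Sprint**: forward integration of
  `m_total · dv/dt = F_prop − mu · m_total · g` at court resistance
  (μ = 0.012) under half-sine rim-force pulses (1 Hz court / 1.5 Hz racing
  cadence, 50% duty).  The pulse amplitude is calibrated by a damped
  log-space secant iteration — delivered power grows faster than
  quadratically with amplitude, so naive proportional updates diverge —
  until the 10-s mean power approximates the target (default 0.9 × true
  P30, the typical sprint-to-WAnT power ratio).  The integrator uses five
  Euler substeps per recorded sample; the energy identity (applied work =
  kinetic energy + friction losses) closes within 1% on the recorded trace.
* **WAnT**: the athlete is a power source tracking a linearly fatiguing
  envelope with mean true P30 and start/end ratio 1.6, shaped into
  half-sine pulses whose per-cycle mean equals the envelope; torque is
  force-limited (≈2.5 × isometric strength) so spin-up from standstill is
  physical.  One modelling fact matters for round-trip expectations: from a
  standing start, the kinetic energy stored in the moving mass
  (½·m·v² ≈ 3–4% of the 30-s energy budget at court velocities) is
  delivered by the athlete but not dissipated by rolling friction, so the
  mean rim velocity under the designed resistance lands ~3% below the 2 m/s
  design point.  The package therefore validates the design twice: a
  pre-rolled steady-state simulation (flat envelope, initial velocity at
  the design point) reproduces 2.0 m/s within ±0.05, and the realistic
  from-standstill test dissipates the predicted P30 and holds the design
  velocity within 5%.
* **GXT**: the athlete holds the target velocity through every stage whose
  demand stays within the true PO_peak and collapses (velocity decaying
  with a 0.6 s time constant) upon entering the first over-capacity stage,
  so the measured duration equals the number of sustainable stages to
  within ~0.1 s.  Breath data follow first-order V̇O2 kinetics (τ = 25 s)
  toward the implied V̇O2peak, RER drifts above 1.10 near exhaustion and HR
  approaches 97% of (200 − age) (75% with a lesion above T5).
* **Cohorts**: sport composition is fixed at the study proportions
  (11/9/12/11 of 43, largest-remainder rounding for other n); mass, age,
  demographics and sprint velocity are truncated normals at the per-sport
  published means/SDs (bounds: mass 35–120 kg, v 1.5–7 m/s — realism
  guards, not protocol values).  A small sex effect on sprint velocity
  (+0.45 m/s for male athletes) is centred and variance-absorbed so the
  per-sport moments still match.  P30/kg follows the sport-aware sprint
  equation plus Gaussian noise whose SD is calibrated against the realized
  linear-predictor SD so the population R² hits the target (0.84 default;
  an R² target of 1 gives exact interpolation); PO_peak/kg likewise
  (target 0.78).  Isometric strength is drawn from the per-sport norms but
  correlated (ρ = 0.8) with the athlete's within-sport anaerobic-power
  score: individual departures from the sprint equation are treated as
  biological (shared with strength), which keeps strength an informative
  but weaker predictor, as observed in testing.  Sprint and WAnT outcome
  families are internally collinear (|r| > 0.8) by construction so the
  pruning rule has something real to do.

All generators are deterministic given their seed, and seeds never alter
ground-truth parameters.

## Problem sizes and numerics

The test suite validates rolling-window outcomes against exhaustive
brute-force scans on 1000 random traces sampled at 10 Hz (full-rate
100 Hz traces are used wherever absolute timing matters); the
parameter-recovery experiment runs 200 replicates of n = 43; the whole
suite completes in a few seconds.  The recovery experiment reports
per-coefficient two-standard-error coverage and the refitted R²
distribution; one structural finding worth knowing is that the sport
block's partial contribution beyond sprint velocity is small under the
generating conditions (partial R² ≈ 0.05), so its joint F-test at n = 43
retains it in most but not all replicates — on a single real cohort of this
size, a non-significant sport block would not by itself contradict the
generating model.

Floating-point ordering invariants (peak ≥ 5-s mean ≥ 30-s mean) are
enforced with a 10⁻⁹ relative tolerance; trace serialization uses
shortest-round-trip float text and parses with round-trip precision, so
write∘read is bit-exact.

## Limitations

The synthetic traces idealize propulsion: symmetric sides by default,
half-sine pulses, no push-rim contact mechanics, no roller or wheel
rotational inertia (the chair-plus-athlete mass carries all kinetic
energy), and breath noise far tamer than a real metabolic cart.  Passing
round-trip tests therefore demonstrates that the analyzers implement their
definitions correctly and that the protocol design is self-consistent — not
that the prediction equations are accurate for any new athlete population,
which only a validation study on measured data can show.  The regression
toolkit deliberately implements plain OLS machinery (no robust or mixed
alternatives, no cross-validation), matching the procedure it reconstructs.
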