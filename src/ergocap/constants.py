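"""Registry of protocol constants.

Every threshold and rule parameter of the standardized wheelchair
(an)aerobic capacity test battery lives here, so that a single audit point
covers the whole pipeline.  The prediction-equation coefficients themselves
are registered in :mod:`ergocap.protocol` (``EQUATIONS``), next to the code
that evaluates them.

All values are SI unless noted.  Velocities distinguish the *rim* frame
(linear speed at the handrim, radius ``r_r``) from the *wheel* frame (linear
speed at the tire, radius ``r_w``); the two are related by the radius ratio.
"""

#: Standard gravitational acceleration (m s^-2).  The rolling-resistance
#: coefficient is the ratio of resistive force to supported weight
#: ``m_total * G``, so G enters every resistance computation.
G = 9.80665

#: Nominal ergometer sampling frequency (Hz) for torque and velocity.
SAMPLE_RATE_HZ = 100.0

#: Low-pass Butterworth conditioning applied to raw torque/velocity.
BUTTER_ORDER = 4
BUTTER_CUTOFF_HZ = 10.0

#: Relative jitter in sample spacing tolerated at load time before a trace
#: is rejected as non-uniform.
MAX_TIME_JITTER = 0.01

#: Rolling-window lengths (s) for outcome extraction.
ISO_WINDOW_S = 3.0          # isometric strength: highest 3-s mean force
SPRINT_DURATION_S = 10.0    # sprint outcomes are taken over the first 10 s
WINGATE_DURATION_S = 30.0   # Wingate P30 averaging window
P5_WINDOW_S = 5.0           # Wingate P5: highest 5-s rolling mean
PO_PEAK_WINDOW_S = 30.0     # GXT PO_peak: highest 30-s mean in final block
GXT_STAGE_DURATION_S = 60.0

#: Fraction of the trace-wide peak total power used to locate the true start
#: of a from-standstill effort (sprint / Wingate), trimming idle lead-in.
START_TRIM_FRACTION = 0.02

#: Wingate validity: peak rim velocity must stay strictly below this (m/s).
RIM_VELOCITY_LIMIT = 3.0

#: Target mean rim velocity (m/s) at which the Wingate resistance
#: coefficient is chosen to dissipate the predicted 30-s power.
WINGATE_TARGET_RIM_VELOCITY = 2.0

#: Rolling-resistance coefficient of a standard gym court, used for the
#: 10-s sprint test (dimensionless).
COURT_MU = 0.012

#: Graded exercise test staircase: start at 20% of predicted peak aerobic
#: power, then increase each minute by 10% of the gap between start load and
#: predicted peak (= 8% of predicted peak per stage).
GXT_START_FRACTION = 0.20
GXT_INCREMENT_FRACTION = 0.10

#: GXT validity window on test duration (minutes, inclusive) and the
#: precision (decimal minutes) at which duration is reported and gated.
GXT_MIN_DURATION_MIN = 8.0
GXT_MAX_DURATION_MIN = 12.0
GXT_DURATION_DECIMALS = 1

#: Termination rule: the test ends when velocity stays this far (m/s) below
#: the target velocity for TERMINATION_DWELL_S seconds.
TERMINATION_MARGIN = 0.28
TERMINATION_DWELL_S = 3.0

#: Secondary criteria for a maximal aerobic effort (two of three must hold;
#: the heart-rate criterion is excluded for lesions above T5).
RER_CRITERION = 1.10
HR_PRED_INTERCEPT = 200.0   # predicted peak heart rate = 200 - age
HR_CRITERION_FRACTION = 0.95
RPE_CRITERION = 8.0

#: Prediction-vs-measurement scatter boundaries (fraction of predicted).
DEVIATION_TOLERANCE = 0.20

#: Saturation heuristic for the isometric test: flag when the force signal
#: sits within this relative tolerance of its own maximum for more than
#: SATURATION_FRACTION of the best 3-s window (possible ergometer clipping).
SATURATION_REL_TOL = 0.005
SATURATION_FRACTION = 0.5
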