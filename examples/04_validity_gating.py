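"""Reproduce the protocol's failure modes and validity gates.

Three constructed sessions show how the gating reacts when the
individualized settings are wrong: a Wingate resistance undersized for the
athlete's true power (peak rim velocity crosses 3 m/s), a GXT designed for
an over-predicted aerobic peak (test collapses at 7 min, below the 8-12 min
window), and the two-of-three secondary maximality criteria with the
heart-rate exclusion for lesions above T5.
"""

import dataclasses

from ergocap import (
    analyze_wingate,
    check_secondary_criteria,
    design_wingate,
    synth_wingate_trace,
)
from ergocap.validation import gxt_session_for_ratio, reference_athlete

gt = reference_athlete()
plan = design_wingate(gt.profile, gt.geometry, equation="legacy_strength",
                      f_iso_per_kg=gt.true_f_iso / gt.profile.mass_user)
strong = dataclasses.replace(gt, true_p30=1.4 * plan.p30_pred)
res = analyze_wingate(synth_wingate_trace(strong, plan.mu, seed=1))
print(f"Wingate with 40% under-predicted P30: v_max_rim {res.v_max_rim:.2f} m/s "
      f"-> valid={res.valid} (limit 3.0 m/s)")

gxt = gxt_session_for_ratio(0.70, seed=1)
print(f"GXT with true peak at 70% of prediction: duration {gxt.duration:.1f} min "
      f"-> valid={gxt.duration_valid} (window 8-12 min)")
gxt_ok = gxt_session_for_ratio(1.00, seed=1)
print(f"GXT with accurate prediction: duration {gxt_ok.duration:.1f} min "
      f"-> valid={gxt_ok.duration_valid}")

crit = check_secondary_criteria(rer_peak=1.15, hr_peak=100.0, rpe_overall=9.0,
                                age=26.0)
print(f"\nsecondary criteria (RER 1.15, HR 100, RPE 9, age 26): met={crit.met} "
      f"(RER {crit.rer_met}, HR {crit.hr_met} vs threshold {crit.hr_threshold:.1f}, "
      f"RPE {crit.rpe_met})")
lesion = check_secondary_criteria(rer_peak=1.12, hr_peak=None, rpe_overall=8.0,
                                  age=30.0, lesion_above_T5=True)
print(f"with lesion above T5 (HR excluded): met={lesion.met}")
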