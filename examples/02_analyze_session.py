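"""Run the four analyzers on one fully synthetic test session.

An athlete with known ground truth performs all four tests; the analyzers
recover strength, sprint, anaerobic and aerobic outcomes, which are printed
next to the generating values.  Differences reflect push-cycle noise and
windowing, not bias.
"""

from ergocap import (
    analyze_gxt,
    analyze_isometric,
    analyze_sprint,
    analyze_wingate,
    design_gxt,
    design_wingate,
    sample_ground_truth,
    synth_gxt_session,
    synth_isometric_trials,
    synth_sprint_trace,
    synth_wingate_trace,
)

gt = sample_ground_truth("basketball", seed=42)
profile = gt.profile
print(f"ground truth: F_iso {gt.true_f_iso:.0f} N, P30 {gt.true_p30:.0f} W, "
      f"PO_peak {gt.true_po_peak:.0f} W ({profile.mass_user:.0f} kg)")

iso = analyze_isometric(synth_isometric_trials(gt, seed=1), profile)
print(f"isometric: F_iso {iso.f_iso:.0f} N "
      f"({iso.f_iso_per_kg:.2f} N/kg, saturated={iso.saturation_flag})")

sprint = analyze_sprint([synth_sprint_trace(gt, seed=s) for s in (2, 3)])
print(f"sprint: PO_mean {sprint.po_mean:.0f} W, PO_max {sprint.po_max:.0f} W, "
      f"v_mean {sprint.v_mean:.2f} m/s, v_max {sprint.v_max:.2f} m/s")

wplan = design_wingate(profile, gt.geometry, equation="legacy_strength",
                       f_iso_per_kg=iso.f_iso_per_kg)
wingate = analyze_wingate(synth_wingate_trace(gt, wplan.mu, seed=4))
print(f"Wingate (mu {wplan.mu:.4f}): P30 {wingate.p30:.0f} W, P5 {wingate.p5:.0f} W, "
      f"PO_max {wingate.po_max:.0f} W, v_max_rim {wingate.v_max_rim:.2f} m/s, "
      f"valid={wingate.valid}")

gplan = design_gxt(profile, chosen_velocity=2.0, equation="wingate",
                   p30_per_kg=wingate.p30 / profile.mass_user)
trace, breaths = synth_gxt_session(gt, gplan, seed=5)
gxt = analyze_gxt(trace, gplan.stages, profile, breaths=breaths,
                  rpe_peripheral=9, rpe_central=8, target_velocity=2.0)
print(f"GXT: PO_peak {gxt.po_peak:.0f} W, duration {gxt.duration:.1f} min "
      f"(valid={gxt.duration_valid}), VO2peak {gxt.vo2peak:.1f} mL/min/kg, "
      f"RER_peak {gxt.rer_peak:.2f}, secondary criteria met={gxt.secondary_criteria_met}")
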