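"""Design individualized Wingate and GXT resistance settings.

A 67 kg tennis athlete (13 kg chair, wheel radius 0.31 m, rim 0.26 m)
pressed 262 N on the isometric test and later produced a measured P30 of
139 W on the Wingate.  The strength result fixes the Wingate resistance so
the predicted 30-s power is dissipated at a 2 m/s mean rim velocity; the
measured P30 fixes the GXT staircase (20% start, +8% of predicted peak per
minute) so exhaustion lands around minute 10.
"""

from ergocap import AthleteProfile, WheelGeometry, design_gxt, design_wingate

profile = AthleteProfile(mass_user=67.0, mass_wheelchair=13.0, sex="male",
                         age=26.0, sport="tennis")
geometry = WheelGeometry(wheel_radius=0.31, rim_radius=0.26)

wingate = design_wingate(profile, geometry, equation="legacy_strength",
                         f_iso_per_kg=262.0 / 67.0)
print(f"P30 predicted from strength: {wingate.p30_pred:.1f} W "
      f"({wingate.p30_pred_per_kg:.2f} W/kg)")
print(f"Wingate resistance coefficient mu = {wingate.mu:.4f} "
      f"(dissipates the prediction at {wingate.target_rim_velocity:.0f} m/s rim)")

gxt = design_gxt(profile, chosen_velocity=2.0, equation="wingate",
                 p30_per_kg=139.0 / 67.0)
print(f"\nPO_peak predicted from measured P30: {gxt.po_peak_pred:.1f} W")
print("GXT staircase (stage, power W, mu):")
for stage in gxt.stages[:12]:
    marker = "  <- prediction reached" if stage.power >= gxt.po_peak_pred else ""
    print(f"  {stage.index:2d}  {stage.power:6.1f}  {stage.mu:.4f}{marker}")
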