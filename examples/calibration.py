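"""Convert between in vivo wall parameters and actuator commands.

The hydraulic segments are driven by syringe pumps; these linear calibrations
translate a desired occlusion degree (% lumen closure), occlusion velocity
(wall speed, mm/s) or membrane displacement (mm) into syringe commands and
back.  The printed values are the operating points of the baseline and
stimulated single contractions.
"""

import dcmkit as dk

for label, sd in [("baseline", 11.91), ("stimulated", 17.95)]:
    md = dk.membrane_displacement(sd)
    od = dk.occlusion_degree_from_syringe(sd)
    print(f"{label}: syringe {sd} mm -> membrane {md:.2f} mm, occlusion {od:.0f}%")

for label, ss in [("baseline", 1.97), ("stimulated", 38.0)]:
    ov = dk.occlusion_velocity(ss)
    print(f"{label}: syringe speed {ss} mm/s -> occlusion velocity {ov:.2f} mm/s")

# inverse: what syringe speed would the fastest in vivo contraction need?
ss_needed = dk.invert_calibration(36.0, "ov")
print(f"in vivo 36 mm/s wall speed needs a {ss_needed:.1f} mm/s syringe (rig max: 38)")
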