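"""Query the synthetic strain oracle that stands in for the FE solver.

The oracle maps 14 screw-tilt angles to the 50th/90th-percentile magnitudes
of the minimum principal bone strain around each screw and pooled over all
screws (microstrain).  Its defaults are calibrated so the calcar screw
(Screw 6) dominates: tilting it 10 deg distally raises the pooled
90th-percentile strain by ~36%, tilting it proximally lowers it by ~13%.
"""

from screwscape import (
    SCREW_IDS,
    Configuration,
    OrientationState,
    default_params,
    strain_response,
)

params = default_params(seed=0)
neutral = strain_response(Configuration.neutral(), collision_flag=False, params=params)

print("Neutral configuration (noise-free):")
for s in SCREW_IDS:
    print(f"  screw {s}: e50 = {neutral.e50[s]:7.1f}  e90 = {neutral.e90[s]:7.1f} microstrain")
print(f"  pooled:  e50 = {neutral.e50['all']:7.1f}  e90 = {neutral.e90['all']:7.1f}")

for dp, label in ((-10, "distal"), (10, "proximal")):
    states = {i: OrientationState() for i in SCREW_IDS}
    states[6] = OrientationState(dp_deg=dp)
    rec = strain_response(Configuration(states), False, params)
    change = 100.0 * (rec.e90["all"] / neutral.e90["all"] - 1.0)
    print(
        f"\nCalcar screw tilted 10 deg {label}: pooled e90 changes by {change:+.1f}%"
    )
print(
    "\nHigher peri-screw compressive strain predicts screw cut-out, so the\n"
    "distal calcar tilt is the dangerous direction on this response surface."
)
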