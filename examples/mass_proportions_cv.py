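"""Are some hindlimb segments more variable in their mass share than others?

Converts the bundled table to per-species segment shares of total limb mass
(thigh + shank + tarsometatarsus + digits = 100%), then tests equality of
coefficients of variation across segments via homogeneity of log-scale
dispersion. Distal segments turn out far more variable than proximal ones —
mass proportions are not developmentally locked the way length proportions
appear to be.
"""

import allomorph as am

table = am.load_neognath()
shares = am.segment_proportions(table)
print(f"{len(shares)} species with all four segment masses")
print("mean shares:", shares.mean().round(3).to_dict())

res = am.test_cv_equality(shares)
print("\nper-segment CV of mass share:")
for seg, cv in res.cv_per_group.items():
    print(f"  {seg:6s} {cv:.3f}")
print(f"omnibus equality test: stat = {res.statistic:.2f}, p = {res.p:.2e}")
print("\npairwise p-values:")
print(am.pairwise_cv(shares).round(4).to_string())
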