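"""Fit trait-evolution models on a time-calibrated tree.

Simulates a pure-birth tree at the study's scale (38 tips, 110 My deep) and a
trait evolving with moderate phylogenetic signal (lambda = 0.8), then fits
Brownian motion and the lambda and delta branch-length transforms by maximum
likelihood, with a parametric-bootstrap CI for lambda. On small, deep trees
the interval is typically wide — little information survives about how trait
change was distributed over the tree.
"""

import allomorph as am

tree = am.simulate_yule_tree(38, seed=7, depth=110.0)
y = am.simulate_trait(tree, "lambda", theta=0.8, sigma2=0.01, root_state=2.0, seed=8)

for model in ("BM", "lambda", "delta"):
    fit = am.fit_model(y, tree, model)
    theta = "  --" if fit.theta is None else f"{fit.theta:.2f}"
    print(f"{model:>6}: theta = {theta}   logL = {fit.loglik:.2f}")

lo, hi = am.bootstrap_ci(y, tree, "lambda", n_sim=200, seed=9)
print(f"\nlambda 95% bootstrap CI: ({lo:.3f}, {hi:.3f})  [true value 0.8]")
print("-> a wide interval at n = 38: parameter weakly identified on deep trees")
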