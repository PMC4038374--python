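"""Parametric-bootstrap (Monte Carlo) comparison of trait-evolution models.

Information criteria behave poorly when comparing the lambda and delta
branch-length transforms on small, deep trees, so the comparison here is a
full parametric bootstrap of the likelihood ratio:

1. fit both models to the observed trait; the observed statistic is
   ``lr = logL(model B) - logL(model A)`` (B-favouring positive);
2. simulate ``n_sim`` traits under the fitted model A, refit both models to
   each, and collect the simulated ratios — the null distribution of the
   ratio when A is true — and its 2.5/97.5 percentile band;
3. repeat simulating under the fitted model B;
4. a model is rejected when the observed ratio falls outside its own null
   band.

Because both transforms reduce to Brownian motion at parameter 1, data truly
evolving by Brownian motion typically retain both models.

All randomness flows from one master seed; each simulation arm draws from a
seed-sequence substream keyed by the arm, so results are reproducible and
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import VariablePair
from .errors import AllomorphError, NumericalError
from .pgls import fit_pgls
from .phylo import _TRANSFORMS, EvoFit, fit_model, prune_to, simulate_mvn, vcv, _resolve_C

__all__ = ["PMCResult", "observed_lr", "pmc", "codiversification_pmc"]


@dataclass(frozen=True)
class PMCResult:
    """Observed likelihood ratio with its two simulated null distributions."""

    model_a: str
    model_b: str
    lr_observed: float
    null_lr_under_a: np.ndarray
    null_lr_under_b: np.ndarray
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n_sim: int
    seed: int
    fit_a: EvoFit
    fit_b: EvoFit

    @property
    def verdict_a(self) -> str:
        return _verdict(self.lr_observed, self.ci_a)

    @property
    def verdict_b(self) -> str:
        return _verdict(self.lr_observed, self.ci_b)


def _verdict(lr: float, ci: tuple[float, float]) -> str:
    return "reject" if (lr < ci[0] or lr > ci[1]) else "retain"


def observed_lr(y, tree, model_a: str = "lambda", model_b: str = "delta") -> float:
    """Log-likelihood difference logL(B) - logL(A) between two fitted models."""
    C = _resolve_C(tree)
    return fit_model(y, C, model_b).loglik - fit_model(y, C, model_a).loglik


def pmc(
    y,
    tree,
    n_sim: int = 1000,
    seed: int | None = None,
    model_a: str = "lambda",
    model_b: str = "delta",
    alpha: float = 0.05,
) -> PMCResult:
    """Monte-Carlo likelihood-ratio comparison of two trait-evolution models.

    ``seed`` is mandatory: the procedure is simulation-based and must be
    reproducible. Refit failures above 1% of ``n_sim`` abort the run.
    """
    if seed is None:
        raise ValueError("pmc requires an explicit seed for reproducibility")
    if n_sim < 100:
        raise ValueError(f"n_sim = {n_sim} < 100 is too small for stable percentiles")
    C = _resolve_C(tree)
    fits = {m: fit_model(y, C, m) for m in (model_a, model_b)}
    lr_obs = fits[model_b].loglik - fits[model_a].loglik

    nulls = {}
    for arm, gen_model in enumerate((model_a, model_b)):
        fit = fits[gen_model]
        C_fit = _TRANSFORMS[gen_model](C, fit.theta) if fit.theta is not None else C
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(arm,)))
        sims = simulate_mvn(C_fit, fit.sigma2, fit.root_state, n_sim, rng)
        lrs = np.empty(n_sim)
        failures = 0
        for i in range(n_sim):
            yi = sims[i]  # rows follow the row order of C
            try:
                lrs[i] = (
                    fit_model(yi, C, model_b).loglik - fit_model(yi, C, model_a).loglik
                )
            except AllomorphError:
                failures += 1
                lrs[i] = np.nan
        if failures > 0.01 * n_sim:
            raise NumericalError(
                f"{failures}/{n_sim} refits failed while simulating under "
                f"{gen_model}; data or tree are pathological"
            )
        if failures:
            # top up from a dedicated retry substream to keep exactly n_sim draws
            rng2 = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(arm, 1))
            )
            bad = np.flatnonzero(np.isnan(lrs))
            extra = simulate_mvn(C_fit, fit.sigma2, fit.root_state, len(bad), rng2)
            for j, i in enumerate(bad):
                yi = extra[j]
                lrs[i] = (
                    fit_model(yi, C, model_b).loglik - fit_model(yi, C, model_a).loglik
                )
        nulls[gen_model] = lrs

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_a = tuple(np.percentile(nulls[model_a], [lo, hi]))
    ci_b = tuple(np.percentile(nulls[model_b], [lo, hi]))
    return PMCResult(
        model_a=model_a,
        model_b=model_b,
        lr_observed=float(lr_obs),
        null_lr_under_a=nulls[model_a],
        null_lr_under_b=nulls[model_b],
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        n_sim=n_sim,
        seed=seed,
        fit_a=fits[model_a],
        fit_b=fits[model_b],
    )


def codiversification_pmc(
    pair: VariablePair,
    tree,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PMCResult:
    """Model comparison applied to PGLS residuals of a trait pair.

    The tree is pruned to the species carrying both traits, the pair is
    regressed by PGLS under the Brownian covariance of the pruned tree, and
    the Monte-Carlo comparison runs on the species-indexed residuals: it asks
    which transform best describes how the two traits co-diversified.
    """
    pruned = prune_to(tree, list(pair.species))
    C = vcv(pruned)
    fit = fit_pgls(pair, C, alpha=alpha)
    return pmc(fit.residuals, C, n_sim=n_sim, seed=seed, alpha=alpha)
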