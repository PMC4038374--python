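"""Phylogenetic generalized least squares (PGLS) regression.

Bivariate regression whose residual covariance follows a phylogenetic
variance-covariance structure C (Brownian motion by default):

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y,   X = [1, x]

Coefficient confidence intervals use the t distribution on n - 2 degrees of
freedom with sigma2 estimated with the n - 2 denominator; the reported
log-likelihood is evaluated at the ML variance (n denominator) so that it is
directly comparable with the trait-evolution model likelihoods in
:mod:`allomorph.phylo`.

Residuals are returned species-indexed so they can be fed straight into
trait co-diversification analyses (lambda/delta fits, Monte-Carlo model
comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dataset import VariablePair
from .errors import TreeError
from .phylo import _as_matrix, _chol

__all__ = ["PGLSFit", "fit_pgls", "pgls_residuals"]


@dataclass(frozen=True)
class PGLSFit:
    intercept: float
    slope: float
    coef_ci: tuple[tuple[float, float], tuple[float, float]]
    sigma2: float          # n-2 denominator, used for coefficient CIs
    sigma2_ml: float       # n denominator, used for the log-likelihood
    loglik: float
    residuals: pd.Series   # y - X beta_hat, species-indexed
    n: int
    alpha: float
    label: str = ""


def fit_pgls(pair: VariablePair, C, alpha: float = 0.05) -> PGLSFit:
    """GLS regression of ``pair.y`` on ``pair.x`` under covariance C.

    ``C`` must be indexed by exactly the species of the pair (prune the tree
    first); a species mismatch raises ``TreeError`` listing the symmetric
    difference. With ``C = I`` the fit reduces exactly to OLS.
    """
    M, index = _as_matrix(C)
    species = list(pair.species)
    if index is not None:
        a, b = set(index), set(species)
        if a != b:
            raise TreeError(
                f"species mismatch between pair and covariance: only in covariance "
                f"{sorted(a - b)}, only in pair {sorted(b - a)}"
            )
        order = [list(index).index(s) for s in species]
        M = M[np.ix_(order, order)]
    n = pair.n
    x = np.asarray(pair.x, float)
    y = np.asarray(pair.y, float)
    X = np.column_stack([np.ones(n), x])

    L = _chol(M)
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    rw = yw - Xw @ beta
    q = float(rw @ rw)
    sigma2 = q / (n - 2)
    sigma2_ml = q / n
    cov_beta = sigma2 * np.linalg.inv(XtX)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    half = tcrit * np.sqrt(np.diag(cov_beta))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    with np.errstate(divide="ignore"):  # perfect fit -> sigma2_ml = 0, loglik = +inf
        loglik = -0.5 * n * np.log(2 * np.pi * sigma2_ml) - 0.5 * logdet - 0.5 * n
    resid = pd.Series(y - X @ beta, index=species, name="pgls_residual")
    return PGLSFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        coef_ci=(
            (float(beta[0] - half[0]), float(beta[0] + half[0])),
            (float(beta[1] - half[1]), float(beta[1] + half[1])),
        ),
        sigma2=float(sigma2),
        sigma2_ml=float(sigma2_ml),
        loglik=float(loglik),
        residuals=resid,
        n=n,
        alpha=alpha,
        label=pair.label,
    )


def pgls_residuals(fit: PGLSFit) -> pd.Series:
    """Species-indexed residuals of a PGLS fit.

    These satisfy the GLS normal equations: the C^-1-weighted residual sum is
    zero. They are the inputs for co-diversification model fitting.
    """
    return fit.residuals.copy()
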