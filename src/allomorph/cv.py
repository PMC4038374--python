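"""Segment mass proportions and equality tests for coefficients of variation.

A species' limb mass budget is summarized as shares: each true segment's mass
(thigh, shank, tarsometatarsal segment, digits — the pes is the sum of the
last two and is not a separate component) divided by their total, so shares
sum to one. Whether some segments are more variable than others across
species is asked through coefficients of variation (CV = SD/mean).

For positive data the CV is tied to dispersion on the log scale — for small
to moderate CVs, SD(log values) ~ CV — so equality of CVs is tested as
homogeneity of log-scale dispersion across groups, using a Levene-type
statistic on log-transformed values (absolute deviations from the group mean
of logs, compared by one-way ANOVA). The test inherits CV's scale invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TraitTable
from .errors import InsufficientDataError, ValidationError

__all__ = ["CVComparison", "segment_proportions", "test_cv_equality", "pairwise_cv"]

logger = logging.getLogger(__name__)

#: the four non-overlapping segments of the proportion budget
PROPORTION_SEGMENTS = ("thigh_mass", "shank_mass", "tars_mass", "digit_mass")


@dataclass(frozen=True)
class CVComparison:
    cv_per_group: dict[str, float]
    statistic: float
    df: tuple[int, int]
    p: float
    alpha: float

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


def segment_proportions(table: TraitTable) -> pd.DataFrame:
    """Per-species shares of each segment in total hindlimb segment mass.

    Species missing any of the four component masses are dropped (the count
    is logged). Rows sum to one.
    """
    cols = {t: table.trait(t) for t in PROPORTION_SEGMENTS}
    df = pd.DataFrame(cols)
    complete = df.dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("segment_proportions: dropped %d species with incomplete segments", dropped)
    total = complete.sum(axis=1)
    if (total <= 0).any():
        raise ValidationError("zero total segment mass for some species")
    shares = complete.div(total, axis=0)
    shares.columns = [c.replace("_mass", "") for c in shares.columns]
    return shares


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        items = {str(c): groups[c].to_numpy(float) for c in groups.columns}
    elif isinstance(groups, dict):
        items = {str(k): np.asarray(v, float) for k, v in groups.items()}
    else:
        items = {f"group{i}": np.asarray(g, float) for i, g in enumerate(groups)}
    if len(items) < 2:
        raise InsufficientDataError("CV comparison needs at least 2 groups")
    for name, v in items.items():
        if len(v) < 3:
            raise InsufficientDataError(f"group {name!r} has n = {len(v)} < 3")
        if np.any(v <= 0):
            raise ValidationError(f"group {name!r} contains non-positive values")
    return items


def test_cv_equality(groups, alpha: float = 0.05) -> CVComparison:
    """Omnibus test that all groups share one coefficient of variation.

    ``groups`` may be a DataFrame (one group per column), a mapping of name to
    values, or a plain sequence of arrays; all values must be positive.
    """
    items = _as_groups(groups)
    cvs = {k: float(np.std(v, ddof=1) / np.mean(v)) for k, v in items.items()}
    logs = [np.log(v) for v in items.values()]
    stat, p = stats.levene(*logs, center="mean")
    n_tot = sum(len(v) for v in logs)
    df = (len(logs) - 1, n_tot - len(logs))
    return CVComparison(cv_per_group=cvs, statistic=float(stat), df=df, p=float(p), alpha=alpha)


def pairwise_cv(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Unadjusted pairwise CV-equality p-values as a symmetric matrix."""
    items = _as_groups(groups)
    names = list(items)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = test_cv_equality({a: items[a], b: items[b]}, alpha)
            out.loc[a, b] = out.loc[b, a] = res.p
    return out
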