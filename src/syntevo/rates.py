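"""Per-branch breakpoint and rearrangement rates with significance tests.

Rates are simple quotients: detected EBRs (or typed rearrangements) on
a branch divided by the branch duration in My.  Each branch is tested
against the remaining branches of its lineage with a leave-one-out
one-sample t statistic,

    t = (r_i - mean(rest)) / (sd(rest) * sqrt(1 + 1/k)),   k = m - 1,

on m - 2 degrees of freedom — the prediction-interval form, chosen so a
single extreme branch cannot inflate its own null.  P values are FDR
corrected with Benjamini–Hochberg and flagged at q < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DatedTree, ValidationError


@dataclass
class BranchRate:
    branch: str
    n_breakpoints: int
    n_rearrangements: int
    dt: float
    bp_rate: float = math.nan
    re_rate: float = math.nan
    p_value: float = math.nan
    fdr_q: float = math.nan
    significant: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError(f"branch {self.branch!r} has non-positive duration")
        self.bp_rate = self.n_breakpoints / self.dt
        self.re_rate = self.n_rearrangements / self.dt


def compute_rates(
    counts: Mapping[str, tuple[int, int]], tree: DatedTree
) -> list[BranchRate]:
    """Rates per branch from (n_breakpoints, n_rearrangements) counts.

    ``counts`` is keyed by the child-node label of each branch; branch
    durations come from the tree.
    """
    out = []
    for branch in sorted(counts):
        nb, nr = counts[branch]
        out.append(BranchRate(branch, nb, nr, tree.branch_length(branch)))
    return out


def leave_one_out_t(values: Sequence[float]) -> list[float]:
    """Two-sided leave-one-out one-sample t-test p-value per element.

    Returns NaN where the remaining values have zero variance.
    """
    x = np.asarray(values, float)
    m = x.size
    if m < 3:
        raise ValidationError("need at least 3 observations")
    out = []
    for i in range(m):
        rest = np.delete(x, i)
        k = rest.size
        sd = rest.std(ddof=1)
        if sd == 0:
            out.append(math.nan)
            continue
        t = (x[i] - rest.mean()) / (sd * math.sqrt(1 + 1 / k))
        out.append(2 * stats.t.sf(abs(t), df=m - 2))
    return out


def test_rates(
    rates: Sequence[BranchRate], which: str = "bp_rate", alpha: float = 0.05
) -> list[BranchRate]:
    """Attach leave-one-out p-values and Benjamini–Hochberg q-values.

    Branches whose leave-one-out null has zero variance get NaN p and q
    (reported as undefined, never silently significant).
    """
    values = [getattr(r, which) for r in rates]
    pvals = leave_one_out_t(values)
    defined = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    qvals = [math.nan] * len(pvals)
    if defined:
        _, q, _, _ = multipletests([pvals[i] for i in defined], method="fdr_bh")
        for i, qi in zip(defined, q):
            qvals[i] = float(qi)
    for r, p, q in zip(rates, pvals, qvals):
        r.p_value = p
        r.fdr_q = q
        r.significant = (not math.isnan(q)) and q < alpha
    return list(rates)
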