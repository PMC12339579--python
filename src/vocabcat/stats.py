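"""Summary statistics for validation studies of the vocabulary test.

Group comparisons use the pooled (equal-variance) independent-samples t
test computed from group summaries (n, mean, SD), with Cohen's d and its
large-sample 95% CI; correlations are Pearson r with the Fisher z
transform ``atanh(r)``.  Descriptives report the sample SD (n-1) and the
adjusted Fisher–Pearson skewness.  The sign convention for comparisons is
group2 minus group1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cat import SessionResult

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PearsonResult",
    "describe",
    "pooled_t_test",
    "pearson_fisher",
    "age_group_means",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    min: float = float("nan")
    max: float = float("nan")
    skewness: float = float("nan")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    cohen_d: float
    d_ci95: tuple[float, float]
    p: float


@dataclass(frozen=True)
class PearsonResult:
    r: float
    fisher_z: float
    p: float


def describe(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD, range, and adjusted Fisher–Pearson skewness.

    Skewness is undefined (NaN) for fewer than 3 values or zero spread.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("describe requires at least one value")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if arr.size >= 3 and sd > 0:
        skew = float(sps.skew(arr, bias=False))
    else:
        skew = float("nan")
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        skewness=skew,
    )


def pooled_t_test(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled-variance t test and Cohen's d from two group summaries.

    ``t = (m2 - m1) / (s_p sqrt(1/n1 + 1/n2))`` with the pooled variance
    ``s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)`` and df = n1+n2-2.
    Cohen's d is ``(m2 - m1)/s_p``; its 95% CI uses the large-sample
    variance ``(n1+n2)/(n1 n2) + d^2/(2(n1+n2))`` with normal quantiles.
    """
    n1, n2 = g1.n, g2.n
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if not (math.isfinite(g1.sd) and math.isfinite(g2.sd)):
        raise ValueError("group SDs must be finite")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    diff = g2.mean - g1.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, cohen_d=0.0, d_ci95=(0.0, 0.0), p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    sp = math.sqrt(sp2)
    t = diff / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    d = diff / sp
    var_d = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    half = 1.959963984540054 * math.sqrt(var_d)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, cohen_d=float(d), d_ci95=(d - half, d + half), p=p)


def pearson_fisher(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson r, Fisher z = atanh(r), and the two-sided p (t transform).

    Perfect correlation yields an infinite Fisher z (boundary case); zero
    variance in either sequence is an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("sequences must have equal length >= 3")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    # an exactly linear relationship can land a rounding error short of +/-1
    if 1.0 - abs(r) < 1e-15:
        z = math.copysign(math.inf, r)
    else:
        z = float(np.arctanh(r))
    return PearsonResult(r=r, fisher_z=z, p=float(res.pvalue))


def age_group_means(
    sessions: Sequence[SessionResult],
    n_groups: int = 11,
    binning: str = "equal_width",
) -> pd.DataFrame:
    """Per-age-group mean vocabulary size by nativeness.

    Ages are split into *n_groups* bins spanning the observed range —
    equal-width by default, ``binning="equal_count"`` for quantile bins.
    Rows cover every (bin, nativeness) combination, with count 0 for empty
    cells.  Columns: bin_left, bin_right, nativeness, mean_vocabulary,
    count.
    """
    if not sessions:
        raise ValueError("no sessions")
    if binning not in {"equal_width", "equal_count"}:
        raise ValueError("binning must be 'equal_width' or 'equal_count'")
    ages = np.array([s.respondent.age for s in sessions], dtype=float)
    lo, hi = float(ages.min()), float(ages.max())
    if lo == hi:
        edges = np.array([lo, hi])
    elif binning == "equal_width":
        edges = np.linspace(lo, hi, n_groups + 1)
    else:
        edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_groups + 1)))
    # assign each age to a bin; the top edge belongs to the last bin
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    groups = sorted({s.respondent.nativeness for s in sessions})
    rows = []
    for j in range(len(edges) - 1):
        for g in groups:
            sel = [
                s
                for s, k in zip(sessions, idx)
                if k == j and s.respondent.nativeness == g
            ]
            rows.append(
                {
                    "bin_left": float(edges[j]),
                    "bin_right": float(edges[j + 1]),
                    "nativeness": g,
                    "mean_vocabulary": float(
                        np.mean([s.vocabulary_size for s in sel])
                    )
                    if sel
                    else float("nan"),
                    "count": len(sel),
                }
            )
    return pd.DataFrame(rows)
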