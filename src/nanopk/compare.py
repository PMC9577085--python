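"""Group-comparison statistics for formulation and PK endpoints.

One-way ANOVA with Tukey HSD post-hoc (Tukey-Kramer for unequal group
sizes), and the Wilcoxon rank-sum test with exact enumeration of the tied
null distribution at small sample sizes — the variant needed to validate
model predictions against replicate measurements, where ties from rounded
values are routine.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["GroupData", "one_way_anova", "tukey_hsd", "wilcoxon_rank_sum",
           "AnovaResult"]


@dataclass
class GroupData:
    """Labelled groups of real observations."""

    labels: list[str]
    observations: list[np.ndarray]

    def __post_init__(self) -> None:
        self.observations = [np.asarray(o, dtype=float) for o in self.observations]
        if len(self.labels) != len(self.observations):
            raise ValueError("labels and observations must align")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")

    @classmethod
    def from_long(cls, frame: pd.DataFrame, group: str = "group",
                  value: str = "value") -> "GroupData":
        labels, obs = [], []
        for g, sub in frame.groupby(group, sort=True):
            labels.append(str(g))
            obs.append(sub[value].to_numpy(dtype=float))
        return cls(labels=labels, observations=obs)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float


def one_way_anova(g: GroupData) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Degenerate all-equal data (zero between- and within-group variation)
    is reported as F = 0, p = 1 rather than NaN.
    """
    for lbl, o in zip(g.labels, g.observations):
        if o.size < 2:
            raise ValueError(f"group {lbl!r} needs >= 2 observations")
    allv = np.concatenate(g.observations)
    grand = allv.mean()
    ssb = sum(o.size * (o.mean() - grand) ** 2 for o in g.observations)
    ssw = sum(float(((o - o.mean()) ** 2).sum()) for o in g.observations)
    dfb = len(g.observations) - 1
    dfw = allv.size - len(g.observations)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0, 0.0, 0.0)
        return AnovaResult(np.inf, dfb, dfw, 0.0, ssb, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, float(scipy.stats.f.sf(F, dfb, dfw)),
                       float(ssb), float(ssw))


def tukey_hsd(g: GroupData, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after one-way ANOVA.

    Unequal group sizes use the Tukey-Kramer standard error.  The q
    statistic is referred to the studentized-range distribution with
    k groups and the ANOVA's within-group df.
    """
    res = one_way_anova(g)
    k = len(g.observations)
    msw = res.ss_within / res.df_within
    rows = []
    for a, b in combinations(range(k), 2):
        oa, ob = g.observations[a], g.observations[b]
        diff = oa.mean() - ob.mean()
        se = np.sqrt(msw / 2.0 * (1.0 / oa.size + 1.0 / ob.size))
        q = abs(diff) / se
        p = float(scipy.stats.studentized_range.sf(q, k, res.df_within))
        rows.append({"group_a": g.labels[a], "group_b": g.labels[b],
                     "difference": float(diff), "q": float(q), "p": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumeration with mid-rank ties.

    Enumerates all C(n+m, n) assignments of the pooled mid-ranks to the
    first sample; p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # mid-ranks for ties
    w_obs = float(ranks[:n].sum())
    total = comb(n + m, n)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return w_obs, min(p, 1.0)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    ``mode='exact'`` enumerates the null distribution of the rank sum over
    all rank assignments, handling ties by mid-ranks — feasible for
    combined n <= 20.  ``mode='approximate'`` uses the tie-corrected normal
    approximation with continuity correction.  ``'auto'`` picks exact for
    combined n <= 20.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approximate"):
        raise ValueError("mode must be auto, exact or approximate")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= 20 else "approximate"
    if mode == "exact":
        if x.size + y.size > 20:
            raise ValueError("exact enumeration limited to combined n <= 20")
        return _exact_ranksum_p(x, y)

    n, m = x.size, y.size
    N = n + m
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n].sum())
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    return w, float(2.0 * scipy.stats.norm.sf(max(z, 0.0)))
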