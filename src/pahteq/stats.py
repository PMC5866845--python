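"""One-way ANOVA with Student-Newman-Keuls (SNK) post-hoc comparisons.

Classical fixed-effects one-way ANOVA (equal-variance, no Welch correction,
matching common SigmaPlot/Prism defaults), followed by the SNK stepwise
multiple-comparison procedure on the studentized range:

    q = |mean_i - mean_j| / sqrt(MSW / n_h)

with n_h the harmonic mean of the pair's group sizes, compared against
q(alpha, p, df_within) where p (the "stretch") is the number of ordered
means the pair spans. The step-down logic is strict: once a span is found
non-significant, every pair inside it is declared non-significant without
testing. Studentized-range quantiles come from numerical evaluation of the
distribution, not printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = ["GroupData", "AnovaResult", "PosthocResult", "one_way_anova", "snk_posthoc"]


@dataclass(frozen=True)
class GroupData:
    group: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 2:
            raise InputError(f"group {self.group!r}: need n >= 2 measurements")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"group {self.group!r}: non-finite measurement")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    mean_diff: float
    q_statistic: float
    stretch: int       # number of ordered means the pair spans
    critical_q: float
    significant: bool


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Classical one-way ANOVA decomposition with F-distribution p-value.

    Zero within-group variance is handled explicitly: identical group means
    give F = 0, p = 1; unequal means with no within-group scatter give
    F = inf, p = 0.
    """
    if len(groups) < 2:
        raise InputError("ANOVA requires >= 2 groups")
    arrays = [np.asarray(g.values) for g in groups]
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(groups) - 1
    df_within = int(ns.sum()) - len(groups)
    if df_within <= 0:
        raise InputError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0, 0.0)
        return AnovaResult(float("inf"), df_between, df_within, 0.0, 0.0)
    f = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p, ms_within)


@lru_cache(maxsize=None)
def _critical_q(alpha: float, stretch: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, stretch, df))


def snk_posthoc(
    groups: Sequence[GroupData], alpha: float = 0.05
) -> list[PosthocResult]:
    """All pairwise SNK comparisons with step-down blocking.

    Means are ranked; spans are tested from the widest stretch downward.
    A pair contained in any non-significant span is reported non-significant
    (blocked) with its q and critical value still attached for inspection.
    """
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    anova = one_way_anova(groups)
    k = len(groups)
    order = np.argsort([np.mean(g.values) for g in groups], kind="stable")
    ordered = [groups[i] for i in order]
    means = np.array([np.mean(g.values) for g in ordered])
    ns = np.array([len(g.values) for g in ordered])
    msw = anova.ms_within
    df = anova.df_within

    blocked: list[tuple[int, int]] = []  # non-significant spans (i, j)
    results: list[PosthocResult] = []
    for stretch in range(k, 1, -1):
        for i in range(0, k - stretch + 1):
            j = i + stretch - 1
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            diff = float(means[j] - means[i])
            if msw == 0:
                q = 0.0 if diff == 0 else float("inf")
            else:
                q = diff / np.sqrt(msw / n_h)
            crit = _critical_q(alpha, stretch, df)
            inside_blocked = any(a <= i and j <= b for a, b in blocked)
            significant = (not inside_blocked) and q > crit
            if not significant:
                blocked.append((i, j))
            results.append(
                PosthocResult(
                    pair=(ordered[i].group, ordered[j].group),
                    mean_diff=diff,
                    q_statistic=float(q),
                    stretch=stretch,
                    critical_q=crit,
                    significant=significant,
                )
            )
    return results
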