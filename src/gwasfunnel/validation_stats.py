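"""Statistics for the wet-lab validation assays.

Time-to-paralysis observations from worm motility assays are treated
as right-censored survival data: the Kaplan-Meier product-limit
estimator summarizes each group and the two-group log-rank test
compares curves.  Endpoint measurements (ATP content, fertility
counts, viability) are compared with fold changes, the Mann-Whitney U
test (exact enumeration for small samples), Student/Welch t-tests (see
:mod:`gwasfunnel.enrichment_stats`), and the Kruskal-Wallis test for
multi-group dose series.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io_formats import EventTable, ValidationError

#: total sample size at or below which the Mann-Whitney U null
#: distribution is enumerated exactly
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate for one group.

    ``times`` are the distinct observation times in increasing order
    (events and censorings), ``survival`` the estimate just after each
    time, ``at_risk`` the risk-set size just before it.
    """

    group: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.survival) == len(self.at_risk)):
            raise ValidationError("times, survival and at_risk must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(self.survival, self.survival[1:])):
            raise ValidationError("survival must be non-increasing")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float


def summarize_group(values: Sequence[float], group: str) -> GroupSummary:
    a = np.asarray(values, dtype=float)
    if len(a) == 0:
        raise ValidationError(f"group {group!r} is empty")
    sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return GroupSummary(group=group, n=len(a), mean=float(a.mean()), sd=sd)


def km_estimate(events: EventTable, group: str) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Censored subjects leave the risk set without a survival drop; with
    no censoring the estimate equals the empirical survival function.
    """
    sub = events.subset(group)
    if len(sub) == 0:
        raise ValidationError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    times = sorted(sub["time"].unique())
    survival = kmf.survival_function_at_times(times).to_numpy()
    table = kmf.event_table
    at_risk = [int(table.loc[t, "at_risk"]) for t in times]
    return SurvivalCurve(
        group=group,
        times=tuple(float(t) for t in times),
        survival=tuple(float(s) for s in survival),
        at_risk=tuple(at_risk),
    )


def logrank_test(events: EventTable, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank test (chi-square, 1 df, two-sided)."""
    a = events.subset(group_a)
    b = events.subset(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(f"empty group among {group_a!r}, {group_b!r}")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def fold_change(value_a: float, value_b: float, orientation: str = "magnitude") -> float:
    """Ratio of two positive measurements, rounded half-up to 2 decimals.

    'magnitude' (default) reports max/min regardless of argument order;
    'directed' reports a/b.
    """
    if orientation not in ("magnitude", "directed"):
        raise ValidationError(f"orientation must be magnitude|directed, got {orientation!r}")
    if not (value_a > 0 and value_b > 0):
        raise ValidationError("fold change requires strictly positive values")
    ratio = (
        max(value_a, value_b) / min(value_a, value_b)
        if orientation == "magnitude"
        else value_a / value_b
    )
    return float(Decimal(repr(ratio)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _u_statistic(ranks: np.ndarray, idx: tuple[int, ...], n1: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney_u(
    sample1: Sequence[float], sample2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For total sample size at most ``EXACT_MW_LIMIT`` the permutation
    null distribution of U is enumerated exactly (midranks handle
    ties); larger samples use the normal approximation with tie
    correction and continuity correction.  Returns (U of sample1, p).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be nonempty")
    if n1 + n2 <= EXACT_MW_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        u_obs = _u_statistic(ranks, tuple(range(n1)), n1)
        null = np.array(
            [
                _u_statistic(ranks, idx, n1)
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        p_le = np.mean(null <= u_obs + eps)
        p_ge = np.mean(null >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, chi-square approximation,
    df = groups - 1.  All-identical data yield (0, 1)."""
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
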