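"""Turnover rates from the regression of mean similarity on lag.

The turnover rate of a community over a period is the (sign-flipped) slope of
an ordinary least-squares regression of mean pairwise similarity against lag,
fitted over lags 1-5 by default, so a declining similarity yields a positive
rate (units: similarity per year).  The intercept is always estimated rather
than pinned at the lag-0 value of 1, because the drop from lag 0 to lag 1 is
dominated by detection-failure pseudo-turnover, which biases all non-zero
lags about equally and is deliberately bypassed by regressing over non-zero
lags only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .similarity import SimilaritySchedule

DEFAULT_LAGS = range(1, 6)


@dataclass
class TurnoverEstimate:
    """Similarity decline per year for one community and period."""

    rate: float
    se: float | None  # nominal OLS slope SE; defined only for >= 3 lags
    n_lags: int
    intercept: float = math.nan
    period: str = ""
    breakyear: int | None = None


@dataclass
class TurnoverChange:
    """Since-minus-before difference of turnover rates for one community."""

    community_id: str
    delta: float
    se_delta: float | None
    taxon_group: str = "all"
    breakyear: int | None = None


def turnover_rate(
    schedule: SimilaritySchedule,
    lags=DEFAULT_LAGS,
    period: str = "",
    breakyear: int | None = None,
) -> TurnoverEstimate | None:
    """OLS fit of mean similarity against lag; rate is the negated slope.

    Only lags present in the schedule (and requested) enter the fit.  With
    fewer than two lag points the community is excluded for this period and
    ``None`` is returned; with exactly two points the rate is defined but its
    standard error is not.
    """
    wanted = set(lags)
    xs = [l for l in schedule.lags if l in wanted]
    if len(xs) < 2:
        return None
    ys = [schedule.means[l] for l in xs]
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    if n >= 3:
        rss = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
        se = math.sqrt(max(rss, 0.0) / (n - 2) / sxx)
    else:
        se = None
    return TurnoverEstimate(
        rate=-slope, se=se, n_lags=n, intercept=intercept, period=period, breakyear=breakyear
    )


def turnover_change(
    before: TurnoverEstimate | None,
    since: TurnoverEstimate | None,
    community_id: str = "",
    taxon_group: str = "all",
    breakyear: int | None = None,
) -> TurnoverChange | None:
    """Difference of turnover rates since minus before a breakpoint.

    Positive delta means turnover accelerated.  The standard error follows
    standard error propagation, sqrt(se_before^2 + se_since^2), and is
    undefined whenever either period's SE is.  If either period's estimate is
    missing the community is excluded (``None``).
    """
    if before is None or since is None:
        return None
    if before.se is not None and since.se is not None:
        se_delta = math.hypot(before.se, since.se)
    else:
        se_delta = None
    return TurnoverChange(
        community_id=community_id,
        delta=since.rate - before.rate,
        se_delta=se_delta,
        taxon_group=taxon_group,
        breakyear=breakyear,
    )
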