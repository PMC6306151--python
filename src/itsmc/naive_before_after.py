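"""Naive before/after Poisson contrasts: per-period rates, rate differences
and rate ratios with 95% Wald confidence intervals.

All quantities have closed forms equivalent to a two-group Poisson GLM
(log link with a log period-count offset for the ratio; identity link for
the difference), so no iterative fitting is needed.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model_io import HalfYearPanel, STRATA, split_pre_post

__all__ = [
    "RateEstimate",
    "ContrastEstimate",
    "period_rate",
    "rate_ratio",
    "rate_difference",
    "before_after_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed summary tables,
    where e.g. 0.935 displays as 0.94; float banker's rounding gives 0.93).

    The value is first snapped to 10 decimal places so that binary float
    representation error (e.g. 0.9349999999999999 for the exact rational
    0.935) does not flip a boundary case."""
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    return norm.ppf(0.5 + level / 2)


@dataclasses.dataclass(frozen=True)
class RateEstimate:
    """Average events per 6-month period with a Wald CI on the rate scale."""

    count: int
    n_periods: int
    rate: float
    ci_low: float
    ci_high: float


@dataclasses.dataclass(frozen=True)
class ContrastEstimate:
    """A before/after contrast (difference or ratio) with its CI.

    ``degenerate`` marks contrasts whose CI is undefined (zero count on the
    log scale); such intervals are flagged rather than silently clipped.
    """

    kind: str
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def period_rate(count: int, n_periods: int, level: float = 0.95) -> RateEstimate:
    """Rate = count / n_periods with Wald CI ``rate +/- z * sqrt(count) / n``.

    The lower bound is clipped at zero (rates cannot be negative).
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if count < 0:
        raise ValueError("count must be >= 0")
    z = _z(level)
    rate = count / n_periods
    half = z * np.sqrt(count) / n_periods
    return RateEstimate(
        count=count,
        n_periods=n_periods,
        rate=rate,
        ci_low=max(0.0, rate - half),
        ci_high=rate + half,
    )


def rate_ratio(
    count_after: int,
    periods_after: int,
    count_before: int,
    periods_before: int,
    level: float = 0.95,
) -> ContrastEstimate:
    """After/before rate ratio with the log-scale Wald CI
    ``exp(ln RR +/- z * sqrt(1/count_after + 1/count_before))``."""
    if count_before <= 0:
        raise ValueError("count_before must be > 0 for a rate ratio")
    if periods_after < 1 or periods_before < 1:
        raise ValueError("period counts must be >= 1")
    estimate = (count_after / periods_after) / (count_before / periods_before)
    if count_after == 0:
        return ContrastEstimate(
            kind="ratio",
            estimate=0.0,
            ci_low=float("nan"),
            ci_high=float("nan"),
            degenerate=True,
        )
    z = _z(level)
    se_log = np.sqrt(1.0 / count_after + 1.0 / count_before)
    return ContrastEstimate(
        kind="ratio",
        estimate=estimate,
        ci_low=float(estimate * np.exp(-z * se_log)),
        ci_high=float(estimate * np.exp(z * se_log)),
    )


def rate_difference(
    count_after: int,
    periods_after: int,
    count_before: int,
    periods_before: int,
    level: float = 0.95,
) -> ContrastEstimate:
    """After - before rate difference with Wald CI
    ``diff +/- z * sqrt(count_after/periods_after^2 + count_before/periods_before^2)``."""
    if periods_after < 1 or periods_before < 1:
        raise ValueError("period counts must be >= 1")
    estimate = count_after / periods_after - count_before / periods_before
    z = _z(level)
    half = z * np.sqrt(
        count_after / periods_after**2 + count_before / periods_before**2
    )
    return ContrastEstimate(
        kind="difference",
        estimate=estimate,
        ci_low=estimate - half,
        ci_high=estimate + half,
    )


def before_after_table(panel: HalfYearPanel, level: float = 0.95) -> pd.DataFrame:
    """Full before/after summary for all three strata.

    Rows mirror the three blocks of a before/after table: raw counts,
    average 6-month rates with CIs, and the difference/ratio contrasts with
    CIs.  Columns are the strata (all, private, public).
    """
    rows: dict[str, dict[str, float]] = {}
    for stratum in STRATA:
        pre, post = split_pre_post(panel, stratum)
        n_pre, n_post = len(pre), len(post)
        c_pre, c_post = int(pre.sum()), int(post.sum())
        r_pre = period_rate(c_pre, n_pre, level)
        r_post = period_rate(c_post, n_post, level)
        diff = rate_difference(c_post, n_post, c_pre, n_pre, level)
        if c_pre > 0:
            ratio = rate_ratio(c_post, n_post, c_pre, n_pre, level)
        else:
            ratio = ContrastEstimate(
                "ratio", float("nan"), float("nan"), float("nan"), degenerate=True
            )
        rows[stratum] = {
            "count_before": c_pre,
            "count_after": c_post,
            "rate_before": r_pre.rate,
            "rate_before_ci_low": r_pre.ci_low,
            "rate_before_ci_high": r_pre.ci_high,
            "rate_after": r_post.rate,
            "rate_after_ci_low": r_post.ci_low,
            "rate_after_ci_high": r_post.ci_high,
            "rate_difference": diff.estimate,
            "rate_difference_ci_low": diff.ci_low,
            "rate_difference_ci_high": diff.ci_high,
            "rate_ratio": ratio.estimate,
            "rate_ratio_ci_low": ratio.ci_low,
            "rate_ratio_ci_high": ratio.ci_high,
            "rate_ratio_degenerate": float(ratio.degenerate),
        }
    return pd.DataFrame(rows)[list(STRATA)]
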