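"""Monte Carlo intervention-effect estimation.

Counterfactual post-period counts are drawn log-normally around the
forecast (log-scale means and standard errors); observed-process counts are
drawn Poisson around the observed values.  Per-period and average effects
(rate differences and percent changes) are summarized as Monte Carlo means
with equal-tailed percentile uncertainty intervals.

Sign convention: effect = observed - counterfactual, so negative values
mean events prevented.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

from .arima_forecast import ForecastPath

__all__ = [
    "McConfig",
    "Interval",
    "EffectSummary",
    "draw_counterfactuals",
    "draw_observed",
    "effect_summary",
    "run_mc",
]


@dataclasses.dataclass(frozen=True)
class McConfig:
    iterations: int = 10_000
    seed: int = 0
    ui_level: float = 0.95
    periods_per_year: int = 2

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.ui_level < 1:
            raise ValueError("ui_level must be in (0, 1)")
        if self.periods_per_year < 1:
            raise ValueError("periods_per_year must be >= 1")


class Interval(NamedTuple):
    """A Monte Carlo point estimate with an uncertainty interval."""

    point: float
    ui_low: float
    ui_high: float

    def excludes_zero(self) -> bool:
        return self.ui_low > 0 or self.ui_high < 0


@dataclasses.dataclass
class EffectSummary:
    """Per-period and average intervention effects with uncertainty intervals.

    Differences are events per 6-month period; ``avg_annualized_diff`` is
    events per year (mean per-period difference times periods_per_year);
    percent changes are 100 * (observed - counterfactual) / counterfactual.
    """

    per_period_diff: list[Interval]
    per_period_pct: list[Interval]
    avg_annualized_diff: Interval
    avg_pct_change: Interval
    significant_per_period: list[bool]
    significant_overall: bool
    cf_per_period: list[Interval]  # counterfactual count band, for plotting
    iterations: int
    n_excluded_pct_draws: int

    def to_dict(self) -> dict:
        def ivl(x: Interval) -> dict:
            return {
                "point": float(x.point),
                "ui_low": float(x.ui_low),
                "ui_high": float(x.ui_high),
            }

        return {
            "per_period_diff": [ivl(x) for x in self.per_period_diff],
            "per_period_pct": [ivl(x) for x in self.per_period_pct],
            "avg_annualized_diff": ivl(self.avg_annualized_diff),
            "avg_pct_change": ivl(self.avg_pct_change),
            "significant_per_period": list(map(bool, self.significant_per_period)),
            "significant_overall": bool(self.significant_overall),
            "counterfactual_per_period": [ivl(x) for x in self.cf_per_period],
            "iterations": int(self.iterations),
            "n_excluded_pct_draws": int(self.n_excluded_pct_draws),
        }


def draw_counterfactuals(
    path: ForecastPath, cfg: McConfig, rng: np.random.Generator
) -> np.ndarray:
    """(iterations x horizon) log-normal draws on the count scale:
    ``exp(Normal(log_mean[h], log_se[h]))``, independent across cells.

    A zero SE yields a point mass at exp(log_mean)."""
    shape = (cfg.iterations, path.horizon)
    z = rng.standard_normal(shape)
    return np.exp(path.log_means[None, :] + z * path.log_ses[None, :])


def draw_observed(
    observed_counts, cfg: McConfig, rng: np.random.Generator
) -> np.ndarray:
    """(iterations x horizon) Poisson draws around the observed counts."""
    obs = np.asarray(observed_counts)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    return rng.poisson(obs[None, :], size=(cfg.iterations, len(obs))).astype(float)


def _interval(draws: np.ndarray, ui_level: float) -> Interval:
    a = (1.0 - ui_level) / 2.0
    lo, hi = np.nanquantile(draws, [a, 1.0 - a])
    return Interval(float(np.nanmean(draws)), float(lo), float(hi))


def effect_summary(
    cf_draws: np.ndarray, obs_draws: np.ndarray, cfg: McConfig
) -> EffectSummary:
    """Summarize effect draws: observed minus counterfactual per period, its
    annualized average, and the percent-change analogues.

    Counterfactual draws of exactly zero (possible only through underflow)
    are excluded from percent computations and counted."""
    cf = np.asarray(cf_draws, dtype=float)
    obs = np.asarray(obs_draws, dtype=float)
    if cf.shape != obs.shape:
        raise ValueError(f"shape mismatch: {cf.shape} vs {obs.shape}")
    n_iter, horizon = cf.shape

    diff = obs - cf
    valid = cf > 0
    n_excluded = int((~valid).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(valid, 100.0 * diff / np.where(valid, cf, 1.0), np.nan)

    per_period_diff = [_interval(diff[:, h], cfg.ui_level) for h in range(horizon)]
    per_period_pct = [_interval(pct[:, h], cfg.ui_level) for h in range(horizon)]
    avg_diff = cfg.periods_per_year * diff.mean(axis=1)
    avg_pct = np.nanmean(pct, axis=1)
    avg_annualized_diff = _interval(avg_diff, cfg.ui_level)
    avg_pct_change = _interval(avg_pct, cfg.ui_level)
    cf_per_period = [_interval(cf[:, h], cfg.ui_level) for h in range(horizon)]

    return EffectSummary(
        per_period_diff=per_period_diff,
        per_period_pct=per_period_pct,
        avg_annualized_diff=avg_annualized_diff,
        avg_pct_change=avg_pct_change,
        significant_per_period=[i.excludes_zero() for i in per_period_diff],
        significant_overall=avg_annualized_diff.excludes_zero(),
        cf_per_period=cf_per_period,
        iterations=n_iter,
        n_excluded_pct_draws=n_excluded,
    )


def run_mc(
    path: ForecastPath, observed_counts, cfg: McConfig
) -> EffectSummary:
    """Draw both matrices from independent sub-streams of ``cfg.seed`` and
    summarize.  Fixed seed implies bitwise-identical output."""
    obs = np.asarray(observed_counts)
    if len(obs) != path.horizon:
        raise ValueError(
            f"observed series length {len(obs)} != forecast horizon {path.horizon}"
        )
    root = np.random.default_rng(cfg.seed)
    cf_stream, obs_stream = root.spawn(2)
    cf = draw_counterfactuals(path, cfg, cf_stream)
    ob = draw_observed(obs, cfg, obs_stream)
    return effect_summary(cf, ob, cfg)
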