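"""Synthetic half-year count panels with latent log-scale ARMA structure.

The generator mirrors the twin distributional assumptions of the analysis:
a latent log-scale mean (linear trend + stationary ARMA noise + optional
intervention effect) with Poisson-distributed observed counts.  Counts are
therefore marginally Poisson-log-normal (over-dispersed) whenever the
innovation standard deviation is positive.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import lfilter

from .data_model_io import HalfYearPanel

__all__ = [
    "SyntheticConfig",
    "SyntheticPanel",
    "simulate_latent",
    "simulate_counts",
    "simulate_panel",
    "study_like_configs",
]

_BURN_IN = 100  # periods discarded so the ARMA noise starts near stationarity
_LOG_MEAN_MAX = 30.0  # exp() overflow guard for Poisson rates

EFFECT_SHAPES = ("none", "step", "ramp")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one stratum's latent process and intervention effect.

    ``effect_size_log`` is the multiplicative effect at full strength on the
    log scale (e.g. ``ln(0.8)`` for a -20% reduction).  A ``step`` effect
    applies it from ``intervention_index`` on; a ``ramp`` reaches full
    strength linearly over ``ramp_periods`` periods.
    """

    n_periods: int
    intervention_index: int
    baseline_log_level: float
    trend_per_period: float = 0.0
    ar_coefs: tuple[float, ...] = ()
    ma_coefs: tuple[float, ...] = ()
    innovation_sd: float = 0.0
    effect_shape: str = "none"
    effect_size_log: float = 0.0
    ramp_periods: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_periods < 2:
            raise ValueError("n_periods must be >= 2")
        if not 0 < self.intervention_index < self.n_periods:
            raise ValueError("require 0 < intervention_index < n_periods")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be >= 0")
        if self.effect_shape not in EFFECT_SHAPES:
            raise ValueError(f"effect_shape must be one of {EFFECT_SHAPES}")
        if self.ramp_periods < 1:
            raise ValueError("ramp_periods must be >= 1")
        object.__setattr__(self, "ar_coefs", tuple(float(a) for a in self.ar_coefs))
        object.__setattr__(self, "ma_coefs", tuple(float(m) for m in self.ma_coefs))
        if self.ar_coefs:
            # stationarity: roots of 1 - phi_1 z - ... - phi_p z^p outside unit circle
            poly = np.r_[1.0, -np.asarray(self.ar_coefs)]
            roots = np.roots(poly[::-1])
            if np.any(np.abs(roots) <= 1.0 + 1e-12):
                raise ValueError(
                    f"AR coefficients {self.ar_coefs} are not stationary"
                )


def effect_profile(config: SyntheticConfig) -> np.ndarray:
    """Deterministic intervention-effect term per period (log scale)."""
    i = np.arange(config.n_periods)
    k = config.intervention_index
    if config.effect_shape == "none":
        return np.zeros(config.n_periods)
    if config.effect_shape == "step":
        return np.where(i >= k, config.effect_size_log, 0.0)
    frac = np.clip((i - k + 1) / config.ramp_periods, 0.0, 1.0)
    return np.where(i >= k, config.effect_size_log * frac, 0.0)


def _arma_noise(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.innovation_sd == 0:
        return np.zeros(config.n_periods)
    e = rng.normal(0.0, config.innovation_sd, size=_BURN_IN + config.n_periods)
    # ARMA(p,q) as the rational filter theta(B)/phi(B) applied to innovations
    b = np.r_[1.0, np.asarray(config.ma_coefs)] if config.ma_coefs else np.array([1.0])
    a = np.r_[1.0, -np.asarray(config.ar_coefs)] if config.ar_coefs else np.array([1.0])
    x = lfilter(b, a, e)
    return x[_BURN_IN:]


def simulate_latent(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent log-mean per period: baseline + trend + ARMA noise + effect."""
    i = np.arange(config.n_periods)
    return (
        config.baseline_log_level
        + config.trend_per_period * i
        + _arma_noise(config, rng)
        + effect_profile(config)
    )


def simulate_counts(
    latent_log_means: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts around ``exp(latent)``, independent given the latent."""
    latent = np.asarray(latent_log_means, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent log-means must be finite")
    if np.any(latent > _LOG_MEAN_MAX):
        raise OverflowError(
            f"latent log-mean exceeds {_LOG_MEAN_MAX}; Poisson rate would overflow"
        )
    return rng.poisson(np.exp(latent))


@dataclasses.dataclass
class SyntheticPanel:
    """One simulated stratum: latent log-means, counts and the config used."""

    latent_log_means: np.ndarray
    counts: np.ndarray
    config: SyntheticConfig


def simulate_stratum(
    config: SyntheticConfig, rng: np.random.Generator
) -> SyntheticPanel:
    latent = simulate_latent(config, rng)
    counts = simulate_counts(latent, rng)
    return SyntheticPanel(latent_log_means=latent, counts=counts, config=config)


def simulate_panel(
    cfg_private: SyntheticConfig,
    cfg_public: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    *,
    start_year: int = 2002,
) -> HalfYearPanel:
    """Simulate both strata and assemble a :class:`HalfYearPanel`.

    The two strata draw from independent sub-streams spawned from one root
    generator, so a fixed seed reproduces the panel bitwise.
    """
    if cfg_private.n_periods != cfg_public.n_periods:
        raise ValueError("strata configs must share n_periods")
    if cfg_private.intervention_index != cfg_public.intervention_index:
        raise ValueError("strata configs must share intervention_index")
    if not isinstance(rng, np.random.Generator):
        seed = rng if rng is not None else cfg_private.seed
        rng = np.random.default_rng(seed)
    stream_private, stream_public = rng.spawn(2)
    private = simulate_stratum(cfg_private, stream_private)
    public = simulate_stratum(cfg_public, stream_public)

    periods = []
    year, half = start_year, 1
    for _ in range(cfg_private.n_periods):
        periods.append((year, half))
        year, half = (year, 2) if half == 1 else (year + 1, 1)
    return HalfYearPanel(
        periods=periods,
        counts_private=private.counts,
        counts_public=public.counts,
        counts_all=private.counts + public.counts,
        intervention_index=cfg_private.intervention_index,
    )


def study_like_configs(
    *,
    effect_shape_private: str = "none",
    effect_shape_public: str = "none",
    effect_size_log_private: float = 0.0,
    effect_size_log_public: float = 0.0,
    innovation_sd: float = 0.05,
    trend_per_period: float = 0.0,
    ar_coefs: tuple[float, ...] = (),
    ramp_periods: int = 10,
) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Stratum configs shaped like the study series: 27 half-year periods,
    intervention at index 17, pre-period baselines of ~74.65 (private) and
    ~28.24 (public) events per period."""
    common = dict(
        n_periods=27,
        intervention_index=17,
        trend_per_period=trend_per_period,
        ar_coefs=ar_coefs,
        innovation_sd=innovation_sd,
        ramp_periods=ramp_periods,
    )
    cfg_private = SyntheticConfig(
        baseline_log_level=math.log(74.65),
        effect_shape=effect_shape_private,
        effect_size_log=effect_size_log_private,
        **common,
    )
    cfg_public = SyntheticConfig(
        baseline_log_level=math.log(28.24),
        effect_shape=effect_shape_public,
        effect_size_log=effect_size_log_public,
        **common,
    )
    return cfg_private, cfg_public
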