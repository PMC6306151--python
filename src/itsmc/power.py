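"""Observation time required for a two-group Poisson pre/post rate test.

Normal approximation on the log rate ratio: with expected counts E_pre and
E_post, the Wald statistic has variance 1/E_pre + 1/E_post, giving the
closed-form smallest total observation time T (in years, two half-year
periods per year) at which a two-sided level-alpha test attains the target
power against rate ratio 1 - pct_reduction/100.
"""

from __future__ import annotations

import dataclasses
import math

from scipy.stats import norm

__all__ = ["PowerSpec", "required_years"]


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    baseline_rate: float  # events per half-year period
    pct_reduction: float  # percent, in (0, 100)
    alpha: float = 0.05  # two-sided
    target_power: float = 0.80
    allocation: tuple[float, float] = (1.0, 1.0)  # pre : post period ratio

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if not 0 < self.pct_reduction < 100:
            raise ValueError("pct_reduction must be in (0, 100)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        a, b = self.allocation
        if a <= 0 or b <= 0:
            raise ValueError("allocation weights must be positive")


def required_years(spec: PowerSpec) -> float:
    """Smallest total observation time in years satisfying the power target.

    Solves (z_{1-alpha/2} + z_{power})^2 * (1/E_pre + 1/E_post) = (ln r)^2
    for total time, where r = 1 - pct_reduction/100 and the expected counts
    are baseline_rate * (periods in each arm) with the post rate scaled by r.
    """
    r = 1.0 - spec.pct_reduction / 100.0
    z_alpha = norm.ppf(1.0 - spec.alpha / 2.0)
    z_beta = norm.ppf(spec.target_power)
    a, b = spec.allocation
    f_pre, f_post = a / (a + b), b / (a + b)
    # periods = 2T, so E_pre = rate * 2T * f_pre and E_post = rate * r * 2T * f_post
    c = (z_alpha + z_beta) ** 2 / math.log(r) ** 2
    per_period = 1.0 / (spec.baseline_rate * f_pre) + 1.0 / (
        spec.baseline_rate * r * f_post
    )
    return c * per_period / 2.0
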