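"""Power of the significance test of a Pearson correlation.

The analytic approximation follows the classic recipe: the critical
correlation comes from the t distribution with n − 2 degrees of freedom at
the chosen level, and the sampling distribution of the observed correlation
is handled on the Fisher-z scale with the small-sample mean correction
r / (2(n − 1)) and standard deviation 1 / sqrt(n − 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    n: int
    r: float
    alpha: float
    sides: int = 2

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4 (Fisher-z SD undefined below)")
        if not (-1 < self.r < 1) or self.r == 0:
            raise ValueError("r must lie in (-1, 1) and differ from 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def correlation_power(q: PowerQuery) -> float:
    """Power to detect a true correlation ``q.r`` at level ``q.alpha``."""
    df = q.n - 2
    t_crit = stats.t.isf(q.alpha / q.sides, df)
    r_crit = np.sqrt(t_crit**2 / (t_crit**2 + df))
    zr = np.arctanh(q.r) + q.r / (2 * (q.n - 1))
    z_crit = np.arctanh(r_crit)
    sd = 1.0 / np.sqrt(q.n - 3)
    power = stats.norm.cdf((zr - z_crit) / sd)
    if q.sides == 2:
        power += stats.norm.cdf((-zr - z_crit) / sd)
    return float(power)


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Per-test level controlling the family-wise error: alpha / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests
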