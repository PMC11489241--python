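"""Exact two-sample t-test power and per-arm sample size from MSDR x slowing.

A treatment that slows progression by fraction ``s`` shifts the mean
composite CFB by ``s`` times the placebo mean while leaving its SD, so the
detectable standardized effect size is ``d = s * MSDR``.  Power for a
two-sided two-sample t-test at equal allocation is evaluated exactly from
the noncentral t distribution with df = 2n - 2 and noncentrality
d * sqrt(n/2); the required per-arm sample size is the smallest n whose
power reaches the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = ["PowerResult", "ttest_power", "sample_size_per_arm", "power_table"]


@dataclass(frozen=True)
class PowerResult:
    label: str
    msdr: float
    slowing: float
    power_target: float
    alpha: float
    effect_size: float
    n_per_arm: int


def ttest_power(n_per_arm: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test at equal allocation."""
    if n_per_arm < 2:
        raise ParameterError("n_per_arm must be at least 2")
    if d <= 0:
        raise ParameterError("effect size d must be positive")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    df = 2 * n_per_arm - 2
    ncp = d * np.sqrt(n_per_arm / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_per_arm(
    msdr: float, slowing: float, power: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest per-arm n whose exact power reaches the target.

    Bracket with the normal approximation 2(z_{1-a/2}+z_{1-b})^2/d^2, then
    step the integer n to the exact noncentral-t boundary.
    """
    if msdr <= 0:
        raise ParameterError("msdr must be positive")
    if not (0.0 < slowing <= 1.0):
        raise ParameterError("slowing must be in (0, 1]")
    if not (0.0 < power < 1.0):
        raise ParameterError("power must be in (0, 1)")
    d = slowing * msdr
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(2, int(np.floor(2.0 * ((za + zb) / d) ** 2)) - 2)
    while ttest_power(n, d, alpha) < power:
        n += 1
    while n > 2 and ttest_power(n - 1, d, alpha) >= power:
        n -= 1
    return n


def power_table(
    msdrs: dict[str, float],
    slowings: list[float],
    powers: list[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-arm sample sizes over the full MSDR x slowing x power grid."""
    if not msdrs or not slowings or not powers:
        raise ParameterError("power_table needs a nonempty grid")
    rows = []
    for label, m in msdrs.items():
        for s in slowings:
            for pw in powers:
                n = sample_size_per_arm(m, s, pw, alpha)
                rows.append(
                    PowerResult(
                        label=label,
                        msdr=m,
                        slowing=s,
                        power_target=pw,
                        alpha=alpha,
                        effect_size=s * m,
                        n_per_arm=n,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])
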