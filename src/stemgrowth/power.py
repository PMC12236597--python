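"""Unbalanced one-way ANOVA power for genotype-phenotype association.

Under HWE the three genotype groups occur with frequencies (p^2, 2pq, q^2).
Given mean differences delta = (het - hom1, hom2 - het) in phenotype units
and residual SD sigma, the test of equal group means at level alpha is a
one-way ANOVA with noncentrality

    lambda = n * sum_g f_g (mu_g - mu_bar)^2 / sigma^2,

and power = P( F'(2, n-3, lambda) > F_crit(alpha; 2, n-3) ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats


@dataclass
class PowerQuery:
    maf: float
    delta: Tuple[float, float]
    sigma: float
    alpha: float

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if np.isscalar(self.delta):
            self.delta = (float(self.delta), float(self.delta))


def _noncentrality(q: PowerQuery, n: int) -> float:
    p = 1.0 - q.maf
    f = np.array([p**2, 2 * p * q.maf, q.maf**2])  # hom1, het, hom2
    d1, d2 = q.delta
    mu = np.array([0.0, d1, d1 + d2])
    mbar = float(f @ mu)
    return n * float(f @ (mu - mbar) ** 2) / q.sigma**2


def genotype_anova_power(q: PowerQuery, n: int) -> float:
    """Analytic power of the genotype-group ANOVA at sample size ``n``."""
    if n <= 3:
        raise ValueError("n must exceed 3 (df2 = n - 3)")
    lam = _noncentrality(q, n)
    crit = stats.f.isf(q.alpha, 2, n - 3)
    if lam < 1e-10:  # central case; scipy's ncf is unreliable at nc = 0
        return float(q.alpha)
    return float(stats.ncf.sf(crit, 2, n - 3, lam))


def required_sample_size(
    q: PowerQuery, target_power: float, n_max: int = 10_000_000
) -> int:
    """Smallest n with power >= ``target_power`` (bisection on n)."""
    if not q.alpha < target_power < 1.0:
        raise ValueError("target power must be in (alpha, 1)")
    if _noncentrality(q, 1) <= 0:
        raise ValueError("zero effect size: target power unreachable")
    lo, hi = 4, 8
    while genotype_anova_power(q, hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable below n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if genotype_anova_power(q, mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_grid(
    mafs, deltas, sigma: float, alpha: float, ns
) -> "pd.DataFrame":  # noqa: F821
    """Power over a (maf x delta x n) grid as a tidy frame."""
    import pandas as pd

    rows = []
    for maf in mafs:
        for d in deltas:
            q = PowerQuery(maf=maf, delta=(d, d), sigma=sigma, alpha=alpha)
            for n in ns:
                rows.append(
                    {"maf": maf, "delta": d, "n": n,
                     "power": genotype_anova_power(q, n)}
                )
    return pd.DataFrame(rows)
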