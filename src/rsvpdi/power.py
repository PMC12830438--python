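"""Sample-size planning for distractor-intrusion designs.

Between-group comparisons of DI rates suffer from the measure's large
between-subject spread (SD around .23 in adult cohorts), so raw group
differences translate into small standardized effects.  The two-group
planner computes exact power from the noncentral-t distribution of the
two-sample t statistic; the correlation planner uses the Fisher-z
approximation, with the method name recorded in its output because
published sample-size figures differ across software and tail conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SampleSizeCapError

TAILS = ("one", "two")
DEFAULT_CAP = 100_000


@dataclass(frozen=True)
class PowerQuery:
    delta: float | None = None  # raw group difference in DI-rate units
    sigma: float = 0.23  # between-subject SD of DI rate
    rho: float | None = None  # target correlation
    power: float = 0.80
    alpha: float = 0.05
    tails: str = "two"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if not 0.0 < self.power < 1.0:
            raise ConfigurationError("power must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0,1)")
        if self.tails not in TAILS:
            raise ConfigurationError(f"tails must be one of {TAILS}")


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05,
                       tails: str = "two") -> float:
    """Exact power of the two-sample t test at effect size d, n per group."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = abs(d) * np.sqrt(n_per_group / 2.0)
    if tails == "two":
        tcrit = stats.t.isf(alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    tcrit = stats.t.isf(alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def n_per_group(delta: float, sigma: float = 0.23, power: float = 0.80,
                alpha: float = 0.05, tails: str = "two",
                cap: int = DEFAULT_CAP) -> int:
    """Smallest per-group n giving the requested power for a raw difference
    ``delta`` in DI-rate units against between-subject SD ``sigma``.

    Depends on (delta, sigma) only through d = delta / sigma.  Raises
    SampleSizeCapError when the search exceeds ``cap``.
    """
    q = PowerQuery(delta=delta, sigma=sigma, power=power, alpha=alpha, tails=tails)
    if delta <= 0:
        raise ConfigurationError("delta must be > 0")
    d = delta / sigma
    lo, hi = 2, 2
    while power_two_sample_t(hi, d, q.alpha, q.tails) < q.power:
        if hi >= cap:
            raise SampleSizeCapError(cap)
        lo, hi = hi, min(hi * 2, cap)
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(mid, d, q.alpha, q.tails) >= q.power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def power_correlation_fisher_z(n: int, rho: float, alpha: float = 0.05,
                               tails: str = "one") -> float:
    """Power to detect a correlation rho at sample size n, Fisher-z approximation."""
    if n < 4:
        return 0.0
    zcrit = stats.norm.isf(alpha / 2.0 if tails == "two" else alpha)
    return float(stats.norm.cdf(np.sqrt(n - 3.0) * abs(np.arctanh(rho)) - zcrit))


def n_for_correlation(rho: float, power: float = 0.80, alpha: float = 0.05,
                      tails: str = "one", cap: int = DEFAULT_CAP) -> dict:
    """Smallest n detecting correlation rho with the requested power under the
    Fisher-z approximation.  The method name is recorded in the output since
    correlation-power algorithms differ across software."""
    q = PowerQuery(rho=rho, power=power, alpha=alpha, tails=tails)
    if not 0.0 < abs(rho) < 1.0:
        raise ConfigurationError("need 0 < |rho| < 1")
    n = 4
    while power_correlation_fisher_z(n, rho, q.alpha, q.tails) < q.power:
        n += 1
        if n > cap:
            raise SampleSizeCapError(cap)
    return {"n": int(n), "rho": rho, "power": power, "alpha": alpha,
            "tails": tails, "method": "fisher_z"}


def power_curve(deltas, sigma: float = 0.23, power: float = 0.80,
                alpha: float = 0.05, cap: int = DEFAULT_CAP) -> pd.DataFrame:
    """Per-group n over a grid of raw DI-rate differences, one- and two-tailed."""
    rows = []
    for delta in deltas:
        row = {"delta": float(delta), "sigma": sigma, "power": power, "alpha": alpha}
        for tails in TAILS:
            try:
                row[f"n_per_group_{tails}_tailed"] = n_per_group(
                    float(delta), sigma, power, alpha, tails, cap)
            except SampleSizeCapError:
                row[f"n_per_group_{tails}_tailed"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
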