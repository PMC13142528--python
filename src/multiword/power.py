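"""Monte-Carlo and closed-form power analysis for the paired suppression
contrast.

The pre-registration-style simulation draws, for each simulated subject, a
mean response in the two-word sequential condition (one-word mean plus a
suppression delta) and in the two-word simultaneous condition (one-word
mean), both with the same between-subject standard deviation, and tests
the paired difference with a two-sided paired t test.  Empirical power per
sample size is reported with a Monte-Carlo confidence interval, and the
smallest n reaching the target power is returned.

The noncentral-t closed form serves as the independent oracle: for a
standardized paired effect d, power(n) = P(|T| > t_crit) with
T ~ noncentral t(df = n - 1, ncp = d * sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "PowerConfig",
    "PowerResult",
    "simulate_power",
    "power_closed_form",
    "min_n_closed_form",
]


@dataclass
class PowerConfig:
    """Simulation settings; defaults follow the prior-study calibration
    (one-word mean 0.32 percent signal change, SD 0.2).  The suppression
    delta is a free input: the effect size the original analysis borrowed
    from earlier data is not published."""

    suppression_delta: float
    mean_1w: float = 0.32
    sd: float = 0.2
    n_grid: tuple[int, ...] = tuple(range(5, 41))
    alpha: float = 0.05
    target_power: float = 0.90
    reps: int = 5000
    seed: int = 0
    paired_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.reps < 100:
            raise ValueError("need at least 100 Monte-Carlo replicates")
        if len(self.n_grid) == 0:
            raise ValueError("n_grid must not be empty")
        if min(self.n_grid) < 2:
            raise ValueError("paired t test needs n >= 2")

    @property
    def effect_size_d(self) -> float:
        """Standardized paired effect: delta over the SD of the paired
        difference (sd * sqrt(2 (1 - rho)) for equal condition SDs)."""
        sd_diff = self.sd * np.sqrt(2.0 * (1.0 - self.paired_correlation))
        return self.suppression_delta / sd_diff


@dataclass
class PowerResult:
    table: pd.DataFrame  # columns n, power, mc_se, ci_low, ci_high
    minimal_n: int | None
    config: PowerConfig = field(repr=False, default=None)


def simulate_power(cfg: PowerConfig) -> PowerResult:
    """Monte-Carlo power over the sample-size grid.

    For each n: draw per-subject condition means (sequential =
    mean_1w + delta, simultaneous = mean_1w, shared SD, optional pairing
    correlation), run the two-sided paired t test at alpha, and report the
    rejection fraction.  The minimal n is the smallest grid point whose
    monotone-smoothed power (running maximum over increasing n) reaches
    the target.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    rho = cfg.paired_correlation
    for n in cfg.n_grid:
        z1 = rng.standard_normal((cfg.reps, n))
        z2 = rng.standard_normal((cfg.reps, n))
        common = rng.standard_normal((cfg.reps, n))
        seq = (cfg.mean_1w + cfg.suppression_delta
               + cfg.sd * (np.sqrt(rho) * common + np.sqrt(1 - rho) * z1))
        sim = (cfg.mean_1w
               + cfg.sd * (np.sqrt(rho) * common + np.sqrt(1 - rho) * z2))
        diff = seq - sim
        mean = diff.mean(axis=1)
        sd = diff.std(axis=1, ddof=1)
        tstat = mean / (sd / np.sqrt(n))
        pvals = 2.0 * sps.t.sf(np.abs(tstat), df=n - 1)
        power = float(np.mean(pvals < cfg.alpha))
        se = float(np.sqrt(power * (1 - power) / cfg.reps))
        rows.append(
            {"n": n, "power": power, "mc_se": se,
             "ci_low": max(0.0, power - 1.96 * se),
             "ci_high": min(1.0, power + 1.96 * se)}
        )
    table = pd.DataFrame(rows).sort_values("n", ignore_index=True)
    smoothed = table["power"].cummax()
    hit = table.loc[smoothed >= cfg.target_power, "n"]
    minimal_n = int(hit.iloc[0]) if len(hit) else None
    return PowerResult(table=table, minimal_n=minimal_n, config=cfg)


def power_closed_form(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact two-sided paired-t power via the noncentral t distribution."""
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    df = n - 1
    ncp = d * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def min_n_closed_form(
    d: float, target_power: float = 0.90, alpha: float = 0.05,
    n_max: int = 10_000,
) -> int:
    """Smallest n whose closed-form paired-t power reaches the target."""
    for n in range(2, n_max + 1):
        if power_closed_form(d, n, alpha) >= target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")
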