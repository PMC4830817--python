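"""Analytic power solvers and the empirical power curve.

``solve_power_parameter`` completes a power query (effect size, per-group n,
power — exactly one unknown) by root-finding on the exact noncentral-t power.
``empirical_power_curve`` estimates power by Monte Carlo across a grid of
alternative means, the way an applied power analysis explores a design.

"Sample size" is per group throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import RandomStream, batch_two_sample_t, noncentral_t_power

__all__ = ["PowerQuery", "EmpiricalPowerCurve", "solve_power_parameter", "empirical_power_curve"]

_MAX_N = 10_000_000


@dataclass(frozen=True)
class PowerQuery:
    """One power-analysis question: exactly one of d, n_per_group, power is None."""

    d: float | None = None
    n_per_group: int | None = None
    power: float | None = None
    alpha: float = 0.05
    tails: str = "two"

    def unknown(self) -> str:
        missing = [k for k in ("d", "n_per_group", "power") if getattr(self, k) is None]
        if len(missing) != 1:
            raise ValueError(
                f"exactly one of d, n_per_group, power must be unknown (got {missing or 'none'})"
            )
        return missing[0]


@dataclass(frozen=True)
class EmpiricalPowerCurve:
    """Monte Carlo power estimates across a grid of alternative means."""

    alternative_means: np.ndarray
    power_raw: np.ndarray
    power_smoothed: np.ndarray
    reps: int
    null_mean: float
    sd: float
    n_per_group: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alt_mean": self.alternative_means,
                "power_raw": self.power_raw,
                "power_smoothed": self.power_smoothed,
            }
        )


def solve_power_parameter(query: PowerQuery) -> PowerQuery:
    """Fill in the single unknown of a :class:`PowerQuery`.

    Solving for n returns the smallest integer per-group size reaching the
    requested power (never a fractional n).  Raises if the target is
    unattainable, e.g. requested power below alpha.
    """
    unknown = query.unknown()
    if not 0 < query.alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    if unknown == "power":
        pw = noncentral_t_power(query.d, query.n_per_group, query.n_per_group,
                                query.alpha, query.tails)
        return replace(query, power=pw)

    if not query.alpha < query.power < 1:
        raise ValueError("requested power must lie strictly between alpha and 1")

    if unknown == "d":
        n = query.n_per_group

        def gap(d: float) -> float:
            return noncentral_t_power(d, n, n, query.alpha, query.tails) - query.power

        hi = 0.5
        while gap(hi) < 0:
            hi *= 2
            if hi > 100:
                raise ValueError("no effect size attains the requested power")
        d = optimize.brentq(gap, 0.0, hi, xtol=1e-10)
        return replace(query, d=float(d))

    # unknown == "n_per_group": smallest integer n with power >= target
    if query.d == 0:
        raise ValueError("power above alpha is unattainable at d = 0")
    d = abs(query.d)
    lo, hi = 2, 2
    while noncentral_t_power(d, hi, hi, query.alpha, query.tails) < query.power:
        lo, hi = hi, hi * 2
        if hi > _MAX_N:
            raise ValueError("required sample size exceeds solver bound")
    while lo < hi:
        mid = (lo + hi) // 2
        if noncentral_t_power(d, mid, mid, query.alpha, query.tails) >= query.power:
            hi = mid
        else:
            lo = mid + 1
    return replace(query, n_per_group=int(lo))


def empirical_power_curve(
    null_mean: float,
    sd: float,
    alt_grid,
    n_per_group: int,
    alpha: float,
    reps: int,
    stream: RandomStream,
    smooth_frac: float = 0.3,
) -> EmpiricalPowerCurve:
    """Monte Carlo power at each alternative mean on a grid.

    Per grid point, ``reps`` paired experiments are simulated: one group from
    N(alt, sd) vs one from N(null_mean, sd), pooled two-sided t at ``alpha``.
    The raw rejection fractions are lowess-smoothed (span ``smooth_frac``).
    """
    grid = np.asarray(alt_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alternative-mean grid must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    raw = np.empty(grid.size)
    for i, alt in enumerate(grid):
        rng = stream.child(i).rng
        a = rng.normal(alt, sd, size=(reps, n_per_group))
        b = rng.normal(null_mean, sd, size=(reps, n_per_group))
        _, p, _ = batch_two_sample_t(a, b)
        raw[i] = float(np.mean(p < alpha))

    if grid.size >= 5:
        smoothed = lowess(raw, grid, frac=smooth_frac, return_sorted=False)
        smoothed = np.clip(smoothed, 0.0, 1.0)
    else:
        smoothed = raw.copy()

    return EmpiricalPowerCurve(
        alternative_means=grid,
        power_raw=raw,
        power_smoothed=smoothed,
        reps=reps,
        null_mean=null_mean,
        sd=sd,
        n_per_group=n_per_group,
        alpha=alpha,
    )
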