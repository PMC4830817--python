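"""Seeded random streams, two-sample t machinery, and distribution utilities.

Everything stochastic in this package draws from a :class:`RandomStream`, a
thin wrapper around numpy's PCG64 generator.  Replicated experiments use
``stream.child(i)`` so that replication ``i`` sees the same draws no matter
how many replications run in total — rerunning with a larger ``reps`` never
invalidates earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RandomStream",
    "GroupSpec",
    "TTestResult",
    "two_sample_t",
    "batch_two_sample_t",
    "truncated_normal_mean",
    "noncentral_t_power",
]


@dataclass
class RandomStream:
    """A seeded, reproducible source of random draws.

    Parameters
    ----------
    seed : int
        Non-negative root seed.  Two streams built from the same seed and
        label produce identical draw sequences.
    label : str
        Identifier of the generator algorithm (informational).
    """

    seed: int
    label: str = "pcg64"
    _spawn_key: tuple = ()
    rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        ss = np.random.SeedSequence(self.seed, spawn_key=self._spawn_key)
        self.rng = np.random.Generator(np.random.PCG64(ss))

    def child(self, index: int) -> "RandomStream":
        """Deterministic child stream for replication ``index``.

        The child depends only on (root seed, index), never on how much the
        parent has already drawn.
        """
        return RandomStream(self.seed, self.label, self._spawn_key + (index,))


@dataclass(frozen=True)
class GroupSpec:
    """Normal population for one experimental arm (IQ-style scores)."""

    n: int
    mean: float = 100.0
    sd: float = 15.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def draw(self, stream: RandomStream) -> np.ndarray:
        return stream.rng.normal(self.mean, self.sd, size=self.n)


@dataclass(frozen=True)
class TTestResult:
    """One two-group comparison: t statistic, df, p-value, Cohen's d."""

    statistic: float
    df: float
    p_value: float
    cohens_d: float
    mean_diff: float


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    return float(
        np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    )


def two_sample_t(
    group_a,
    group_b,
    tails: str = "two",
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test with Cohen's d.

    Pooled-variance Student t by default (the designs simulated here use
    equal group sizes and equal SDs); set ``welch=True`` for the unequal
    variance form.  ``tails="one"`` halves the two-sided p, i.e. tests in
    the direction actually observed.  Cohen's d always uses the pooled
    (Bessel-corrected) SD.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")

    sp = _pooled_sd(a, b)
    if sp == 0.0:
        raise ValueError("zero pooled variance: degenerate (constant) input")

    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if tails == "one":
        p /= 2.0
    mean_diff = float(a.mean() - b.mean())
    return TTestResult(
        statistic=t,
        df=df,
        p_value=min(max(p, np.finfo(float).tiny), 1.0),
        cohens_d=mean_diff / sp,
        mean_diff=mean_diff,
    )


def batch_two_sample_t(a: np.ndarray, b: np.ndarray):
    """Vectorised pooled two-sided t over replications.

    ``a`` and ``b`` are (reps, n1) and (reps, n2) arrays; returns arrays
    (t, p, cohens_d) of length reps.  Used by the Monte Carlo loops, where
    calling :func:`two_sample_t` per replication would dominate runtime.
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / df)
    diff = a.mean(axis=1) - b.mean(axis=1)
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, diff / sp


def truncated_normal_mean(z_cut: float, side: str = "lower") -> float:
    """Mean of a standard normal truncated at ``z_cut``.

    ``lower`` returns E[Z | Z <= z_cut] = -phi(z)/Phi(z); ``upper`` returns
    E[Z | Z >= z_cut] = phi(z)/(1 - Phi(z)).  This is the inverse Mills
    ratio underlying regression toward the mean under quantile selection.
    """
    if not np.isfinite(z_cut):
        if side == "lower" and z_cut > 0:
            return 0.0
        if side == "upper" and z_cut < 0:
            return 0.0
        raise ValueError("z_cut must be finite (or the untruncated side)")
    z = float(z_cut)
    if side == "lower":
        return float(-stats.norm.pdf(z) / stats.norm.cdf(z))
    if side == "upper":
        return float(stats.norm.pdf(z) / stats.norm.sf(z))
    raise ValueError("side must be 'lower' or 'upper'")


def noncentral_t_power(
    d: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    tails: str = "two",
) -> float:
    """Exact power of the pooled two-sample t-test.

    Uses the noncentral t distribution with noncentrality
    d * sqrt(n1 n2 / (n1 + n2)).  At d = 0 this returns alpha (the test's
    size), as it must.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")

    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    k = 2 if tails == "two" else 1
    tcrit = stats.t.ppf(1 - alpha / k, df)
    power = stats.nct.sf(tcrit, df, nc)
    if tails == "two":
        power += stats.nct.cdf(-tcrit, df, nc)
    return float(power)
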