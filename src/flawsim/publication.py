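"""Study pools, significance filters, funnel data, and p-curves.

A study pool is a literature-in-silico: per study an (n per group, true d)
pair is drawn uniformly, a two-group experiment is simulated, and the
observed d and p recorded.  Filtering on p < alpha reproduces the familiar
pathologies: inflated published effects at small n, an asymmetric funnel,
and — with the explicit relocation model in :func:`biased_p_curve` — the
tell-tale bump of p-values just under .05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RandomStream, batch_two_sample_t

__all__ = [
    "StudyPool",
    "PCurve",
    "generate_study_pool",
    "apply_publication_filter",
    "funnel_data",
    "p_curve",
    "biased_p_curve",
]


@dataclass(frozen=True)
class StudyPool:
    """One simulated study per row: design, truth, and observed outcome."""

    table: pd.DataFrame  # columns: n_per_group, true_d, observed_d, p_value, published

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class PCurve:
    """Histogram of p-values over (0, 1] with fixed-width bins."""

    bin_edges: np.ndarray
    densities: np.ndarray  # relative frequencies, sum to 1
    reps: int
    p_values: np.ndarray

    def significant_fraction(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p_values < alpha))


def generate_study_pool(
    size: int,
    n_range: tuple[int, int] = (5, 100),
    d_range: tuple[float, float] = (0.0, 2.0),
    sd: float = 15.0,
    mean: float = 100.0,
    stream: RandomStream | None = None,
) -> StudyPool:
    """Simulate a pool of two-group studies with independent (n, d) draws.

    n per group is uniform on the integers of ``n_range``; the true effect d
    is uniform on ``d_range``; the two draws are independent, so true effect
    and sample size are uncorrelated across the pool.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    n_lo, n_hi = n_range
    if n_lo < 2 or n_hi < n_lo:
        raise ValueError("n_range must satisfy 2 <= lo <= hi")
    d_lo, d_hi = d_range
    if d_hi < d_lo:
        raise ValueError("d_range must be ordered")
    if stream is None:
        stream = RandomStream(0)

    rng = stream.rng
    ns = rng.integers(n_lo, n_hi + 1, size=size)
    ds = rng.uniform(d_lo, d_hi, size=size)

    observed_d = np.empty(size)
    p = np.empty(size)
    # batch the simulation by group size so each batch is one vectorised call
    for n in np.unique(ns):
        idx = np.flatnonzero(ns == n)
        exp = rng.normal(mean + ds[idx, None] * sd, sd, size=(len(idx), n))
        ctl = rng.normal(mean, sd, size=(len(idx), n))
        _, p[idx], observed_d[idx] = batch_two_sample_t(exp, ctl)

    table = pd.DataFrame(
        {
            "n_per_group": ns,
            "true_d": ds,
            "observed_d": observed_d,
            "p_value": p,
            "published": np.ones(size, dtype=bool),
        }
    )
    return StudyPool(table)


def apply_publication_filter(pool: StudyPool, alpha: float = 0.05) -> StudyPool:
    """Mark studies as published iff p < alpha."""
    table = pool.table.copy()
    table["published"] = table["p_value"] < alpha
    return StudyPool(table)


def funnel_data(
    pool: StudyPool,
    published_only: bool = False,
    n_bins: int = 10,
) -> dict[str, pd.DataFrame]:
    """Funnel-plot points plus a per-sample-size dispersion summary.

    Returns ``points`` (observed_d, n_per_group per study) and ``strata``
    (n bins with mean and SD of observed d).  Larger studies cluster around
    the true effect; small ones scatter — and filtering on significance
    leaves only the large observed effects at small n.
    """
    table = pool.table
    if published_only:
        table = table[table["published"]]
    if table.empty:
        raise ValueError("no studies selected")

    points = table[["observed_d", "n_per_group"]].reset_index(drop=True)
    edges = np.unique(
        np.quantile(table["n_per_group"], np.linspace(0, 1, n_bins + 1)).astype(int)
    )
    bins = pd.cut(table["n_per_group"], bins=edges, include_lowest=True)
    strata = (
        table.groupby(bins, observed=True)["observed_d"]
        .agg(mean="mean", sd="std", count="size")
        .reset_index()
    )
    strata["n_mid"] = strata["n_per_group"].map(lambda iv: iv.mid).astype(float)
    return {"points": points, "strata": strata}


def _simulate_p_values(
    reps: int, n_per_group: int, d: float, sd: float, mean: float, stream: RandomStream
) -> np.ndarray:
    rng = stream.rng
    exp = rng.normal(mean + d * sd, sd, size=(reps, n_per_group))
    ctl = rng.normal(mean, sd, size=(reps, n_per_group))
    _, p, _ = batch_two_sample_t(exp, ctl)
    return p


def _histogram(p: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    return edges, counts / counts.sum()


def p_curve(
    reps: int,
    n_per_group: int,
    d: float,
    sd: float = 20.0,
    bin_width: float = 0.01,
    mean: float = 100.0,
    stream: RandomStream | None = None,
) -> PCurve:
    """Distribution of p-values from repeated two-group experiments.

    d = 0 gives a flat (uniform) curve; d > 0 piles mass at small p with no
    discontinuity anywhere, in particular not at .05.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < bin_width <= 0.5:
        raise ValueError("bin_width must be in (0, 0.5]")
    if stream is None:
        stream = RandomStream(0)
    p = _simulate_p_values(reps, n_per_group, d, sd, mean, stream)
    edges, dens = _histogram(p, bin_width)
    return PCurve(bin_edges=edges, densities=dens, reps=reps, p_values=p)


def biased_p_curve(
    reps: int,
    n_per_group: int,
    d: float,
    sd: float = 20.0,
    bin_width: float = 0.01,
    mean: float = 100.0,
    shift_fraction: float = 0.3,
    shift_window: tuple[float, float] = (0.05, 0.10),
    stream: RandomStream | None = None,
) -> PCurve:
    """p-curve under a simple p-hacking selection model.

    A fraction of the results landing in ``shift_window`` (just above .05)
    is relocated uniformly into the bin immediately below .05, producing the
    local bump seen in biased literatures.  Total mass is conserved; one of
    several possible selection models.
    """
    lo, hi = shift_window
    if not (lo == 0.05 and hi > lo):
        raise ValueError("shift_window must start at 0.05 and extend above it")
    if not 0 <= shift_fraction <= 1:
        raise ValueError("shift_fraction must be in [0, 1]")
    if stream is None:
        stream = RandomStream(0)

    p = _simulate_p_values(reps, n_per_group, d, sd, mean, stream)
    in_window = np.flatnonzero((p > lo) & (p <= hi))
    rng = stream.rng
    n_shift = int(round(shift_fraction * len(in_window)))
    if n_shift:
        chosen = rng.choice(in_window, size=n_shift, replace=False)
        p = p.copy()
        p[chosen] = rng.uniform(max(0.05 - bin_width, 0.0), 0.05, size=n_shift)
    edges, dens = _histogram(p, bin_width)
    return PCurve(bin_edges=edges, densities=dens, reps=reps, p_values=p)
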