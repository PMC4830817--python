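"""Regression toward the mean under quantile splits of pretest scores.

With test-retest correlation rho < 1, subjects selected for an extreme
pretest score move toward the mean at posttest even with zero true change.
The expected gain of a lower-tail "low performers" group has the closed form

    E[gain | selected] = (rho - 1) * sd * E[Z | Z on the selected side],

with the truncated-normal mean supplying E[Z | . ].  The simulator draws
pre/post pairs that are marginally N(mean, sd) with correlation rho and no
mean shift ("no test-retest effect"), so any group-level gain after a split
is pure selection artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RandomStream, truncated_normal_mean

__all__ = [
    "PrePostSample",
    "SplitSummary",
    "simulate_pre_post",
    "expected_gain_under_selection",
    "quantile_split_summary",
    "deviation_gain_curve",
]


@dataclass(frozen=True)
class PrePostSample:
    """Paired pre/post scores plus the parameters that generated them."""

    pre: np.ndarray
    post: np.ndarray
    mean: float
    sd: float
    test_retest_rho: float

    @property
    def gain(self) -> np.ndarray:
        return self.post - self.pre


@dataclass(frozen=True)
class SplitSummary:
    """Pre/post/gain means after a quantile split into low vs rest."""

    cut_quantile: float
    low_n: int
    low_pre_mean: float
    low_post_mean: float
    low_gain: float
    rest_n: int
    rest_pre_mean: float
    rest_post_mean: float
    rest_gain: float


def simulate_pre_post(
    n: int,
    mean: float,
    sd: float,
    rho: float,
    stream: RandomStream,
) -> PrePostSample:
    """Bivariate-normal pre/post scores with identical margins.

    Both sessions are N(mean, sd); corr(pre, post) = rho.  rho = 1 returns
    post identical to pre.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")

    rng = stream.rng
    z1 = rng.standard_normal(n)
    if rho == 1.0:
        z2 = z1
    else:
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return PrePostSample(
        pre=mean + sd * z1,
        post=mean + sd * z2,
        mean=mean,
        sd=sd,
        test_retest_rho=rho,
    )


def expected_gain_under_selection(
    rho: float,
    sd: float,
    cut_quantile: float,
    side: str = "lower",
) -> float:
    """Closed-form expected gain of a tail-selected group with no true change.

    Selecting the lower tail (pre below its ``cut_quantile``) yields a
    positive expected gain whenever rho < 1; upper-tail selection is the
    mirror image.
    """
    if not 0 < cut_quantile < 1:
        raise ValueError("cut_quantile must be in (0, 1)")
    if side == "lower":
        z_cut = stats.norm.ppf(cut_quantile)
    elif side == "upper":
        z_cut = stats.norm.ppf(1.0 - cut_quantile)  # cut_quantile = tail mass
    else:
        raise ValueError("side must be 'lower' or 'upper'")
    return (rho - 1.0) * sd * truncated_normal_mean(z_cut, side)


def quantile_split_summary(sample: PrePostSample, cut_quantile: float) -> SplitSummary:
    """Split at the empirical pretest quantile (low group: pre <= cut).

    Uses numpy's default (type-7) empirical quantile; membership is
    "inferior or equal" to the cut score.
    """
    if not 0 < cut_quantile < 1:
        raise ValueError("cut_quantile must be in (0, 1)")
    cut = np.quantile(sample.pre, cut_quantile)
    low = sample.pre <= cut
    rest = ~low
    if low.sum() == 0 or rest.sum() == 0:
        raise ValueError("quantile split produced an empty group")
    return SplitSummary(
        cut_quantile=cut_quantile,
        low_n=int(low.sum()),
        low_pre_mean=float(sample.pre[low].mean()),
        low_post_mean=float(sample.post[low].mean()),
        low_gain=float(sample.gain[low].mean()),
        rest_n=int(rest.sum()),
        rest_pre_mean=float(sample.pre[rest].mean()),
        rest_post_mean=float(sample.post[rest].mean()),
        rest_gain=float(sample.gain[rest].mean()),
    )


def deviation_gain_curve(sample: PrePostSample, n_bins: int) -> dict[str, pd.DataFrame]:
    """Binned relationship between pretest deviation and absolute gain.

    Returns two tables built from equal-count (quantile) bins:

    - ``"absolute"``: |pre - mean| bins vs mean |gain| — increasing when
      rho < 1 (the farther from the mean, the larger the expected change);
    - ``"signed"``: signed deviation bins vs mean |gain| — U-shaped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    def _binned(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9  # include the minimum in the first bin
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        df = pd.DataFrame({"bin": idx, "x": x, "y": y})
        out = df.groupby("bin").agg(
            bin_center=("x", "mean"), mean_abs_gain=("y", "mean"), count=("x", "size")
        )
        return out.reset_index(drop=True)

    abs_gain = np.abs(sample.gain)
    deviation = sample.pre - sample.mean
    return {
        "absolute": _binned(np.abs(deviation), abs_gain),
        "signed": _binned(deviation, abs_gain),
    }
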