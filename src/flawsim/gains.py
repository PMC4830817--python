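"""Correlated gain scores without transfer, and the interaction remedy.

Gain scores on a trained task and a transfer task can correlate purely
because the tasks correlated at pretest.  With the four variables ordered
(training_pre, transfer_pre, training_post, transfer_post) and covariance C,

    Cov(gain_t, gain_x) = C[2,3] - C[2,1] - C[0,3] + C[0,1]

normalized by the two gain SDs.  In the benchmark case — pretests correlated
at rho, posttests independent of everything, equal variances — this gives
r_gain = rho / 2 with zero transfer built in.

The recommended test of transfer is the group x session interaction, which
for a 2-group / 2-session design is algebraically the two-sample t on gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RandomStream, TTestResult, two_sample_t
from .regression_mean import PrePostSample

__all__ = [
    "TwoTaskPrePost",
    "GainCorrelationResult",
    "InteractionTestResult",
    "default_covariance",
    "gain_correlation_analytic",
    "simulate_two_task",
    "mean_shift_invariance_check",
    "transfer_interaction_test",
]

# variable order used throughout this module
VARIABLES = ("training_pre", "transfer_pre", "training_post", "transfer_post")


@dataclass(frozen=True)
class TwoTaskPrePost:
    """Scores on a training and a transfer task at two sessions."""

    training_pre: np.ndarray
    transfer_pre: np.ndarray
    training_post: np.ndarray
    transfer_post: np.ndarray
    covariance: np.ndarray
    means: np.ndarray

    def as_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.training_pre, self.transfer_pre, self.training_post, self.transfer_post]
        )

    @property
    def training_gain(self) -> np.ndarray:
        return self.training_post - self.training_pre

    @property
    def transfer_gain(self) -> np.ndarray:
        return self.transfer_post - self.transfer_pre


@dataclass(frozen=True)
class GainCorrelationResult:
    r_gain_empirical: float
    r_gain_analytic: float
    n: int


@dataclass(frozen=True)
class InteractionTestResult:
    """Group x session interaction for a 2x2 pre/post design."""

    interaction_estimate: float
    statistic: float
    df: float
    p_value: float
    control_pre_mean: float
    control_post_mean: float
    experimental_pre_mean: float
    experimental_post_mean: float


def default_covariance(rho_pre: float = 0.92, sd: float = 15.0) -> np.ndarray:
    """Benchmark covariance: pretests correlated, posttests independent."""
    if abs(rho_pre) > 1:
        raise ValueError("|rho_pre| must be <= 1")
    cov = np.eye(4) * sd**2
    cov[0, 1] = cov[1, 0] = rho_pre * sd**2
    return cov


def _check_covariance(cov) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (4, 4):
        raise ValueError("covariance must be 4x4, ordered " + ", ".join(VARIABLES))
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise ValueError("covariance must be positive semi-definite")
    return cov


def gain_correlation_analytic(cov) -> float:
    """Exact correlation of the two gain scores from covariance algebra."""
    c = _check_covariance(cov)
    cov_gains = c[2, 3] - c[2, 1] - c[0, 3] + c[0, 1]
    var_t = c[2, 2] - 2 * c[0, 2] + c[0, 0]
    var_x = c[3, 3] - 2 * c[1, 3] + c[1, 1]
    if var_t <= 0 or var_x <= 0:
        raise ValueError("a gain score has zero variance (perfect retest): correlation undefined")
    return float(cov_gains / np.sqrt(var_t * var_x))


def simulate_two_task(
    n: int,
    cov=None,
    means=None,
    stream: RandomStream | None = None,
) -> tuple[TwoTaskPrePost, GainCorrelationResult]:
    """Draw n subjects from the 4-variate normal and compare empirical
    vs analytic gain correlation."""
    if n < 4:
        raise ValueError("n must be >= 4")
    cov = _check_covariance(default_covariance() if cov is None else cov)
    means = np.full(4, 100.0) if means is None else np.asarray(means, dtype=float)
    if means.shape != (4,):
        raise ValueError("means must have 4 entries, ordered " + ", ".join(VARIABLES))
    if stream is None:
        stream = RandomStream(0)

    x = stream.rng.multivariate_normal(means, cov, size=n, method="svd")
    sample = TwoTaskPrePost(
        training_pre=x[:, 0],
        transfer_pre=x[:, 1],
        training_post=x[:, 2],
        transfer_post=x[:, 3],
        covariance=cov,
        means=means,
    )
    r_emp = float(np.corrcoef(sample.training_gain, sample.transfer_gain)[0, 1])
    result = GainCorrelationResult(
        r_gain_empirical=r_emp,
        r_gain_analytic=gain_correlation_analytic(cov),
        n=n,
    )
    return sample, result


def mean_shift_invariance_check(base: TwoTaskPrePost, shifts) -> tuple[float, float]:
    """Gain correlation before and after adding constants to the variables.

    Correlations are unaffected by linear shifts, so simulated "transfer"
    (a posttest mean bump) cannot change the gain correlation.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (4,):
        raise ValueError("shifts must have 4 entries")
    before = float(np.corrcoef(base.training_gain, base.transfer_gain)[0, 1])
    x = base.as_matrix() + shifts
    after = float(np.corrcoef((x[:, 2] - x[:, 0]), (x[:, 3] - x[:, 1]))[0, 1])
    return before, after


def transfer_interaction_test(
    control: PrePostSample,
    experimental: PrePostSample,
) -> InteractionTestResult:
    """Group x session interaction test for transfer.

    Computed as the pooled two-sample t on gain scores (equivalent to the
    repeated-measures ANOVA interaction in the 2x2 design).  Pre AND post
    means are always reported per group, never just gains.
    """
    gain_c = control.gain
    gain_e = experimental.gain
    if len(gain_c) < 2 or len(gain_e) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.allclose(gain_e, gain_e.mean()) and np.allclose(gain_c, gain_c.mean()) \
            and np.isclose(gain_e.mean(), gain_c.mean()):
        res = TTestResult(0.0, len(gain_c) + len(gain_e) - 2, 1.0, 0.0, 0.0)
    else:
        res = two_sample_t(gain_e, gain_c)
    return InteractionTestResult(
        interaction_estimate=float(gain_e.mean() - gain_c.mean()),
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        control_pre_mean=float(control.pre.mean()),
        control_post_mean=float(control.post.mean()),
        experimental_pre_mean=float(experimental.pre.mean()),
        experimental_post_mean=float(experimental.post.mean()),
    )
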