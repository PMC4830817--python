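"""Sampling error under the null, and group-assignment remedies.

Even when every subject is drawn from one population, randomly split groups
differ at baseline: significantly so at rate alpha, and substantially so (in
Cohen's d units) whenever samples are small.  The two remedies implemented
are rerandomization (redraw assignments until baseline balance passes a
threshold) and blocking (stratify on pretest score, assign half of each
block to each arm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RandomStream, batch_two_sample_t

__all__ = [
    "NullExperimentResult",
    "AssignmentPlan",
    "simulate_null_assignment",
    "median_abs_effect_curve",
    "assign_groups",
]

RERANDOMIZATION_CAP = 10_000


@dataclass(frozen=True)
class NullExperimentResult:
    """p-values from repeated null experiments, with running diagnostics."""

    p_values: np.ndarray
    cumulative_mean_p: np.ndarray
    rejection_rate: float
    alpha: float


@dataclass(frozen=True)
class AssignmentPlan:
    """Group labels (0/1) per subject plus the standardized baseline gap."""

    assignments: np.ndarray
    method: str
    balance_stat: float


def simulate_null_assignment(
    total_n: int,
    mean: float = 100.0,
    sd: float = 15.0,
    reps: int = 10_000,
    alpha: float = 0.05,
    stream: RandomStream | None = None,
) -> NullExperimentResult:
    """Draw ``total_n`` scores from one normal, split in half, t-test; repeat.

    Under this true null the rejection rate converges to alpha and the
    running mean of the p-values converges to 0.5.  ``total_n`` must be even
    (two equal arms).  Because draws are i.i.d., splitting the vector in half
    is distributionally identical to a random division.
    """
    if total_n < 4 or total_n % 2:
        raise ValueError("total_n must be even and at least 4")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if stream is None:
        stream = RandomStream(0)

    half = total_n // 2
    scores = stream.rng.normal(mean, sd, size=(reps, total_n))
    _, p, _ = batch_two_sample_t(scores[:, :half], scores[:, half:])
    cum = np.cumsum(p) / np.arange(1, reps + 1)
    return NullExperimentResult(
        p_values=p,
        cumulative_mean_p=cum,
        rejection_rate=float(np.mean(p < alpha)),
        alpha=alpha,
    )


def median_abs_effect_curve(
    n_grid,
    reps: int,
    stream: RandomStream,
    mean: float = 100.0,
    sd: float = 15.0,
) -> "pd.DataFrame":
    """Median and quartiles of |Cohen's d| under H0, per per-group n.

    Small groups spuriously produce substantial standardized differences;
    the median |d| shrinks toward 0 as n grows.  Returns a DataFrame with
    columns n, q25, median, q75.
    """
    import pandas as pd

    n_grid = [int(n) for n in n_grid]
    if any(n < 2 for n in n_grid) or reps < 1:
        raise ValueError("each n must be >= 2 and reps >= 1")

    rows = []
    for i, n in enumerate(n_grid):
        rng = stream.child(i).rng
        a = rng.normal(mean, sd, size=(reps, n))
        b = rng.normal(mean, sd, size=(reps, n))
        _, _, d = batch_two_sample_t(a, b)
        q25, med, q75 = np.percentile(np.abs(d), [25, 50, 75])
        rows.append({"n": n, "q25": q25, "median": med, "q75": q75})
    return pd.DataFrame(rows)


def _balance_stat(scores: np.ndarray, assignments: np.ndarray) -> float:
    a = scores[assignments == 0]
    b = scores[assignments == 1]
    n1, n2 = len(a), len(b)
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def _split_in_half(n: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat([0, 1], [n - n // 2, n // 2])
    rng.shuffle(labels)
    return labels


def assign_groups(
    baseline_scores,
    method: str = "simple",
    threshold: float | None = None,
    n_blocks: int | None = None,
    stream: RandomStream | None = None,
) -> AssignmentPlan:
    """Assign subjects to two arms: simple, rerandomized, or blocked.

    rerandomized: redraw simple assignments until the absolute standardized
    baseline difference falls below ``threshold`` (capped at
    ``RERANDOMIZATION_CAP`` iterations).

    blocked: rank subjects by pretest score (ties broken at random), cut into
    ``n_blocks`` contiguous blocks, and assign half of each block to each arm,
    preserving baseline heterogeneity within both arms.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if stream is None:
        stream = RandomStream(0)
    rng = stream.rng

    if method == "simple":
        assignments = _split_in_half(n, rng)

    elif method == "rerandomized":
        if threshold is None or threshold <= 0:
            raise ValueError("rerandomized assignment needs a positive threshold")
        for _ in range(RERANDOMIZATION_CAP):
            assignments = _split_in_half(n, rng)
            if abs(_balance_stat(scores, assignments)) < threshold:
                break
        else:
            raise RuntimeError(
                f"no assignment met |balance| < {threshold} "
                f"within {RERANDOMIZATION_CAP} iterations"
            )

    elif method == "blocked":
        if n_blocks is None or n_blocks < 1 or n_blocks > n // 2:
            raise ValueError("n_blocks must be in [1, n//2]")
        # random keys break score ties so repeated scores spread across blocks
        order = np.lexsort((rng.random(n), scores))
        blocks = np.array_split(order, n_blocks)
        assignments = np.empty(n, dtype=int)
        deficit = 0  # arm-0 surplus carried across odd blocks to keep arms within 1
        for block in blocks:
            m = len(block)
            n1 = m // 2
            if m % 2:
                extra = 1 if deficit <= 0 else 0
                n1 += extra
                deficit += 1 if extra else -1
            labels = np.repeat([0, 1], [n1, m - n1])
            rng.shuffle(labels)
            assignments[block] = labels

    else:
        raise ValueError("method must be simple, rerandomized, or blocked")

    return AssignmentPlan(
        assignments=assignments,
        method=method,
        balance_stat=_balance_stat(scores, assignments),
    )
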