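"""Familywise error, Bonferroni, FDR/PPV arithmetic, and BH adjustment.

The worked example: if 10% of interventions are truly effective and each is
tested at alpha = .05 with power .80, then out of 10,000 interventions the
expected confusion table is 800 TP / 200 FN / 450 FP / 8550 TN, giving a
false discovery rate of 36% despite the "standard" error rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import RandomStream

__all__ = [
    "MultiplicityScenario",
    "ConfusionCounts",
    "familywise_error",
    "bonferroni_alpha",
    "confusion_counts",
    "fdr_prevalence_curve",
    "bh_adjust",
]


@dataclass(frozen=True)
class MultiplicityScenario:
    """k independent pairwise comparisons, each at level alpha."""

    k_comparisons: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k_comparisons < 1:
            raise ValueError("k_comparisons must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    """Expected TP/FN/FP/TN tallies for a population of interventions."""

    n_interventions: int
    prevalence: float
    power: float
    alpha: float
    tp: float
    fn: float
    fp: float
    tn: float
    fdr: float
    ppv: float


def familywise_error(scenario: MultiplicityScenario) -> float:
    """P(at least one false positive) = 1 - (1 - alpha)^k, independent tests."""
    return 1.0 - (1.0 - scenario.alpha) ** scenario.k_comparisons


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Per-test threshold alpha / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / k


def confusion_counts(
    n: int,
    prevalence: float,
    power: float,
    alpha: float,
    stream: RandomStream | None = None,
) -> ConfusionCounts:
    """Expected confusion table over n interventions.

    tp = n*pi*power, fn = n*pi*(1-power), fp = n*(1-pi)*alpha,
    tn = n*(1-pi)*(1-alpha); FDR = fp/(fp+tp), PPV = 1 - FDR.

    Deterministic expected counts by default; pass a stream to draw the
    cells binomially instead (a teaching mode — cells then vary but still
    satisfy the margin identities).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, v in (("prevalence", prevalence), ("power", power), ("alpha", alpha)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")

    if stream is None:
        n_true = n * prevalence
        tp = n_true * power
        fp = (n - n_true) * alpha
    else:
        rng = stream.rng
        n_true = rng.binomial(n, prevalence)
        tp = float(rng.binomial(n_true, power)) if n_true else 0.0
        fp = float(rng.binomial(n - n_true, alpha)) if n_true < n else 0.0
    fn = n_true - tp
    tn = (n - n_true) - fp

    positives = tp + fp
    if positives == 0:
        raise ZeroDivisionError("no positive results: FDR undefined")
    fdr = fp / positives
    return ConfusionCounts(
        n_interventions=n,
        prevalence=prevalence,
        power=power,
        alpha=alpha,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        fdr=fdr,
        ppv=1.0 - fdr,
    )


def fdr_prevalence_curve(
    prevalence_grid,
    alpha: float = 0.05,
    power_range: tuple[float, float] = (0.5, 1.0),
    reps: int = 1000,
    stream: RandomStream | None = None,
    reference_power: float = 0.8,
) -> pd.DataFrame:
    """FDR as a function of prevalence with power free to vary.

    Per replication, power is drawn uniformly on ``power_range`` and the FDR
    computed analytically; the summary reports median and quartiles per
    prevalence, plus the fixed-power reference line (power = .80 by default).
    """
    grid = np.asarray(prevalence_grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    lo, hi = power_range
    if not 0 <= lo <= hi <= 1:
        raise ValueError("invalid power range")
    if stream is None:
        stream = RandomStream(0)

    powers = stream.rng.uniform(lo, hi, size=reps)
    rows = []
    for pi in grid:
        fdr = (1 - pi) * alpha / ((1 - pi) * alpha + pi * powers)
        ref = (1 - pi) * alpha / ((1 - pi) * alpha + pi * reference_power)
        q25, med, q75 = np.percentile(fdr, [25, 50, 75])
        rows.append(
            {"prevalence": pi, "fdr_q25": q25, "fdr_median": med,
             "fdr_q75": q75, "fdr_at_reference_power": ref}
        )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
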