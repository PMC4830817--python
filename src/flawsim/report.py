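"""One-shot reproduction of every headline number, with pass/fail checks.

``reproduce_all`` reruns each demonstration at its reference settings and
compares the recomputed quantity with the value the source figures print,
using a tolerance appropriate to the quantity: half a unit of printed
precision for exact arithmetic, three Monte Carlo / Fisher-z standard errors
for stochastic estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import (
    MultiplicityScenario,
    RandomStream,
    bonferroni_alpha,
    composite_validity_analytic,
    confusion_counts,
    expected_gain_under_selection,
    familywise_error,
    gain_correlation_analytic,
    default_covariance,
    noncentral_t_power,
    p_curve,
    quantile_split_summary,
    simulate_battery,
    simulate_null_assignment,
    simulate_pre_post,
    simulate_two_task,
    unit_weighted_composite,
)

__all__ = ["CheckRow", "reproduce_all"]


@dataclass(frozen=True)
class CheckRow:
    quantity: str
    expected: float
    computed: float
    tolerance: float
    passed: bool


def _row(quantity: str, expected: float, computed: float, tolerance: float) -> CheckRow:
    return CheckRow(
        quantity=quantity,
        expected=float(expected),
        computed=float(computed),
        tolerance=float(tolerance),
        passed=bool(abs(computed - expected) <= tolerance),
    )


def _fisher_tol(r: float, n: int) -> float:
    """Three Fisher-z standard errors, mapped back to the r scale at r."""
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return float(max(np.tanh(z + 3 * se) - r, r - np.tanh(z - 3 * se)))


def reproduce_all(seed: int, reps_scale: float = 1.0) -> pd.DataFrame:
    """Recompute all printed quantities; returns a tidy comparison table.

    ``reps_scale`` scales the Monte Carlo replication counts (1.0 = the
    reference settings).
    """
    root = RandomStream(seed)
    rows: list[CheckRow] = []

    # --- multiple comparisons: exact arithmetic -------------------------
    for k, alpha, printed in [
        (10, 0.05, 0.40), (15, 0.05, 0.54), (20, 0.05, 0.64),
        (10, 0.01, 0.10), (15, 0.01, 0.14), (20, 0.01, 0.18),
    ]:
        fwe = familywise_error(MultiplicityScenario(k, alpha))
        rows.append(_row(f"fwer_k{k}_alpha{alpha}", printed, fwe, 0.005))
    for k, printed, tol in [(10, 0.005, 5e-4), (15, 0.003, 5e-4), (20, 0.0025, 5e-5)]:
        rows.append(_row(f"bonferroni_alpha05_k{k}", printed, bonferroni_alpha(0.05, k), tol))

    cc = confusion_counts(10_000, 0.10, 0.80, 0.05)
    for name, printed in [("tp", 800), ("fn", 200), ("fp", 450), ("tn", 8550)]:
        rows.append(_row(f"confusion_{name}", printed, getattr(cc, name), 0.5))
    rows.append(_row("fdr_worked_example", 0.36, cc.fdr, 0.005))
    rows.append(_row("ppv_worked_example", 0.64, cc.ppv, 0.005))

    # --- composite scores: validity of single vs pooled measurements ----
    n_batt = 10_000
    battery = simulate_battery(n_batt, 3, 100.0, 15.0, 7.5, stream=root.child(1))
    r_single = float(np.corrcoef(battery.measurements[:, 0], battery.construct)[0, 1])
    rows.append(_row("single_measurement_validity", 0.89, r_single,
                     _fisher_tol(composite_validity_analytic(15.0, [7.5], [1.0]), n_batt) + 0.005))
    r_unit = unit_weighted_composite(battery).validity
    rows.append(_row("unit_weighted_validity", 0.96, r_unit,
                     _fisher_tol(composite_validity_analytic(15.0, [7.5] * 3, [1.0] * 3), n_batt) + 0.005))

    # --- sampling error under the null ----------------------------------
    reps = max(int(10_000 * reps_scale), 100)
    null = simulate_null_assignment(40, reps=reps, stream=root.child(2))
    rows.append(_row("null_rejection_rate", 0.05, null.rejection_rate,
                     3 * np.sqrt(0.05 * 0.95 / reps)))
    rows.append(_row("null_cumulative_mean_p", 0.50, null.cumulative_mean_p[-1],
                     3 / np.sqrt(12 * reps)))

    # --- regression toward the mean --------------------------------------
    n_rtm = 10_000
    sample = simulate_pre_post(n_rtm, 100.0, 15.0, 0.0, stream=root.child(3))
    split = quantile_split_summary(sample, 0.25)
    closed = expected_gain_under_selection(0.0, 15.0, 0.25, "lower")
    # gain SD within the selected quarter is sd*sqrt(2) at rho=0, minus selection shrinkage
    se_low = 15.0 * np.sqrt(2) / np.sqrt(n_rtm * 0.25)
    rows.append(_row("low_group_gain_rho0", closed, split.low_gain, 3 * se_low))
    rows.append(_row("whole_sample_mean_gain", 0.0, float(sample.gain.mean()),
                     3 * 15.0 * np.sqrt(2) / np.sqrt(n_rtm)))

    # --- correlated gains -------------------------------------------------
    r_analytic = gain_correlation_analytic(default_covariance(0.92))
    rows.append(_row("gain_correlation_analytic_rho92", 0.46, r_analytic, 0.005))
    n_gain = 1000
    _, gres = simulate_two_task(n_gain, stream=root.child(4))
    rows.append(_row("gain_correlation_empirical_rho92", r_analytic,
                     gres.r_gain_empirical, _fisher_tol(r_analytic, n_gain)))

    # --- p-curve significant fraction ------------------------------------
    pc_reps = max(int(1000 * reps_scale), 100)
    pc = p_curve(pc_reps, 20, 0.5, sd=20.0, stream=root.child(5))
    analytic_power = noncentral_t_power(0.5, 20, 20)
    rows.append(_row("pcurve_significant_fraction_d05_n20", analytic_power,
                     pc.significant_fraction(),
                     3 * np.sqrt(analytic_power * (1 - analytic_power) / pc_reps)))

    return pd.DataFrame([asdict(r) for r in rows])
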