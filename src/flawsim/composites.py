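"""Latent-construct measurement batteries and composite-score estimators.

A battery is k noisy measurements of one latent construct: column j equals
construct + independent N(0, error_sd_j) noise.  A single measurement's
validity (correlation with the construct) is sigma_T / sqrt(sigma_T^2 +
sigma_Ej^2); combining measurements averages error out, and the validity of
any weighted composite has the closed form implemented in
:func:`composite_validity_analytic`.

Estimators: row median, unit-weighted mean, and a regression-weighted
composite whose weights come from a one-factor principal-axis fit (factor
scores by the regression method), computable without ever observing the
latent construct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RandomStream

__all__ = [
    "MeasurementBattery",
    "CompositeResult",
    "simulate_battery",
    "composite_validity_analytic",
    "unit_weighted_composite",
    "regression_weighted_composite",
    "median_composite",
    "principal_axis_loadings",
]


@dataclass(frozen=True)
class MeasurementBattery:
    """Latent construct plus its k noisy measurements (n x k matrix)."""

    construct: np.ndarray
    measurements: np.ndarray
    construct_sd: float
    error_sds: np.ndarray

    @property
    def n(self) -> int:
        return self.measurements.shape[0]

    @property
    def k(self) -> int:
        return self.measurements.shape[1]


@dataclass(frozen=True)
class CompositeResult:
    """Composite scores, the weights that built them, and their validity.

    ``validity`` is the Pearson correlation with the latent construct; it is
    None when the battery has no construct column (real data).
    """

    scores: np.ndarray
    weights: np.ndarray
    method: str
    validity: float | None


def simulate_battery(
    n: int,
    k: int,
    construct_mean: float = 100.0,
    construct_sd: float = 15.0,
    error_sds=7.5,
    stream: RandomStream | None = None,
) -> MeasurementBattery:
    """Simulate n subjects measured k times with independent normal error."""
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 and k >= 1")
    if construct_sd <= 0:
        raise ValueError("construct_sd must be positive")
    error_sds = np.broadcast_to(np.asarray(error_sds, dtype=float), (k,)).copy()
    if np.any(error_sds < 0):
        raise ValueError("error SDs must be non-negative")
    if stream is None:
        stream = RandomStream(0)

    rng = stream.rng
    construct = rng.normal(construct_mean, construct_sd, size=n)
    noise = rng.standard_normal((n, k)) * error_sds
    return MeasurementBattery(
        construct=construct,
        measurements=construct[:, None] + noise,
        construct_sd=construct_sd,
        error_sds=error_sds,
    )


def composite_validity_analytic(construct_sd: float, error_sds, weights) -> float:
    """Exact correlation of a weighted composite with the construct.

    corr(sum w_j M_j, T) = (sum w_j) sigma_T /
                           sqrt((sum w_j)^2 sigma_T^2 + sum w_j^2 sigma_Ej^2)
    """
    w = np.asarray(weights, dtype=float)
    e = np.asarray(error_sds, dtype=float)
    if w.shape != e.shape:
        raise ValueError("weights and error_sds must have the same length")
    sw = w.sum()
    var = sw**2 * construct_sd**2 + np.sum(w**2 * e**2)
    if var <= 0 or construct_sd <= 0 or np.all(w == 0):
        raise ValueError("degenerate composite: zero variance")
    return float(sw * construct_sd**2 / (construct_sd * np.sqrt(var)))


def _validity(scores: np.ndarray, battery: MeasurementBattery) -> float | None:
    if battery.construct is None:
        return None
    return float(np.corrcoef(scores, battery.construct)[0, 1])


def unit_weighted_composite(battery: MeasurementBattery) -> CompositeResult:
    """Row mean of the measurements — the plain unit-weighted composite."""
    k = battery.k
    weights = np.full(k, 1.0 / k)
    scores = battery.measurements.mean(axis=1)
    return CompositeResult(scores, weights, "unit", _validity(scores, battery))


def median_composite(battery: MeasurementBattery) -> CompositeResult:
    """Row median — better than any single measurement, worse than the mean."""
    scores = np.median(battery.measurements, axis=1)
    weights = np.full(battery.k, 1.0 / battery.k)  # nominal; median is not linear
    return CompositeResult(scores, weights, "median", _validity(scores, battery))


def principal_axis_loadings(
    corr: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> np.ndarray:
    """One-factor principal-axis loadings with iterated communalities.

    Replaces the correlation-matrix diagonal with communality estimates and
    iterates the leading-eigenvector extraction until they stabilise.
    """
    k = corr.shape[0]
    r = corr.copy()
    # initial communalities: squared multiple correlations
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular measurement correlation matrix") from err
    h2 = np.clip(h2, 0.0, 1.0)
    loadings = np.zeros(k)
    for _ in range(max_iter):
        np.fill_diagonal(r, h2)
        eigval, eigvec = np.linalg.eigh(r)
        lead = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
        if lead.sum() < 0:
            lead = -lead
        new_h2 = np.clip(lead**2, 0.0, 1.0)
        done = np.max(np.abs(new_h2 - h2)) < tol
        h2, loadings = new_h2, lead
        if done:
            return loadings
    raise RuntimeError("principal-axis factor fit did not converge")


def regression_weighted_composite(battery: MeasurementBattery) -> CompositeResult:
    """Composite weighted by one-factor loadings (regression method).

    Fits a principal-axis single factor to the measurement correlation matrix
    (the latent construct is never used), then scores subjects with the
    regression (Thurstone) weights R^{-1} lambda applied to standardized
    measurements.  With unequal error SDs these weights approach the optimal
    inverse-error-variance weighting; with equal error SDs they reduce to the
    unit-weighted composite up to sampling noise.
    """
    if battery.k < 2:
        raise ValueError("regression weighting needs k >= 2 measurements")
    x = battery.measurements
    corr = np.corrcoef(x, rowvar=False)
    if np.linalg.matrix_rank(corr) < battery.k or not np.all(np.isfinite(corr)):
        raise ValueError("singular measurement covariance: collinear columns")

    loadings = principal_axis_loadings(corr)
    w_std = np.linalg.solve(corr, loadings)  # weights on standardized columns
    col_sd = x.std(axis=0, ddof=1)
    weights = w_std / col_sd
    if weights.sum() < 0:
        weights = -weights
    # rescale so the composite sits on the construct's score scale
    weights = weights / weights.sum()
    scores = x @ weights
    return CompositeResult(scores, weights, "regression", _validity(scores, battery))
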