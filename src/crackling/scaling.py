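"""Crackling-noise scaling relation: <S> ~ D^beta.

At criticality the mean avalanche size at a given duration grows as a power
of the duration, with exponent beta tied to the size exponent tau and the
duration exponent alpha by beta = (alpha - 1) / (tau - 1).  The fitted beta
is the slope of an ordinary least-squares regression of log10(<S>) on
log10(D) over the durations inside the duration fit's truncation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .avalanches import AvalancheSet
from .exceptions import InsufficientDataError, ParameterError
from .powerlaw import PowerLawFit

__all__ = ["ScalingResult", "mean_size_by_duration", "fit_beta", "predicted_beta", "scaling_analysis"]


@dataclass
class ScalingResult:
    durations: np.ndarray
    mean_sizes: np.ndarray
    beta_fitted: float
    beta_predicted: float
    fit_range: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "beta_fitted": float(self.beta_fitted),
            "beta_predicted": float(self.beta_predicted),
            "fit_range": [int(self.fit_range[0]), int(self.fit_range[1])],
            "n_durations": int(self.durations.size),
        }


def mean_size_by_duration(avalanches: AvalancheSet) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean avalanche size at each distinct duration, sorted."""
    if len(avalanches) == 0:
        raise InsufficientDataError("empty avalanche set")
    durations = avalanches.durations
    sizes = avalanches.sizes
    uniq = np.unique(durations)
    means = np.array([sizes[durations == d].mean() for d in uniq])
    return uniq, means


def fit_beta(durations, mean_sizes, fit_range: tuple[int, int] | None = None) -> float:
    """OLS slope of log10(mean size) on log10(duration).

    The regression is on the per-duration means (one point per duration,
    unweighted), optionally restricted to durations within ``fit_range``
    (inclusive).  Requires at least 3 distinct durations.
    """
    durations = np.asarray(durations, dtype=float)
    mean_sizes = np.asarray(mean_sizes, dtype=float)
    if fit_range is not None:
        mask = (durations >= fit_range[0]) & (durations <= fit_range[1])
        durations, mean_sizes = durations[mask], mean_sizes[mask]
    if np.unique(durations).size < 3:
        raise InsufficientDataError("need >= 3 distinct durations in the fit range")
    slope, _ = np.polyfit(np.log10(durations), np.log10(mean_sizes), 1)
    return float(slope)


def predicted_beta(tau: float, alpha: float) -> float:
    """Scaling-relation prediction beta = (alpha - 1) / (tau - 1)."""
    if tau <= 1:
        raise ParameterError("tau must exceed 1 for the prediction to be defined")
    return (alpha - 1.0) / (tau - 1.0)


def scaling_analysis(
    avalanches: AvalancheSet,
    size_fit: PowerLawFit,
    duration_fit: PowerLawFit,
) -> ScalingResult:
    """Fitted vs predicted beta for one condition.

    The regression range is the duration fit's truncation window
    ``[s_min, s_max]``, linking the scaling fit to the power-law body.
    """
    durations, means = mean_size_by_duration(avalanches)
    fit_range = (duration_fit.s_min, duration_fit.s_max)
    beta_f = fit_beta(durations, means, fit_range)
    beta_p = predicted_beta(size_fit.exponent, duration_fit.exponent)
    return ScalingResult(durations, means, beta_f, beta_p, fit_range)
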