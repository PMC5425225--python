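"""From fluorescence traces to binary spike rasters.

Stages mirror a standard calcium-imaging workflow: sliding-baseline dF/F
normalization (baseline = mean of the lower 50% of the previous 10 s of
samples), non-negative sparse deconvolution against an exponential-decay
kernel (0.8 s default) to obtain a per-neuron max-normalized spike
probability, thresholding at 3 SDs above zero pooled over the whole
population, and dropping neurons on an explicit exclusion list.

The deconvolution here is a deliberately simple L1-regularized non-negative
least-squares solve (FISTA); rasters obtained by other means can bypass this
stage entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .containers import CalciumTraces, SpikeRaster, default_neuron_ids
from .exceptions import BaselineError, DegenerateInputError, ParameterError

__all__ = [
    "DffTraces",
    "SpikeProbability",
    "compute_dff",
    "dff_traces",
    "infer_spike_probability",
    "threshold_spikes",
    "exclude_neurons",
]


@dataclass
class DffTraces:
    """dF/F-normalized traces, frames x neurons."""

    values: np.ndarray
    frame_rate: float
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.neuron_ids:
            self.neuron_ids = default_neuron_ids(self.values.shape[1])


@dataclass
class SpikeProbability:
    """Deconvolved, per-neuron max-normalized drive in [0, 1], frames x neurons."""

    values: np.ndarray
    frame_rate: float
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.neuron_ids:
            self.neuron_ids = default_neuron_ids(self.values.shape[1])


def compute_dff(
    trace: np.ndarray,
    frame_rate: float,
    window: float = 10.0,
    lower_fraction: float = 0.5,
) -> np.ndarray:
    """Sliding-baseline dF/F of one raw fluorescence series.

    For frame ``t`` the baseline is the mean of the lowest ``lower_fraction``
    of the ``window``-seconds of samples ending at ``t`` (inclusive); output
    is ``(f - b) / b``.  Start-up frames without a full trailing window reuse
    the first complete window's baseline, keeping output aligned with input.
    The result is invariant under scaling the raw trace by any c > 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ParameterError("compute_dff expects a 1-D series")
    w = max(2, int(round(window * frame_rate)))
    if trace.size <= w:
        raise ParameterError(f"trace length {trace.size} must exceed window of {w} frames")
    n_low = max(1, int(np.floor(w * lower_fraction)))

    windows = np.lib.stride_tricks.sliding_window_view(trace, w)
    lowest = np.sort(windows, axis=1)[:, :n_low]
    baselines = lowest.mean(axis=1)  # baseline for frames w-1 .. T-1
    full = np.empty_like(trace)
    full[w - 1:] = baselines
    full[: w - 1] = baselines[0]
    if (full <= 0).any():
        raise BaselineError("non-positive baseline; input must be raw nonnegative fluorescence")
    return (trace - full) / full


def dff_traces(
    traces: CalciumTraces,
    window: float = 10.0,
    lower_fraction: float = 0.5,
) -> DffTraces:
    """Apply :func:`compute_dff` to every neuron of a trace matrix."""
    out = np.column_stack(
        [
            compute_dff(traces.values[:, j], traces.frame_rate, window, lower_fraction)
            for j in range(traces.n_neurons)
        ]
    )
    return DffTraces(out, traces.frame_rate, list(traces.neuron_ids))


def _fista_nonneg_l1(
    y: np.ndarray, gamma: float, lam: float, max_iter: int, tol: float
) -> np.ndarray:
    """Minimize ||y - K s||^2 + lam * sum(s) over s >= 0.

    K is the causal exponential kernel (column j = gamma^(t-j) for t >= j);
    products with K and K^T are first-order recursive filters, so the
    proximal-gradient (FISTA) iterations cost O(T x neurons) each.
    """

    def K(v):
        return lfilter([1.0], [1.0, -gamma], v, axis=0)

    def Kt(v):
        return lfilter([1.0], [1.0, -gamma], v[::-1], axis=0)[::-1]

    lip = 2.0 / (1.0 - gamma) ** 2  # bound on ||2 K^T K||
    step = 1.0 / lip
    s = np.zeros_like(y)
    z = s.copy()
    t_mom = 1.0
    prev_obj = np.inf
    for it in range(max_iter):
        grad = 2.0 * Kt(K(z) - y)
        s_new = np.maximum(z - step * (grad + lam), 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        z = s_new + ((t_mom - 1.0) / t_new) * (s_new - s)
        s, t_mom = s_new, t_new
        if it % 25 == 24:
            resid = K(s) - y
            obj = float((resid**2).sum() + lam * s.sum())
            if abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
                break
            prev_obj = obj
    return s


def infer_spike_probability(
    dff: DffTraces,
    decay_constant: float = 0.8,
    lam: float | None = None,
    max_iter: int = 600,
    tol: float = 1e-9,
) -> SpikeProbability:
    """Sparse non-negative deconvolution of dF/F into spike probability.

    Solves, per neuron, ``min_{s >= 0} ||y - K s||^2 + lam ||s||_1`` with the
    causal exponential kernel of the given ``decay_constant``; ``lam``
    defaults to 0.1 x the pooled dF/F SD.  The solution is max-normalized per
    neuron (silent neurons stay all-zero).
    """
    if decay_constant <= 0:
        raise ParameterError("decay_constant must be positive")
    y = np.asarray(dff.values, dtype=float)
    if not np.isfinite(y).all():
        raise ParameterError("dF/F must be finite")
    gamma = float(np.exp(-1.0 / (dff.frame_rate * decay_constant)))
    if lam is None:
        lam = 0.1 * float(y.std())
    s = _fista_nonneg_l1(y, gamma, lam, max_iter, tol)
    peaks = s.max(axis=0)
    norm = np.where(peaks > 0, peaks, 1.0)
    return SpikeProbability(s / norm, dff.frame_rate, list(dff.neuron_ids))


def threshold_spikes(prob: SpikeProbability, k_sd: float = 3.0) -> SpikeRaster:
    """Binarize spike probabilities at ``k_sd`` SDs above zero.

    The threshold is ``k_sd`` times the population-pooled root-mean-square of
    all entries (deviation measured about zero, as the probabilities are
    nonnegative with a zero floor); entries strictly above become 1.
    Scaling all probabilities by c > 0 leaves the output unchanged.
    """
    v = np.asarray(prob.values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty probability matrix")
    rms = float(np.sqrt(np.mean(v**2)))
    if rms == 0:
        raise DegenerateInputError("pooled SD is zero; no events inferable")
    binary = (v > k_sd * rms).astype(np.uint8)
    return SpikeRaster(binary.T, 1.0 / prob.frame_rate, list(prob.neuron_ids))


def exclude_neurons(obj, exclusion_list):
    """Drop the named neurons from a raster / trace / probability object.

    Order of the remaining neurons is preserved; an unknown label raises
    ``KeyError``.  Returns an object of the same type.
    """
    labels = list(exclusion_list)
    known = set(obj.neuron_ids)
    for lab in labels:
        if lab not in known:
            raise KeyError(f"unknown neuron label {lab!r}")
    keep = [i for i, lab in enumerate(obj.neuron_ids) if lab not in set(labels)]
    kept_ids = [obj.neuron_ids[i] for i in keep]
    if isinstance(obj, SpikeRaster):
        return SpikeRaster(obj.values[keep, :], obj.bin_width, kept_ids)
    if isinstance(obj, CalciumTraces):
        return CalciumTraces(
            obj.values[:, keep], obj.frame_rate, obj.decay_constant,
            obj.amplitude, obj.noise_sd, kept_ids,
        )
    if isinstance(obj, DffTraces):
        return DffTraces(obj.values[:, keep], obj.frame_rate, kept_ids)
    if isinstance(obj, SpikeProbability):
        return SpikeProbability(obj.values[:, keep], obj.frame_rate, kept_ids)
    raise ParameterError(f"cannot exclude neurons from {type(obj).__name__}")
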