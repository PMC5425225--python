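"""Core in-memory containers shared across the pipeline.

The central object is :class:`SpikeRaster`, a binary neurons x time-bins
matrix.  :class:`CalciumTraces` holds the fluorescence forward-model output
(frames x neurons, i.e. transposed relative to the raster, matching how
imaging software exports time series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = ["SpikeRaster", "CalciumTraces", "default_neuron_ids"]


def default_neuron_ids(n: int) -> list[str]:
    """Zero-padded neuron labels ``n000 .. n{N-1}``."""
    width = max(3, len(str(max(n - 1, 0))))
    return [f"n{i:0{width}d}" for i in range(n)]


@dataclass
class SpikeRaster:
    """Binary spike raster.

    Parameters
    ----------
    values
        ``(n_neurons, n_bins)`` array of 0/1 entries.
    bin_width
        Temporal resolution of one column, in seconds.
    neuron_ids
        One label per row; generated if omitted.
    """

    values: np.ndarray
    bin_width: float
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ParameterError("raster must be 2-D (neurons x bins)")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ParameterError("raster entries must be binary")
        self.values = self.values.astype(np.uint8)
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if not self.neuron_ids:
            self.neuron_ids = default_neuron_ids(self.values.shape[0])
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ParameterError("neuron_ids length must match rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total recording length in seconds."""
        return self.n_bins * self.bin_width

    @property
    def spike_counts(self) -> np.ndarray:
        """Per-neuron spike counts (row sums)."""
        return self.values.sum(axis=1)

    @property
    def times(self) -> np.ndarray:
        """Bin start times in seconds."""
        return np.arange(self.n_bins) * self.bin_width


@dataclass
class CalciumTraces:
    """Fluorescence traces, one column per neuron.

    ``values`` are raw fluorescence in arbitrary units (baseline + transients);
    ``amplitude`` and ``noise_sd`` record the forward-model parameters in
    dF/F units per spike.
    """

    values: np.ndarray
    frame_rate: float
    decay_constant: float = 0.8
    amplitude: float = 0.1
    noise_sd: float = 0.0
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("traces must be 2-D (frames x neurons)")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.decay_constant <= 0:
            raise ParameterError("decay_constant must be positive")
        if not self.neuron_ids:
            self.neuron_ids = default_neuron_ids(self.values.shape[1])
        if len(self.neuron_ids) != self.values.shape[1]:
            raise ParameterError("neuron_ids length must match columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate
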