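"""Network activity and neuronal-avalanche segmentation.

Network activity is the number of neurons spiking per time bin (250 ms by
default).  An avalanche is a maximal run of consecutive bins with activity
strictly above the threshold — the median of the activity series — quantified
by its size S (summed activity over the run) and duration D (run length in
bins).  Runs touching the first or last bin have no observed threshold
crossing and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpikeRaster
from .exceptions import BinningError, ParameterError

__all__ = ["NetworkActivity", "Avalanche", "AvalancheSet", "network_activity", "extract_avalanches"]


@dataclass
class NetworkActivity:
    """Per-bin population spike-count series with its median threshold."""

    counts: np.ndarray
    bin_width: float
    threshold: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class Avalanche:
    """One supra-threshold excursion (bins are inclusive indices)."""

    start_bin: int
    end_bin: int
    size: int
    duration: int  # bins


@dataclass
class AvalancheSet:
    """Ordered, disjoint avalanches from one activity series."""

    avalanches: list[Avalanche]
    bin_width: float
    threshold: float

    def __len__(self) -> int:
        return len(self.avalanches)

    def __iter__(self):
        return iter(self.avalanches)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([a.size for a in self.avalanches], dtype=int)

    @property
    def durations(self) -> np.ndarray:
        """Durations in bins (seconds = durations * bin_width)."""
        return np.array([a.duration for a in self.avalanches], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_bin": [a.start_bin for a in self.avalanches],
                "end_bin": [a.end_bin for a in self.avalanches],
                "size": [a.size for a in self.avalanches],
                "duration_bins": [a.duration for a in self.avalanches],
                "duration_s": [a.duration * self.bin_width for a in self.avalanches],
            }
        )


def network_activity(
    raster: SpikeRaster,
    bin_width: float = 0.25,
    rule: str = "any",
) -> NetworkActivity:
    """Bin a raster into population activity counts.

    ``rule="any"`` (default) counts a neuron once per bin if it has at least
    one spike frame inside the bin; ``rule="sum"`` sums its spike frames
    instead (exactly spike-conserving).  ``bin_width`` must be an integer
    multiple of the raster resolution (1% tolerance); bin membership of a
    frame follows half-open intervals [t, t + bin_width).  The threshold is
    set to the median of the counts.
    """
    if rule not in ("any", "sum"):
        raise ParameterError(f"unknown counting rule {rule!r}")
    ratio = bin_width / raster.bin_width
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 0.01 * m:
        raise BinningError(
            f"bin_width {bin_width} is not an integer multiple of raster resolution {raster.bin_width}"
        )
    n_coarse = -(-raster.n_bins // m)  # ceil; trailing partial bin kept
    padded = np.zeros((raster.n_neurons, n_coarse * m), dtype=raster.values.dtype)
    padded[:, : raster.n_bins] = raster.values
    grouped = padded.reshape(raster.n_neurons, n_coarse, m)
    if rule == "any":
        per_neuron = grouped.max(axis=2)
    else:
        per_neuron = grouped.sum(axis=2)
    counts = per_neuron.sum(axis=0).astype(int)
    return NetworkActivity(counts, bin_width, float(np.median(counts)))


def extract_avalanches(
    activity: NetworkActivity,
    threshold: float | None = None,
    integration: str = "raw",
) -> AvalancheSet:
    """Segment supra-threshold excursions of the network activity.

    Bins with ``counts > threshold`` (strict) belong to avalanches; maximal
    runs form one avalanche each, with size = summed counts over the run
    (``integration="raw"``) or summed threshold-subtracted excess
    (``integration="excess"``) and duration = run length.  Runs touching the
    first or last bin are discarded.  An activity series that never crosses
    the threshold yields an empty set.
    """
    if integration not in ("raw", "excess"):
        raise ParameterError(f"unknown integration rule {integration!r}")
    thr = activity.threshold if threshold is None else float(threshold)
    counts = np.asarray(activity.counts)
    above = counts > thr
    avalanches: list[Avalanche] = []
    if above.any():
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1)  # inclusive end indices
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [counts.size - 1]))
        for s, e in zip(starts, ends):
            if s == 0 or e == counts.size - 1:
                continue  # no observed crossing at the recording edge
            run = counts[s : e + 1]
            size = run.sum() if integration == "raw" else (run - thr).sum()
            avalanches.append(Avalanche(int(s), int(e), int(round(size)), int(e - s + 1)))
    return AvalancheSet(avalanches, activity.bin_width, thr)
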