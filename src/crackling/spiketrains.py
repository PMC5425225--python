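"""Per-neuron interspike-interval statistics.

The coefficient of variation of the interspike intervals,
CV = SD(ISI) / mean(ISI), measures spiking irregularity: 1 for a Poisson
process, 0 for a clock, above 1 for bursty trains.  A population-mean CV
above 1 together with a right-skewed firing-rate distribution is the
single-neuron signature of near-critical network dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpikeRaster

__all__ = ["SpikeTrainStats", "compute_isi_stats"]


@dataclass
class SpikeTrainStats:
    """Per-neuron table plus population summaries.

    ``per_neuron`` columns: neuron_id, n_spikes, n_isis, isi_mean (s),
    isi_sd (s), cv, rate (Hz).  CV entries are NaN for neurons below the
    ``min_isis`` cut; those neurons still contribute a firing rate.
    """

    per_neuron: pd.DataFrame
    mean_cv: float
    sem_cv: float
    rate_skewness: float
    bin_width: float
    min_isis: int

    @property
    def cvs(self) -> np.ndarray:
        """CVs of the eligible neurons."""
        return self.per_neuron["cv"].dropna().to_numpy()

    def to_dict(self) -> dict:
        return {
            "mean_cv": float(self.mean_cv),
            "sem_cv": float(self.sem_cv),
            "rate_skewness": float(self.rate_skewness),
            "n_neurons": int(len(self.per_neuron)),
            "n_cv_eligible": int(self.per_neuron["cv"].notna().sum()),
            "bin_width": float(self.bin_width),
            "min_isis": int(self.min_isis),
        }


def compute_isi_stats(raster: SpikeRaster, min_isis: int = 10) -> SpikeTrainStats:
    """ISI statistics at native raster resolution.

    ISIs are differences of consecutive spike-bin times in seconds.  Neurons
    with fewer than ``min_isis`` intervals are excluded from the CV summary
    (their CV is NaN) but keep their firing rate.  Population summaries are
    the mean CV with its SEM across eligible neurons and the sample skewness
    of the firing-rate distribution.
    """
    rows = []
    total_time = raster.duration
    for i, label in enumerate(raster.neuron_ids):
        spike_bins = np.flatnonzero(raster.values[i])
        n_spikes = spike_bins.size
        isis = np.diff(spike_bins) * raster.bin_width
        if isis.size >= min_isis:
            isi_mean = float(isis.mean())
            isi_sd = float(isis.std(ddof=1))
            cv = isi_sd / isi_mean
        else:
            isi_mean = isi_sd = cv = np.nan
        rows.append(
            {
                "neuron_id": label,
                "n_spikes": int(n_spikes),
                "n_isis": int(isis.size),
                "isi_mean": isi_mean,
                "isi_sd": isi_sd,
                "cv": cv,
                "rate": n_spikes / total_time,
            }
        )
    table = pd.DataFrame(rows)
    cvs = table["cv"].dropna().to_numpy()
    if cvs.size == 0:
        warnings.warn("no neurons reached the minimum ISI count; CV summary is empty")
        mean_cv = sem_cv = np.nan
    else:
        mean_cv = float(cvs.mean())
        sem_cv = float(cvs.std(ddof=1) / np.sqrt(cvs.size)) if cvs.size > 1 else np.nan
    rates = table["rate"].to_numpy()
    rate_skew = float(stats.skew(rates)) if rates.size > 2 and rates.std() > 0 else np.nan
    return SpikeTrainStats(table, mean_cv, sem_cv, rate_skew, raster.bin_width, min_isis)
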