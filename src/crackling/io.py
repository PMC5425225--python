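"""Delimited-text readers and writers.

Rasters and traces travel as TSV: first column ``time_s``, one column per
neuron with the neuron label as header.  Avalanche sets are CSV tables,
reports and configs are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .avalanches import Avalanche, AvalancheSet
from .containers import CalciumTraces, SpikeRaster
from .exceptions import ParameterError

__all__ = [
    "write_raster_tsv",
    "read_raster_tsv",
    "write_traces_tsv",
    "read_traces_tsv",
    "write_avalanches_csv",
    "read_avalanches_csv",
    "write_json",
    "read_json",
]


def _matrix_frame(times: np.ndarray, values: np.ndarray, neuron_ids) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=list(neuron_ids))
    df.insert(0, "time_s", times)
    return df


def write_raster_tsv(raster: SpikeRaster, path) -> None:
    df = _matrix_frame(raster.times, raster.values.T, raster.neuron_ids)
    df.to_csv(path, sep="\t", index=False)


def read_raster_tsv(path) -> SpikeRaster:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_s":
        raise ParameterError("first TSV column must be time_s")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ParameterError("need at least two time points to infer bin width")
    bin_width = float(np.median(np.diff(times)))
    values = df.drop(columns="time_s").to_numpy().T
    return SpikeRaster(values, bin_width, list(df.columns[1:]))


def write_traces_tsv(traces: CalciumTraces, path) -> None:
    df = _matrix_frame(traces.times, traces.values, traces.neuron_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_traces_tsv(path, decay_constant: float = 0.8) -> CalciumTraces:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_s":
        raise ParameterError("first TSV column must be time_s")
    times = df["time_s"].to_numpy(dtype=float)
    frame_rate = 1.0 / float(np.median(np.diff(times)))
    return CalciumTraces(
        values=df.drop(columns="time_s").to_numpy(),
        frame_rate=frame_rate,
        decay_constant=decay_constant,
        neuron_ids=list(df.columns[1:]),
    )


def write_avalanches_csv(avalanches: AvalancheSet, path) -> None:
    avalanches.to_dataframe().to_csv(path, index=False)


def read_avalanches_csv(path, bin_width: float | None = None, threshold: float = np.nan) -> AvalancheSet:
    df = pd.read_csv(path)
    if bin_width is None:
        if len(df) == 0:
            raise ParameterError("cannot infer bin width from an empty table")
        bin_width = float((df["duration_s"] / df["duration_bins"]).iloc[0])
    avs = [
        Avalanche(int(r.start_bin), int(r.end_bin), int(r.size), int(r.duration_bins))
        for r in df.itertuples()
    ]
    return AvalancheSet(avs, bin_width, threshold)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(data), indent=2) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
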