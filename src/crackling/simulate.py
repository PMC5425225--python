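"""Branching-network simulator and calcium-imaging forward model.

The generator stands in for two-photon recordings of ~100 layer-2/3 neurons:
a quenched random directed graph (fixed out-degree) on which activity spreads
as a probabilistic branching process.  An active neuron transmits to each of
its ``connectivity_degree`` targets independently with probability
``p = sigma / connectivity_degree``, so ``sigma`` is the expected number of
directly triggered descendants — the branching parameter.  ``sigma = 1`` is
the critical regime; below/above it activity decays/explodes.  External
drive activates each neuron independently per bin with probability
``drive_rate`` (scalar, or a per-bin time course emulating a stimulus).

Spike rasters can be rendered into synthetic fluorescence traces with an
exponential-decay calcium kernel (OGB-1-like, 0.8 s decay, ~4.07 Hz frames)
plus white Gaussian dF/F noise, and spike-time shuffling provides the
rate-preserving control used to destroy avalanche structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .containers import CalciumTraces, SpikeRaster, default_neuron_ids
from .exceptions import InvalidProbabilityError, ParameterError

__all__ = [
    "NetworkConfig",
    "simulate_branching_network",
    "spikes_to_calcium",
    "shuffle_spike_times",
    "drive_profile",
    "CONDITIONS",
]

#: the three emulated stimulus conditions (drive time-course shapes)
CONDITIONS = ("ongoing", "grating", "movie")


@dataclass
class NetworkConfig:
    """Parameters of one branching-network simulation.

    Defaults emulate one recording condition: 100 neurons, ~13 minutes at
    50 ms resolution, near-critical recurrence with sparse external drive.
    """

    n_neurons: int = 100
    branching_parameter: float = 1.0
    drive_rate: float | np.ndarray = 0.001
    connectivity_degree: int = 10
    n_bins: int = 15_600
    bin_width: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_bins < 1:
            raise ParameterError("n_neurons and n_bins must be positive")
        if self.branching_parameter < 0:
            raise ParameterError("branching parameter must be non-negative")
        if not 0 < self.connectivity_degree < self.n_neurons:
            raise ParameterError("need 0 < connectivity_degree < n_neurons")
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        drive = np.asarray(self.drive_rate, dtype=float)
        if drive.ndim not in (0, 1):
            raise ParameterError("drive_rate must be scalar or per-bin vector")
        if drive.ndim == 1 and drive.size != self.n_bins:
            raise ParameterError("per-bin drive_rate must have length n_bins")
        if (drive < 0).any() or (drive > 1).any():
            raise ParameterError("drive_rate must lie in [0, 1]")
        p = self.branching_parameter / self.connectivity_degree
        if p > 1:
            raise InvalidProbabilityError(
                f"per-edge probability sigma/degree = {p:.3f} exceeds 1"
            )

    @property
    def transmission_probability(self) -> float:
        return self.branching_parameter / self.connectivity_degree

    def to_dict(self) -> dict:
        drive = np.asarray(self.drive_rate, dtype=float)
        return {
            "n_neurons": self.n_neurons,
            "branching_parameter": self.branching_parameter,
            "drive_rate": drive.tolist() if drive.ndim else float(drive),
            "connectivity_degree": self.connectivity_degree,
            "n_bins": self.n_bins,
            "bin_width": self.bin_width,
            "seed": self.seed,
        }


def _quenched_adjacency(n: int, degree: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed random graph: each neuron projects to ``degree`` distinct others."""
    adj = np.zeros((n, n), dtype=np.float32)
    others = np.arange(n)
    for i in range(n):
        pool = others[others != i]
        adj[i, rng.choice(pool, size=degree, replace=False)] = 1.0
    return adj


def simulate_branching_network(
    config: NetworkConfig,
    initial_active: np.ndarray | None = None,
) -> SpikeRaster:
    """Run the branching network and return its binary spike raster.

    Neuron ``j`` is active in bin ``t+1`` with probability
    ``1 - (1 - p)^k_j * (1 - drive_t)`` where ``k_j`` is its number of active
    presynaptic partners in bin ``t``.  Bin 0 is seeded by ``initial_active``
    if given, otherwise by the external drive alone.  Identical configs
    (including seed) give bit-identical rasters.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_neurons, config.n_bins
    adj = _quenched_adjacency(n, config.connectivity_degree, rng)
    log_miss = np.log1p(-config.transmission_probability) if config.transmission_probability < 1 else -np.inf

    drive = np.broadcast_to(np.asarray(config.drive_rate, dtype=float), (T,))
    raster = np.zeros((n, T), dtype=np.uint8)

    if initial_active is not None:
        initial_active = np.asarray(initial_active)
        if initial_active.shape != (n,):
            raise ParameterError("initial_active must have shape (n_neurons,)")
        state = initial_active.astype(bool)
    else:
        state = rng.random(n) < drive[0]
    raster[:, 0] = state

    for t in range(1, T):
        if state.any():
            k = state.astype(np.float32) @ adj
            p_syn = -np.expm1(k * log_miss)  # 1 - (1-p)^k
        else:
            p_syn = 0.0
        p_total = 1.0 - (1.0 - p_syn) * (1.0 - drive[t])
        state = rng.random(n) < p_total
        raster[:, t] = state
    return SpikeRaster(raster, config.bin_width, default_neuron_ids(n))


def drive_profile(
    condition: str,
    n_bins: int,
    bin_width: float,
    base_rate: float = 0.001,
    modulation: float = 0.75,
    period: float = 10.0,
    timescale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-bin external drive emulating one stimulus condition.

    ``ongoing``
        dark screen: constant ``base_rate``.
    ``grating``
        5 s stimulus / 5 s gray alternation (``period`` = 10 s): square-wave
        drive between ``base_rate * (1 +/- modulation)``.
    ``movie``
        naturalistic fluctuations: log-normal AR(1) envelope with the given
        correlation ``timescale`` (seconds) and unit mean, multiplying
        ``base_rate``.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}")
    t = np.arange(n_bins) * bin_width
    if condition == "ongoing":
        rate = np.full(n_bins, base_rate)
    elif condition == "grating":
        on = (t % period) < (period / 2)
        rate = base_rate * np.where(on, 1 + modulation, 1 - modulation)
    else:  # movie
        rng = np.random.default_rng(seed)
        rho = np.exp(-bin_width / timescale)
        innov = rng.standard_normal(n_bins) * np.sqrt(1 - rho**2)
        x = lfilter([1.0], [1.0, -rho], innov)
        sd = 0.5
        rate = base_rate * np.exp(sd * x - sd**2 / 2)
    return np.clip(rate, 0.0, 1.0)


def spikes_to_calcium(
    raster: SpikeRaster,
    frame_rate: float = 4.07,
    decay_constant: float = 0.8,
    amplitude: float = 0.1,
    noise_sd: float = 0.02,
    baseline: float = 1.0,
    seed: int = 0,
) -> CalciumTraces:
    """Render a spike raster into synthetic fluorescence traces.

    Per neuron the fluorescence follows
    ``f(t) = f(t - dt) * exp(-dt / decay_constant) + amplitude * spikes(t)``
    sampled at ``frame_rate`` (dt = 1/frame_rate), plus white Gaussian noise
    of SD ``noise_sd`` and a constant ``baseline`` (so the output is raw
    nonnegative-mean fluorescence suitable for dF/F extraction; amplitude and
    noise are expressed in dF/F units relative to that baseline).
    """
    if frame_rate <= 0 or decay_constant <= 0:
        raise ParameterError("frame_rate and decay_constant must be positive")
    if raster.n_bins == 0 or raster.n_neurons == 0:
        raise ParameterError("raster must be nonempty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    # half-open frame membership: bin at time t belongs to frame floor(t/dt);
    # epsilon guards against bin edges landing a float ulp below a frame edge
    frame_of_bin = np.floor(
        np.arange(raster.n_bins) * raster.bin_width * frame_rate + 1e-9
    ).astype(int)
    n_frames = int(frame_of_bin[-1]) + 1
    spikes = np.zeros((n_frames, raster.n_neurons))
    np.add.at(spikes, frame_of_bin, raster.values.T.astype(float))

    gamma = np.exp(-dt / decay_constant)
    transients = lfilter([amplitude], [1.0, -gamma], spikes, axis=0)
    noise = rng.normal(0.0, noise_sd, size=transients.shape) if noise_sd > 0 else 0.0
    values = baseline + transients + noise
    return CalciumTraces(
        values=values,
        frame_rate=frame_rate,
        decay_constant=decay_constant,
        amplitude=amplitude,
        noise_sd=noise_sd,
        neuron_ids=list(raster.neuron_ids),
    )


def shuffle_spike_times(raster: SpikeRaster, seed: int = 0) -> SpikeRaster:
    """Relocate each neuron's spikes to uniformly random distinct bins.

    Per-neuron spike counts are exactly preserved; all temporal structure
    (and hence large avalanches) is destroyed.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.zeros_like(raster.values)
    for i in range(raster.n_neurons):
        m = int(raster.values[i].sum())
        if m:
            shuffled[i, rng.choice(raster.n_bins, size=m, replace=False)] = 1
    return SpikeRaster(shuffled, raster.bin_width, list(raster.neuron_ids))
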