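"""End-to-end orchestration: simulate/load -> preprocess -> avalanches ->
power-law fits -> scaling -> ISI statistics -> correlations, per condition,
plus cross-condition exponent comparison.

All randomness is funnelled through named sub-seeds derived from the master
seed and the stage name, so identical configs give bit-identical reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from . import io as cio
from .avalanches import AvalancheSet, extract_avalanches, network_activity
from .containers import SpikeRaster
from .correlations import (
    CorrelationMatrix,
    correlation_significance,
    pairwise_correlation,
)
from .exceptions import CracklingError, InsufficientDataError, PairingError
from .powerlaw import PowerLawFit, bootstrap_exponent_sd, fit_truncated_power_law, goodness_of_fit_test
from .preprocess import dff_traces, exclude_neurons, infer_spike_probability, threshold_spikes
from .scaling import ScalingResult, scaling_analysis
from .simulate import NetworkConfig, drive_profile, shuffle_spike_times, simulate_branching_network
from .spiketrains import SpikeTrainStats, compute_isi_stats

__all__ = ["RunConfig", "ConditionReport", "run_pipeline", "compare_exponents", "stage_seed"]


def stage_seed(master_seed: int, *labels: str) -> int:
    """Deterministic sub-seed (< 2^31) from the master seed and stage labels."""
    h = hashlib.blake2b("/".join(labels).encode(), digest_size=4).digest()
    return (int(master_seed) * 0x9E3779B1 + int.from_bytes(h, "little")) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``conditions`` maps a condition label to its input: either
    ``{"simulate": {...NetworkConfig fields..., "drive": "<condition name>"}}``
    or ``{"raster": "<tsv path>"}`` or ``{"traces": "<tsv path>"}``.
    Stage parameters default to the analysis conventions: 250 ms bins,
    3-SD spike threshold, 0.8 s decay, 1000 surrogates and bootstraps,
    significance 0.05 (power law) / 0.1 (correlations).
    """

    conditions: dict = field(default_factory=dict)
    out_dir: str | None = None
    master_seed: int = 0
    subject: str = "sim"
    bin_width: float = 0.25
    k_sd: float = 3.0
    decay_constant: float = 0.8
    dff_window: float = 10.0
    n_surrogates: int = 1000
    n_bootstrap: int = 1000
    gof_alpha: float = 0.05
    corr_p_threshold: float = 0.1
    min_isis: int = 10
    exclude: dict = field(default_factory=dict)  # condition -> list of labels
    shuffle_control: bool = False
    reference_condition: str | None = None
    unpaired_ttest: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**cio.read_json(path))

    def to_json(self, path) -> None:
        cio.write_json(self.__dict__, path)


@dataclass
class ConditionReport:
    """Per-condition results; ``skipped`` lists stages that failed and why."""

    condition: str
    raster: SpikeRaster | None = None
    avalanches: AvalancheSet | None = None
    size_fit: PowerLawFit | None = None
    duration_fit: PowerLawFit | None = None
    scaling: ScalingResult | None = None
    isi_stats: SpikeTrainStats | None = None
    correlations: CorrelationMatrix | None = None
    shuffle_size_fit: PowerLawFit | None = None
    skipped: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"condition": self.condition, "skipped": self.skipped}
        if self.raster is not None:
            out["n_neurons"] = self.raster.n_neurons
            out["n_bins"] = self.raster.n_bins
        if self.avalanches is not None:
            out["n_avalanches"] = len(self.avalanches)
            out["activity_threshold"] = self.avalanches.threshold
        if self.size_fit is not None:
            out["size_fit"] = self.size_fit.to_dict()
        if self.duration_fit is not None:
            out["duration_fit"] = self.duration_fit.to_dict()
        if self.scaling is not None:
            out["scaling"] = self.scaling.to_dict()
        if self.isi_stats is not None:
            out["isi_stats"] = self.isi_stats.to_dict()
        if self.correlations is not None:
            off = self.correlations.offdiagonal()
            sig = self.correlations.significant
            out["correlations"] = {
                "mean_offdiagonal": float(off.mean()) if off.size else None,
                "fraction_significant": None
                if sig is None
                else float(sig[np.triu_indices(sig.shape[0], 1)].mean()),
            }
        if self.shuffle_size_fit is not None:
            out["shuffle_size_fit"] = self.shuffle_size_fit.to_dict()
        return out


def _load_raster(cond: str, spec: dict, config: RunConfig) -> SpikeRaster:
    if "raster" in spec:
        return cio.read_raster_tsv(spec["raster"])
    if "traces" in spec:
        traces = cio.read_traces_tsv(spec["traces"], decay_constant=config.decay_constant)
    elif "simulate" in spec:
        params = dict(spec["simulate"])
        drive_kind = params.pop("drive", None)
        params.setdefault("seed", stage_seed(config.master_seed, "simulate", cond))
        if drive_kind is not None:
            probe = NetworkConfig(**params)
            params["drive_rate"] = drive_profile(
                drive_kind,
                probe.n_bins,
                probe.bin_width,
                base_rate=float(np.asarray(probe.drive_rate).mean()),
                seed=stage_seed(config.master_seed, "drive", cond),
            )
        return simulate_branching_network(NetworkConfig(**params))
    else:
        raise CracklingError(f"condition {cond!r} has no input (raster/traces/simulate)")
    if config.exclude.get(cond):
        traces = exclude_neurons(traces, config.exclude[cond])
    dff = dff_traces(traces, window=config.dff_window)
    prob = infer_spike_probability(dff, decay_constant=config.decay_constant)
    return threshold_spikes(prob, k_sd=config.k_sd)


def _fit_with_tests(samples, config: RunConfig, cond: str, what: str) -> PowerLawFit:
    fit = fit_truncated_power_law(samples)
    fit.gof_p = goodness_of_fit_test(
        samples, fit, n_surrogates=config.n_surrogates,
        seed=stage_seed(config.master_seed, "gof", cond, what),
    )
    if fit.converged:
        try:
            boot = bootstrap_exponent_sd(
                samples, n_boot=config.n_bootstrap,
                seed=stage_seed(config.master_seed, "bootstrap", cond, what),
            )
            fit.exponent_sd = boot.exponent_sd
        except CracklingError:
            pass
    return fit


def run_pipeline(config: RunConfig) -> dict[str, ConditionReport]:
    """Execute every stage for every condition; failures are recorded per
    stage and remaining conditions continue."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, ConditionReport] = {}
    for cond, spec in config.conditions.items():
        rep = ConditionReport(condition=cond)
        reports[cond] = rep
        try:
            raster = _load_raster(cond, spec, config)
            if "raster" in spec and config.exclude.get(cond):
                raster = exclude_neurons(raster, config.exclude[cond])
            rep.raster = raster
        except Exception as exc:  # input failure: nothing downstream can run
            rep.skipped["input"] = f"{type(exc).__name__}: {exc}"
            continue

        def _stage(name, fn):
            try:
                return fn()
            except Exception as exc:
                rep.skipped[name] = f"{type(exc).__name__}: {exc}"
                return None

        activity = _stage("network_activity", lambda: network_activity(raster, config.bin_width))
        if activity is not None:
            rep.avalanches = _stage("avalanches", lambda: extract_avalanches(activity))
        if rep.avalanches is not None and len(rep.avalanches) >= 30:
            rep.size_fit = _stage(
                "size_fit", lambda: _fit_with_tests(rep.avalanches.sizes, config, cond, "size")
            )
            rep.duration_fit = _stage(
                "duration_fit",
                lambda: _fit_with_tests(rep.avalanches.durations, config, cond, "duration"),
            )
        elif rep.avalanches is not None:
            rep.skipped["size_fit"] = "fewer than 30 avalanches"
        if rep.size_fit is not None and rep.duration_fit is not None:
            rep.scaling = _stage(
                "scaling", lambda: scaling_analysis(rep.avalanches, rep.size_fit, rep.duration_fit)
            )
        rep.isi_stats = _stage("isi_stats", lambda: compute_isi_stats(raster, config.min_isis))

        def _corr():
            matrix = pairwise_correlation(raster, condition=cond)
            correlation_significance(
                matrix, raster, n_surrogates=config.n_surrogates,
                p_threshold=config.corr_p_threshold,
                seed=stage_seed(config.master_seed, "corr", cond),
            )
            return matrix

        rep.correlations = _stage("correlations", _corr)

        if config.shuffle_control:

            def _shuffle():
                shuffled = shuffle_spike_times(
                    raster, seed=stage_seed(config.master_seed, "shuffle", cond)
                )
                s_act = network_activity(shuffled, config.bin_width)
                s_av = extract_avalanches(s_act)  # median recomputed on shuffled data
                if len(s_av) < 30:
                    raise InsufficientDataError("fewer than 30 shuffled avalanches")
                fit = fit_truncated_power_law(s_av.sizes)
                fit.gof_p = goodness_of_fit_test(
                    s_av.sizes, fit, n_surrogates=config.n_surrogates,
                    seed=stage_seed(config.master_seed, "gof", cond, "shuffle"),
                )
                return fit

            rep.shuffle_size_fit = _stage("shuffle_control", _shuffle)

        if out_dir:
            base = out_dir / f"{config.subject}_{cond}"
            if rep.raster is not None:
                cio.write_raster_tsv(rep.raster, base.with_name(base.name + "_raster.tsv"))
            if rep.avalanches is not None:
                cio.write_avalanches_csv(rep.avalanches, base.with_name(base.name + "_avalanches.csv"))
            cio.write_json(rep.to_dict(), base.with_name(base.name + "_report.json"))

    if out_dir:
        cio.write_json(
            {c: r.to_dict() for c, r in reports.items()}, out_dir / f"{config.subject}_summary.json"
        )
    return reports


def compare_exponents(
    exponents: dict,
    condition_a: str,
    condition_b: str,
    paired: bool = True,
) -> tuple[float, float]:
    """t-test on per-subject exponents between two conditions.

    ``exponents`` maps condition -> {subject: exponent}.  The default is a
    two-sided paired t-test on the per-subject differences (per-subject
    values are linked across conditions); ``paired=False`` uses Welch's
    unpaired test.  Returns ``(t, p)``.
    """
    try:
        a_map, b_map = exponents[condition_a], exponents[condition_b]
    except KeyError as exc:
        raise PairingError(f"condition {exc} missing from exponent mapping") from exc
    if paired:
        subjects = sorted(set(a_map) & set(b_map))
        if len(subjects) < 3:
            raise PairingError(f"need >= 3 paired subjects, got {len(subjects)}")
        if set(a_map) != set(b_map):
            missing = set(a_map) ^ set(b_map)
            raise PairingError(f"unpaired subjects: {sorted(missing)}")
        d = np.array([a_map[s] - b_map[s] for s in subjects], dtype=float)
        sd = d.std(ddof=1)
        if sd == 0:  # degenerate: identical differences
            if d.mean() == 0:
                return 0.0, 1.0
            return float(np.sign(d.mean()) * np.inf), 0.0
        t, p = sps.ttest_1samp(d, 0.0)
        return float(t), float(p)
    a = np.array(list(a_map.values()), dtype=float)
    b = np.array(list(b_map.values()), dtype=float)
    if a.size < 3 or b.size < 3:
        raise PairingError("need >= 3 subjects per condition")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
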