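# Methods

This note records the models, conventions, and numerical choices behind
`crackling`, and what the synthetic-data tests do and do not establish.

## Branching-network simulator

The generator is a probabilistic branching process on a quenched random
directed graph: each of `n_neurons` projects to `connectivity_degree`
distinct targets (drawn once per seed), and an active neuron transmits to
each target independently with probability `p = sigma / connectivity_degree`.
Neuron *j* is therefore active in bin *t+1* with probability
`1 − (1 − p)^k_j · (1 − drive_t)`, where `k_j` is its number of active
presynaptic partners in bin *t*. `sigma` is the branching parameter — the
expected number of direct descendants of one active neuron — and
`sigma = 1` is the critical regime. Defaults (100 neurons, out-degree 10,
drive 0.001 per neuron per bin, 50 ms bins, ~13 min) emulate the scale of a
two-photon population recording; the three stimulus conditions are drive
time courses sharing the same recurrent dynamics: constant (dark screen /
ongoing), a 5 s on / 5 s off square wave (drifting gratings), and a
log-normal AR(1) envelope with 1 s correlation time and unit mean
(naturalistic movie).

The calcium forward model renders spikes into fluorescence with a causal
exponential kernel (decay 0.8 s, the standard value for OGB-1 transients),
sampled at 4.07 Hz, with amplitude 0.1 ΔF/F per spike over a unit baseline
and white Gaussian ΔF/F noise (0.02 default). This emulates indicator decay
and shot-like noise only: no neuropil contamination, motion, drift,
nonlinear indicator saturation, or cell-to-cell kernel variability. Passing
the end-to-end recovery tests therefore validates the thresholding and
deconvolution *logic*, not robustness to every artifact of real imaging.

What the simulator is not: a biophysical model. It has no conductances,
cell types, inhibition, or refractoriness. It is the canonical minimal
generator of the sub/critical/supercritical regimes with analytically known
critical exponents, which is exactly what the downstream statistics need
for validation. No simulator parameter is tuned to match any particular
recorded dataset.

## Preprocessing

- **ΔF/F**: per frame, baseline = mean of the lowest 50% of the samples in
  the trailing 10 s window (window and fraction configurable); output
  `(f − b)/b`. Start-up frames reuse the first complete window's baseline
  so output stays aligned with input. A non-positive baseline raises — the
  input must be raw fluorescence, not an already-normalized signal.
- **Spike inference**: sparse non-negative deconvolution,
  `min_{s≥0} ‖y − Ks‖² + λ‖s‖₁` with the exponential kernel, solved by
  FISTA (products with K are first-order recursive filters, so iterations
  are O(T)). `λ = 0.1 ×` pooled ΔF/F SD by default. This is a deliberately
  simple stand-in for heavier inference machinery; rasters obtained by any
  other route can bypass it. Output is max-normalized per neuron.
- **Thresholding**: "3 SDs above 0" is implemented as 3 × the pooled
  root-mean-square of all entries (deviation about zero, since the
  probabilities are nonnegative with a zero floor), pooled across the whole
  population *after* per-neuron normalization. Both the multiplier and the
  pooling stage are configurable; entries strictly above become 1.
- **Exclusion**: visual-inspection neuron rejection is replaced by an
  explicit label list, applied identically before or after binarization.

## Avalanche definition

Network activity is the number of neurons with ≥1 spike frame per bin
(250 ms by default, matching imaging practice; a "sum frames" rule is
available and is exactly spike-conserving). The threshold is the median of
the activity; supra-threshold means strictly greater, so with integer
counts and a half-integer median there is no ambiguity and ties at an
integer median fall below. An avalanche is a maximal supra-threshold run:
size = summed activity over the run (raw integration; threshold-subtracted
"excess" is an option), duration = run length. Runs touching either end of
the recording have no observed crossing and are discarded.

For branching-simulator output the package's own analyses use the
simulator's native 50 ms resolution: at 250 ms the median threshold on
these rasters is positive, which floors sizes at `D·(thr+1)` and distorts
the small-size body of the distribution; at native resolution the median is
zero and the classical avalanche segmentation applies. The 250 ms default
remains for imaging-style data, whose frame rate imposes it.

## Truncated power-law inference

The discrete pmf `f(S) = S^(−a) / Σ_{S_min}^{S_max} S^(−a)` is used
throughout (sizes and durations are integers; durations in bins). The MLE
is a bounded 1-D minimization of the negative log-likelihood on
`a ∈ (1.01, 5]` to 1e−6; a dense grid search is the test oracle. The KS
statistic is the sup distance between empirical and model CDFs on the
support.

Window selection: `S_max` starts at the sample maximum; for
`S_min ∈ {1, 2, 3}` the fit with smallest KS wins (ties to smaller
`S_min`); if `KS < 1/√N_av` the fit is accepted, else `S_max` decreases by
one. The square-root criterion is the one consistent with the scale of KS
fluctuations: for a sample of n points the KS of even a perfect fit is
O(1/√n), so a 1/N_av rule (offered as `criterion="1/n"`) can only be met by
collapsing the support and is useful mainly as an aggressive tail pruner.
Exhausting the support returns a fit flagged `converged=False` carrying the
best window, so batch runs continue; such a fit fails the surrogate test,
which is the correct verdict for data with no power-law body.

Surrogates are drawn from the exact discrete inverse-CDF table of the
fitted pmf (matched exponent, `S_min`, `S_max`, and sample size), with the
continuous inverse formula `S_min(1 − r)^(−1/(a−1))` floored to integers —
and, for `S_min = 1`, a Zipf-envelope acceptance-rejection scheme — kept as
a compatibility option; truncation is redraw-until-accepted, which
preserves the sample size and the renormalized shape. Surrogate KS values
are computed against the fitted model itself (no refitting), so the test is
conservative for fitted data: `p` = fraction of surrogate KS ≥ data KS,
reject when `p < 0.05`. The mirrored fraction is available via
`alternative="smaller"`. Bootstrap exponent uncertainty refits the full
window-selection loop on resamples with replacement; failed refits are
skipped and counted, and more than 50% failures raises.

## Scaling relation

`⟨S⟩` is averaged per distinct duration; `β` is the unweighted OLS slope of
log10⟨S⟩ on log10 D, restricted to durations inside the duration fit's
truncation window (linking the regression to the power-law body, since
durations outside it were excluded from exponent estimation). The predicted
value is `(α − 1)/(τ − 1)` from the same condition's size and duration
exponents.

## Spike-train and correlation statistics

ISIs are computed at native raster resolution (irregularity is a
single-neuron property; coarse binning would alias it); CV = SD/mean of the
ISIs, neurons need ≥10 ISIs (configurable) to enter the CV summary but
always report a rate. The population summary is mean CV ± SEM and the
sample skewness of the rate distribution.

Correlations are zero-lag Pearson coefficients of the binary trains at
native resolution. Significance is two-sided against independent Bernoulli
surrogate trains matched to each pair's mean rates and the recording
length, `p < 0.1`, uncorrected for multiple comparisons (an exploratory
convention; expect ~10% flags under independence by construction). The
surrogate coefficients are sampled through their sufficient statistics —
train sums are Binomial and the overlap count given the sums is
Hypergeometric — which is distributionally identical to simulating the
trains and orders of magnitude faster. Constant trains give flagged
undefined entries, never silent zeros. Clustering is complete-linkage on
distance `1 − r` (anticorrelated pairs are distant); neurons with undefined
pairings are dropped greedily (most-undefined first) and appended after the
leaf order. Other conditions are re-displayed under the reference
condition's leaf order, with absent neurons blank.

## Reproducibility and problem sizes

Every stochastic stage takes a seed; the pipeline derives per-stage seeds
from the master seed and the stage name (BLAKE2-based, < 2³¹). The test
suite and the acceptance script use, as their standard problem sizes:
200 datasets × 2000 samples with 500 surrogates for GOF calibration;
50,000-bin simulations (100 neurons) for the criticality signatures;
40 trials × 10⁴ samples with 200 bootstrap resamples for exponent-recovery
coverage; 10 seeds × 30,000 bins for the shuffle control. These sizes give
the quoted checks comfortable statistical resolution (e.g. SD of the
bootstrap SD ≈ 5% at 200 resamples).

## Known limitations

- The deconvolution stand-in has a single global λ and kernel; it is not a
  replacement for dedicated spike-inference tools on real data.
- The GOF test inherits the conservatism of comparing fitted data against
  un-refitted surrogates; its null rejection rate is well below nominal.
- KS-based truncation is insensitive to sparse contamination beyond the
  fitted body (a few stragglers in thousands of samples are absorbed or
  only partially pruned); the strict `1/n` criterion prunes aggressively at
  the cost of never certifying convergence on realistic samples.
- Exponents from median-thresholded avalanches depend on bin width, firing
  rate, and subsampling; cross-dataset comparisons should hold these fixed.
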