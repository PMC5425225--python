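"""Pairwise correlation structure and its stimulus-dependent reorganization.

Zero-lag Pearson correlations of the binarized spike trains (at native frame
resolution), per-pair significance against rate-matched independent
surrogates (p < 0.1, two-sided, uncorrected), complete-linkage hierarchical
clustering of one condition's matrix, and re-display of other conditions
under that reference neuron ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .containers import SpikeRaster
from .exceptions import ParameterError

__all__ = [
    "CorrelationMatrix",
    "pairwise_correlation",
    "correlation_significance",
    "cluster_order",
    "reorder_by_reference",
]


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson matrix with bookkeeping.

    ``defined`` flags entries computable at all (False where either train is
    constant, or where a neuron is absent after reordering); ``significant``
    is filled by :func:`correlation_significance`.
    """

    values: np.ndarray
    neuron_ids: list[str]
    condition: str = ""
    defined: np.ndarray | None = None
    significant: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.defined is None:
            self.defined = np.isfinite(self.values)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """Off-diagonal defined coefficients as a flat array."""
        iu = np.triu_indices(self.n_neurons, k=1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]


def pairwise_correlation(raster: SpikeRaster, condition: str = "") -> CorrelationMatrix:
    """Zero-lag Pearson correlations of the binary trains.

    Constant trains give undefined (NaN) rows/columns, flagged in
    ``defined`` rather than silently zeroed; their diagonal is NaN too.
    """
    if raster.n_neurons < 2 or raster.n_bins < 2:
        raise ParameterError("need >= 2 neurons and >= 2 bins")
    x = raster.values.astype(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    constant = sd == 0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    return CorrelationMatrix(r, list(raster.neuron_ids), condition)


def _surrogate_correlations(
    T: int, n1: int, n2: int, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Null Pearson coefficients for independent Bernoulli trains.

    Equivalent to drawing two independent Bernoulli trains of length ``T``
    at rates ``n1/T`` and ``n2/T`` and correlating them, but sampled through
    the sufficient statistics: train sums are Binomial, and the overlap
    count given the sums is Hypergeometric (spike positions are uniform).
    """
    m1 = rng.binomial(T, n1 / T, size=n_surrogates)
    m2 = rng.binomial(T, n2 / T, size=n_surrogates)
    ok = (m1 > 0) & (m1 < T) & (m2 > 0) & (m2 < T)
    while not ok.all():  # degenerate constant surrogates: redraw
        bad = ~ok
        m1[bad] = rng.binomial(T, n1 / T, size=bad.sum())
        m2[bad] = rng.binomial(T, n2 / T, size=bad.sum())
        ok = (m1 > 0) & (m1 < T) & (m2 > 0) & (m2 < T)
    n11 = rng.hypergeometric(m1, T - m1, m2)
    num = T * n11 - m1 * m2
    den = np.sqrt(m1 * (T - m1.astype(float)) * m2 * (T - m2))
    return num / den


def correlation_significance(
    matrix: CorrelationMatrix,
    raster: SpikeRaster,
    n_surrogates: int = 1000,
    p_threshold: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided per-pair significance against rate-matched surrogates.

    For each pair, ``n_surrogates`` null coefficients from independent
    Bernoulli trains matched to the two neurons' mean rates and the
    recording length give a two-sided p-value
    ``p = mean(|r_null| >= |r_obs|)``; the pair is significant when
    ``p < p_threshold``.  Pairs involving a silent or saturated neuron, or
    an undefined coefficient, are untestable and flagged False with NaN p.
    The ``significant`` and ``p_values`` fields of ``matrix`` are filled in
    place; the boolean matrix is also returned.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_neurons
    counts = raster.spike_counts
    T = raster.n_bins
    sig = np.zeros((n, n), dtype=bool)
    pvals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r_obs = matrix.values[i, j]
            if not np.isfinite(r_obs) or counts[i] in (0, T) or counts[j] in (0, T):
                continue
            null = _surrogate_correlations(T, int(counts[i]), int(counts[j]), n_surrogates, rng)
            p = float(np.mean(np.abs(null) >= abs(r_obs)))
            pvals[i, j] = pvals[j, i] = p
            sig[i, j] = sig[j, i] = p < p_threshold
    matrix.significant = sig
    matrix.p_values = pvals
    return sig


def cluster_order(matrix: CorrelationMatrix) -> np.ndarray:
    """Dendrogram leaf order from complete-linkage clustering on 1 - r.

    Neurons with any undefined coefficient are left out of the clustering
    and appended last in their original order.  Deterministic given input.
    Returns a permutation of row indices.
    """
    # greedily drop the neuron with the most undefined pairings until the
    # remaining submatrix is fully defined (one constant train NaNs a whole
    # row *and* column, so a plain row filter would discard everyone)
    keep = list(range(matrix.n_neurons))
    while keep:
        sub = matrix.values[np.ix_(keep, keep)]
        nan_counts = (~np.isfinite(sub)).sum(axis=1)
        if nan_counts.max() == 0:
            break
        keep.pop(int(np.argmax(nan_counts)))
    clusterable = np.array(keep, dtype=int)
    rest = np.array(sorted(set(range(matrix.n_neurons)) - set(keep)), dtype=int)
    if clusterable.size < 2:
        return np.arange(matrix.n_neurons)
    sub = matrix.values[np.ix_(clusterable, clusterable)]
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    order = clusterable[leaves_list(z)]
    return np.concatenate([order, rest])


def reorder_by_reference(
    matrix: CorrelationMatrix, reference_order: list[str]
) -> CorrelationMatrix:
    """Permute a matrix to a reference neuron ordering.

    ``reference_order`` is a sequence of neuron labels (e.g. the clustered
    order of the reference condition).  Neurons absent from this condition
    are rendered as blank (NaN, flagged undefined) rows/columns, so matrices
    from different conditions stay visually comparable.
    """
    ref = list(reference_order)
    pos = {lab: k for k, lab in enumerate(matrix.neuron_ids)}
    m = len(ref)
    out = np.full((m, m), np.nan)
    present = [k for k, lab in enumerate(ref) if lab in pos]
    src = [pos[ref[k]] for k in present]
    out[np.ix_(present, present)] = matrix.values[np.ix_(src, src)]
    return CorrelationMatrix(out, ref, matrix.condition)
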