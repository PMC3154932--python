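"""Fidelity statistics for time series and Markov networks.

Time-series measures (autocorrelation, periodogram, value distribution,
spectral slope), network measures (strengths, arc weights, inverted-weight
shortest paths, modularity with a value-shuffle null) and the
first-vs-second-generation comparators used by the round-trip experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from scipy.sparse.csgraph import dijkstra

from .generators import ToyParams, shuffle_series, toy_series
from .inverse import inverse_map
from .mapping import MarkovNetwork, forward_map

__all__ = [
    "SeriesStats",
    "NetworkStats",
    "NullSummary",
    "GenerationDistances",
    "acf",
    "periodogram",
    "spectral_slope",
    "strengths",
    "shortest_path_distribution",
    "modularity",
    "detect_communities",
    "modularity_shuffle_null",
    "series_stats",
    "network_stats",
    "compare_generations",
    "roundtrip_ensemble",
    "curves_within_band",
]


def _weights(W: Union[MarkovNetwork, np.ndarray]) -> np.ndarray:
    if isinstance(W, MarkovNetwork):
        return W.weights
    return np.asarray(W, dtype=float)


# ---------------------------------------------------------------------------
# time-series measures


def acf(series: Sequence[float], maxlag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags ``0..maxlag``.

    Mean-removed autocovariance at each lag divided by the lag-0
    autocovariance; ``acf[0] == 1``.  Raises for a constant series.
    """
    x = np.asarray(series, dtype=float)
    L = x.size
    if not 0 <= maxlag < L:
        raise ValueError("maxlag must satisfy 0 <= maxlag < L")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has no autocorrelation")
    # biased estimator via FFT: divide by L at every lag, then normalize
    nfft = int(2 ** np.ceil(np.log2(2 * L - 1)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: maxlag + 1]
    return acov / var


def periodogram(series: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed series.

    Returns ``(freqs, power)`` at the positive Fourier frequencies
    ``k / L`` for ``k = 1 .. L // 2``, normalized so that the total power
    equals the (biased) sample variance (Parseval).
    """
    x = np.asarray(series, dtype=float)
    L = x.size
    if L < 4:
        raise ValueError("need at least 4 points")
    x = x - x.mean()
    X = np.fft.rfft(x)
    k = np.arange(1, L // 2 + 1)
    power = np.abs(X[1 : L // 2 + 1]) ** 2 / L**2
    power *= 2.0
    if L % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin appears once in the full spectrum
    return k / L, power


def spectral_slope(
    freqs: np.ndarray, power: np.ndarray, band: Optional[tuple[float, float]] = None
) -> float:
    """Least-squares slope of log-power versus log-frequency over a band."""
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(power, dtype=float)
    if band is not None:
        lo, hi = band
        sel = (f >= lo) & (f <= hi)
        f, p = f[sel], p[sel]
    keep = p > 0
    f, p = f[keep], p[keep]
    if f.size < 10:
        raise ValueError("fewer than 10 positive-power frequencies in band")
    slope, _ = np.polyfit(np.log(f), np.log(p), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# network measures


def strengths(W: Union[MarkovNetwork, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-node in-strength (column sums) and out-strength (row sums)."""
    M = _weights(W)
    return M.sum(axis=0), M.sum(axis=1)


def shortest_path_distribution(
    W: Union[MarkovNetwork, np.ndarray]
) -> tuple[np.ndarray, int]:
    """All-pairs directed shortest paths with arc length ``1 / weight``.

    Returns the multiset of finite path lengths over ordered node pairs
    (diagonal excluded) and the count of unreachable pairs.
    """
    M = _weights(W)
    if np.any(M < 0):
        raise ValueError("weights must be non-negative")
    N = M.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(M > 0, 1.0 / np.where(M > 0, M, 1.0), 0.0)
    D = dijkstra(lengths, directed=True)
    off = ~np.eye(N, dtype=bool)
    vals = D[off]
    finite = vals[np.isfinite(vals)]
    return np.sort(finite), int(np.sum(~np.isfinite(vals)))


def _as_labels(partition, N: int) -> np.ndarray:
    """Accept a label array or an iterable of node collections."""
    arr = np.asarray(partition)
    if arr.ndim == 1 and arr.size == N and np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    labels = np.full(N, -1, dtype=np.int64)
    for c, members in enumerate(partition):
        for v in members:
            labels[int(v)] = c
    if np.any(labels < 0):
        raise ValueError("partition does not cover all nodes")
    return labels


def modularity(W: Union[MarkovNetwork, np.ndarray], partition) -> float:
    """Newman-Girvan modularity of a node partition.

    Computed on the symmetrized, total-weight-normalized matrix:
    ``sum_m (e_mm - a_m^2)`` where ``e_mm`` is the fraction of weight
    inside community ``m`` and ``a_m`` its total incident fraction.
    """
    M = _weights(W)
    N = M.shape[0]
    labels = _as_labels(partition, N)
    communities = np.unique(labels)
    if any(np.sum(labels == c) == 0 for c in communities):  # pragma: no cover
        raise ValueError("empty community")
    S = (M + M.T) / 2.0
    total = S.sum()
    if total == 0:
        raise ValueError("network has no weight")
    q = 0.0
    for c in communities:
        idx = labels == c
        e_mm = S[np.ix_(idx, idx)].sum() / total
        a_m = S[idx].sum() / total
        q += e_mm - a_m**2
    return float(q)


def detect_communities(W: Union[MarkovNetwork, np.ndarray], seed: int = 0) -> np.ndarray:
    """Greedy agglomerative modularity maximization (deterministic).

    Runs on the symmetrized weight matrix and returns a community label
    per node.  The ``seed`` is accepted for interface stability; the
    algorithm itself is deterministic.
    """
    import networkx as nx

    M = _weights(W)
    S = (M + M.T) / 2.0
    G = nx.from_numpy_array(S)
    communities = nx.community.greedy_modularity_communities(G, weight="weight")
    labels = np.empty(M.shape[0], dtype=np.int64)
    for c, members in enumerate(communities):
        for v in members:
            labels[v] = c
    return labels


@dataclass(frozen=True)
class NullSummary:
    """Observed statistic against a shuffle-null distribution."""

    observed: float
    null_mean: float
    null_se: float
    n_replicates: int

    @property
    def z(self) -> float:
        return (self.observed - self.null_mean) / self.null_se if self.null_se > 0 else np.inf


def modularity_shuffle_null(
    series: Sequence[float], Q: int, R: int = 10, seed: int = 0
) -> NullSummary:
    """Modularity of the forward-mapped series against a value-shuffle null.

    The null destroys temporal order while preserving the value
    distribution: each replicate shuffles the series, forward-maps it,
    detects communities and records the modularity.
    """
    if R < 2:
        raise ValueError("need at least 2 null replicates")
    x = np.asarray(series, dtype=float)
    net = forward_map(x, Q, dangling_policy="selfloop")
    observed = modularity(net, detect_communities(net, seed))
    null_vals = np.empty(R)
    for r in range(R):
        shuffled = shuffle_series(x, seed=seed + 1 + r)
        net_r = forward_map(shuffled, Q, dangling_policy="selfloop")
        null_vals[r] = modularity(net_r, detect_communities(net_r, seed))
    return NullSummary(
        observed=observed,
        null_mean=float(null_vals.mean()),
        null_se=float(null_vals.std(ddof=1) / np.sqrt(R)),
        n_replicates=R,
    )


# ---------------------------------------------------------------------------
# generation comparison


@dataclass
class SeriesStats:
    """Summary statistics of one time series."""

    acf: np.ndarray
    spectrum_freqs: np.ndarray
    spectrum_power: np.ndarray
    hist_edges: np.ndarray
    hist_density: np.ndarray
    values: Optional[np.ndarray] = None


@dataclass
class NetworkStats:
    """Summary statistics of one weighted directed network."""

    in_strengths: np.ndarray
    out_strengths: np.ndarray
    arc_weights: np.ndarray
    path_lengths: np.ndarray
    n_unreachable: int
    modularity: Optional[float] = None


def series_stats(
    series: Sequence[float],
    maxlag: int = 100,
    bins: int = 20,
    value_range: Optional[tuple[float, float]] = None,
    keep_values: bool = True,
) -> SeriesStats:
    x = np.asarray(series, dtype=float)
    freqs, power = periodogram(x)
    density, edges = np.histogram(x, bins=bins, range=value_range, density=True)
    return SeriesStats(
        acf=acf(x, maxlag),
        spectrum_freqs=freqs,
        spectrum_power=power,
        hist_edges=edges,
        hist_density=density,
        values=x if keep_values else None,
    )


def network_stats(
    W: Union[MarkovNetwork, np.ndarray], with_modularity: bool = False, seed: int = 0
) -> NetworkStats:
    M = _weights(W)
    ins, outs = strengths(M)
    paths, unreachable = shortest_path_distribution(M)
    mod = modularity(M, detect_communities(M, seed)) if with_modularity else None
    return NetworkStats(
        in_strengths=ins,
        out_strengths=outs,
        arc_weights=np.sort(M[M > 0]),
        path_lengths=paths,
        n_unreachable=unreachable,
        modularity=mod,
    )


def _log_binned_log_spectrum(
    freqs: np.ndarray, power: np.ndarray, n_bins: int = 30
) -> np.ndarray:
    """Mean log-power in logarithmically spaced frequency bins."""
    edges = np.geomspace(freqs[0], freqs[-1] * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    out = np.full(n_bins, np.nan)
    logp = np.log(np.maximum(power, 1e-300))
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            out[b] = logp[sel].mean()
    return out


def _hist_l1(a: np.ndarray, b: np.ndarray) -> float:
    """L1 distance between two empirical distributions.

    Computed as the area between the CDFs (1-Wasserstein distance), which
    is the binning-free limit of an L1 histogram distance and robust to
    lattice effects in count-derived samples.
    """
    if a.size == 0 and b.size == 0:
        return 0.0
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare an empty distribution")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0
    return float(sps.wasserstein_distance(a, b))


@dataclass(frozen=True)
class GenerationDistances:
    """Distances between two sets of generation statistics."""

    acf_max_abs: float
    spectrum_log_l1: float
    value_ks: float
    in_strength_l1: float
    arc_weight_l1: float
    path_length_l1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acf_max_abs": self.acf_max_abs,
            "spectrum_log_l1": self.spectrum_log_l1,
            "value_ks": self.value_ks,
            "in_strength_l1": self.in_strength_l1,
            "arc_weight_l1": self.arc_weight_l1,
            "path_length_l1": self.path_length_l1,
        }


def compare_generations(
    s1: SeriesStats,
    s2: SeriesStats,
    n1: Optional[NetworkStats] = None,
    n2: Optional[NetworkStats] = None,
) -> GenerationDistances:
    """Distance report between first- and second-generation statistics.

    Raises if the lag or frequency grids do not match.
    """
    if s1.acf.size != s2.acf.size:
        raise ValueError("ACF lag grids do not match")
    if s1.spectrum_freqs.size != s2.spectrum_freqs.size:
        raise ValueError("frequency grids do not match")
    acf_d = float(np.max(np.abs(s1.acf - s2.acf)))
    ls1 = _log_binned_log_spectrum(s1.spectrum_freqs, s1.spectrum_power)
    ls2 = _log_binned_log_spectrum(s2.spectrum_freqs, s2.spectrum_power)
    ok = np.isfinite(ls1) & np.isfinite(ls2)
    spec_d = float(np.abs(ls1[ok] - ls2[ok]).mean())
    if s1.values is not None and s2.values is not None:
        ks = float(sps.ks_2samp(s1.values, s2.values).statistic)
    else:
        c1 = np.cumsum(s1.hist_density * np.diff(s1.hist_edges))
        c2 = np.cumsum(s2.hist_density * np.diff(s2.hist_edges))
        ks = float(np.max(np.abs(c1 - c2)))
    if n1 is not None and n2 is not None:
        in_d = _hist_l1(n1.in_strengths, n2.in_strengths)
        w_d = _hist_l1(n1.arc_weights, n2.arc_weights)
        p_d = _hist_l1(n1.path_lengths, n2.path_lengths)
    else:
        in_d = w_d = p_d = 0.0
    return GenerationDistances(acf_d, spec_d, ks, in_d, w_d, p_d)


def curves_within_band(
    curves1: np.ndarray, curves2: np.ndarray, n_sigma: float = 3.0, atol: float = 0.0
) -> bool:
    """Pointwise mean-curve agreement within ``n_sigma`` pooled std-devs.

    ``curves*`` are (n_realizations, n_points) arrays.  At each point the
    two ensemble means must differ by less than
    ``n_sigma * sqrt(s1^2 + s2^2) + atol`` where ``s*`` are the
    across-realization standard deviations.
    """
    c1 = np.asarray(curves1, dtype=float)
    c2 = np.asarray(curves2, dtype=float)
    m1, m2 = c1.mean(axis=0), c2.mean(axis=0)
    s1 = c1.std(axis=0, ddof=1)
    s2 = c2.std(axis=0, ddof=1)
    band = n_sigma * np.sqrt(s1**2 + s2**2) + atol
    return bool(np.all(np.abs(m1 - m2) <= band))


def resample_transition_rows(
    counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial-resample each row of a transition count matrix.

    Draws fresh counts per row at the observed row totals and
    renormalizes, producing a surrogate network that differs from the
    original only by the unavoidable Markov sampling noise — the null for
    round-trip network comparisons.
    """
    C = np.asarray(counts, dtype=np.int64)
    W = np.zeros(C.shape)
    for i in range(C.shape[0]):
        n = int(C[i].sum())
        if n > 0:
            W[i] = rng.multinomial(n, C[i] / n) / n
        else:
            W[i, i] = 1.0
    return W


def roundtrip_ensemble(
    p: float,
    n_realizations: int = 10,
    L: int = 10_000,
    Q: int = 50,
    k: Optional[float] = None,
    seed: int = 0,
    maxlag: int = 100,
) -> dict:
    """Run the two-generation round-trip protocol for one noise level.

    For each realization: draw a first-generation toy series, forward-map
    it, apply the inverse map with the known quantile correspondence to
    get the second-generation series, and forward-map that again reusing
    the first generation's bins.  ``k`` defaults to ``1/Q`` so the
    regular endpoint (``p=0``) maps to the Q-ring.

    Two reference draws support resampling bands: extra independent
    first-generation series (series-domain nulls) and multinomial row
    resamples of each first-generation network (network-domain nulls,
    which must include the second generation's extra sampling layer).
    """
    from .mapping import assign_quantiles, count_transitions, normalize_rows

    if k is None:
        k = 1.0 / Q
    gen1_s, gen2_s, extra_s = [], [], []
    gen1_n, gen2_n, extra_n, resamp_n = [], [], [], []
    for r in range(n_realizations):
        x1 = toy_series(ToyParams(k=k, p=p, L=L, seed=seed + 1000 * r))
        symbols, part = assign_quantiles(x1, Q)
        counts = count_transitions(symbols, Q)
        net1 = normalize_rows(counts, "selfloop", partition=part)
        x2, _ = inverse_map(
            net1, L, seed=seed + 1000 * r + 1, partition=part, reorder=False
        )
        net2 = forward_map(x2, Q, dangling_policy="selfloop", partition=part)
        x1b = toy_series(ToyParams(k=k, p=p, L=L, seed=seed + 1000 * r + 2))
        net1b = forward_map(x1b, Q, dangling_policy="selfloop")
        resampled = resample_transition_rows(
            counts, np.random.default_rng(seed + 1000 * r + 3)
        )
        gen1_s.append(series_stats(x1, maxlag=maxlag))
        gen2_s.append(series_stats(x2, maxlag=maxlag))
        extra_s.append(series_stats(x1b, maxlag=maxlag))
        gen1_n.append(network_stats(net1))
        gen2_n.append(network_stats(net2))
        extra_n.append(network_stats(net1b))
        resamp_n.append(network_stats(resampled))
    return {
        "gen1_series": gen1_s,
        "gen2_series": gen2_s,
        "extra_series": extra_s,
        "gen1_network": gen1_n,
        "gen2_network": gen2_n,
        "extra_network": extra_n,
        "resampled_network": resamp_n,
    }
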