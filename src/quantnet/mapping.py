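"""Forward map from a univariate time series to a weighted directed network.

The construction has a single parameter ``Q``: the series is discretized
into ``Q`` equal-occupancy quantile bins, each bin becomes a node, and the
arc ``i -> j`` carries the empirical first-order Markov transition
probability between consecutive time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "QuantilePartition",
    "MarkovNetwork",
    "assign_quantiles",
    "assign_with_partition",
    "count_transitions",
    "normalize_rows",
    "forward_map",
]

DanglingPolicy = Literal["error", "selfloop", "uniform"]


@dataclass(frozen=True)
class QuantilePartition:
    """Equal-occupancy partition of a series' value range into ``Q`` bins.

    Attributes
    ----------
    boundaries : ndarray, shape (Q + 1,)
        Non-decreasing bin edges spanning the data range.  ``boundaries[q]``
        is the smallest value in bin ``q``; ``boundaries[Q]`` is the overall
        maximum.
    occupancy : ndarray of int, shape (Q,)
        Number of points assigned to each bin; sums to the series length.
    """

    boundaries: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        occ = np.asarray(self.occupancy, dtype=np.int64)
        if b.ndim != 1 or occ.ndim != 1 or b.size != occ.size + 1:
            raise ValueError("boundaries must have one more entry than occupancy")
        if np.any(np.diff(b) < 0):
            raise ValueError("boundaries must be non-decreasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "occupancy", occ)

    @property
    def Q(self) -> int:
        return int(self.occupancy.size)

    @classmethod
    def uniform(cls, Q: int) -> "QuantilePartition":
        """The uniform partition of [0, 1) into ``Q`` equal bins."""
        if Q < 2:
            raise ValueError("Q must be >= 2")
        return cls(np.linspace(0.0, 1.0, Q + 1), np.zeros(Q, dtype=np.int64))


@dataclass
class MarkovNetwork:
    """A row-stochastic weighted directed graph on nodes ``0..Q-1``.

    ``weights[i, j]`` is the probability of moving from node ``i`` to node
    ``j``.  Rows of all-zero weight ("dangling" nodes) may survive only
    under an explicit dangling policy.
    """

    weights: np.ndarray
    partition: Optional[QuantilePartition] = None
    node_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0) or np.any(W > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = W
        if self.node_labels is None:
            self.node_labels = np.arange(W.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def is_row_stochastic(self, atol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.row_sums() - 1.0) < atol))


def _validate_series(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 2:
        raise ValueError("series must contain at least 2 points")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite value at index {bad}")
    return x


def assign_quantiles(series: Sequence[float], Q: int) -> tuple[np.ndarray, QuantilePartition]:
    """Discretize ``series`` into ``Q`` rank-based quantile symbols.

    Points are sorted by (value, time index); the sorted order is cut into
    ``Q`` consecutive blocks of near-equal size and block ``q`` becomes
    symbol ``q``.  When the length ``L`` is not divisible by ``Q``, the
    first ``L mod Q`` blocks take the extra point.  Rank-based assignment
    makes the symbol sequence invariant under any strictly increasing
    transform of the values and guarantees occupancies differ by at most 1.

    Returns
    -------
    symbols : ndarray of int, shape (L,)
        Symbol of each point, in original time order; values in ``[0, Q)``.
    partition : QuantilePartition
        Bin edges (block extremes) and occupancies.
    """
    x = _validate_series(series)
    Q = int(Q)
    if Q < 2:
        raise ValueError("Q must be >= 2")
    L = x.size
    if L < Q:
        raise ValueError("more quantiles than points")

    order = np.argsort(x, kind="stable")  # stable: ties broken by time index
    base, extra = divmod(L, Q)
    sizes = np.full(Q, base, dtype=np.int64)
    sizes[:extra] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])

    symbols = np.empty(L, dtype=np.int64)
    for q in range(Q):
        symbols[order[edges[q]:edges[q + 1]]] = q

    sorted_vals = x[order]
    boundaries = np.empty(Q + 1)
    boundaries[:Q] = sorted_vals[edges[:Q]]
    boundaries[Q] = sorted_vals[-1]
    return symbols, QuantilePartition(boundaries, sizes)


def assign_with_partition(
    series: Sequence[float], partition: QuantilePartition
) -> np.ndarray:
    """Bin a series with an existing partition's value boundaries.

    Used on round trips to reuse the original bins: a value in
    ``[boundaries[q], boundaries[q+1])`` gets symbol ``q``; values outside
    the spanned range are clipped into the end bins.
    """
    x = _validate_series(series)
    inner = partition.boundaries[1:-1]
    return np.searchsorted(inner, x, side="right").astype(np.int64)


def count_transitions(symbols: Sequence[int], Q: int) -> np.ndarray:
    """Count first-order transitions between consecutive symbols.

    ``counts[i, j]`` is the number of times symbol ``i`` is immediately
    followed by symbol ``j``; the total equals ``L - 1`` (no wrap-around).
    """
    s = np.asarray(symbols, dtype=np.int64)
    Q = int(Q)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("symbol sequence must contain at least 2 symbols")
    if np.any(s < 0) or np.any(s >= Q):
        raise ValueError(f"symbol out of range [0, {Q})")
    counts = np.zeros((Q, Q), dtype=np.int64)
    np.add.at(counts, (s[:-1], s[1:]), 1)
    return counts


def normalize_rows(
    counts: np.ndarray,
    dangling_policy: DanglingPolicy = "error",
    partition: Optional[QuantilePartition] = None,
) -> MarkovNetwork:
    """Row-normalize a non-negative count matrix into a Markov network.

    Zero rows are handled per ``dangling_policy``: ``"error"`` raises,
    ``"selfloop"`` places a unit self-loop, ``"uniform"`` spreads 1/Q over
    the row.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if np.any(C < 0):
        raise ValueError("counts must be non-negative")
    Q = C.shape[0]
    row_sums = C.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size and dangling_policy == "error":
        raise ValueError(f"dangling node(s) with no outgoing transitions: {zero_rows.tolist()}")

    W = np.zeros_like(C)
    nz = row_sums > 0
    W[nz] = C[nz] / row_sums[nz, None]
    if zero_rows.size:
        if dangling_policy == "selfloop":
            W[zero_rows, zero_rows] = 1.0
        elif dangling_policy == "uniform":
            W[zero_rows] = 1.0 / Q
        else:  # pragma: no cover - guarded above
            raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    return MarkovNetwork(W, partition=partition)


def forward_map(
    series: Sequence[float],
    Q: int,
    dangling_policy: DanglingPolicy = "error",
    partition: Optional[QuantilePartition] = None,
) -> MarkovNetwork:
    """Map a time series to its quantile-transition Markov network.

    Composition of :func:`assign_quantiles`, :func:`count_transitions` and
    :func:`normalize_rows`.  The returned network carries its
    :class:`QuantilePartition` so round trips can reuse the original bins:
    pass an existing ``partition`` to bin by its value boundaries instead
    of fresh rank quantiles.
    """
    if partition is not None:
        symbols = assign_with_partition(series, partition)
        Q = partition.Q
    else:
        symbols, partition = assign_quantiles(series, Q)
    counts = count_transitions(symbols, Q)
    return normalize_rows(counts, dangling_policy, partition=partition)
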