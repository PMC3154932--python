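"""Approximate inverse map: network -> time series.

Pipeline: row-normalize an arbitrary non-negative adjacency matrix,
recover a node -> quantile ordering by simulated-annealing seriation of a
distance-to-diagonal cost, run a random walk on the Markov matrix, and
emit one value per step drawn uniformly from the walked node's quantile
bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .mapping import DanglingPolicy, MarkovNetwork, QuantilePartition, normalize_rows

__all__ = [
    "AnnealingSchedule",
    "WalkRealization",
    "normalize_adjacency",
    "ordering_cost",
    "propose_segment_move",
    "anneal_ordering",
    "random_walk",
    "emit_series",
    "inverse_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Temperature ladder and move budget for the seriation search.

    ``initial_temperature=None`` requests auto-calibration: the starting
    temperature is set so that roughly half of uphill probe moves would be
    accepted.  ``moves_per_level=None`` defaults to N^2 at run time.
    """

    initial_temperature: Optional[float] = None
    cooling_factor: float = 0.99
    moves_per_level: Optional[int] = None
    min_temperature_ratio: float = 1e-6
    segment_width_scale: float = 1.0
    calibration_moves: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.moves_per_level is not None and self.moves_per_level < 1:
            raise ValueError("moves_per_level must be positive")
        if self.min_temperature_ratio <= 0:
            raise ValueError("min_temperature_ratio must be positive")
        if self.segment_width_scale <= 0:
            raise ValueError("segment_width_scale must be positive")


@dataclass(frozen=True)
class WalkRealization:
    """A random-walk path with the series emitted from it."""

    path: np.ndarray
    emitted: np.ndarray
    seed: int
    start_node: int


def normalize_adjacency(
    A: np.ndarray, dangling_policy: DanglingPolicy = "error"
) -> MarkovNetwork:
    """Row-normalize a square non-negative adjacency matrix.

    For a symmetric 0/1 matrix this is the degree normalization
    ``W_ij = A_ij / deg(i)``.  Already row-stochastic input is returned
    unchanged up to floating-point rounding.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency matrix must be finite")
    if np.any(A < 0):
        raise ValueError("adjacency matrix must be non-negative")
    if not A.any():
        raise ValueError("adjacency matrix is all zero")
    return normalize_rows(A, dangling_policy)


def _as_weights(W: Union[MarkovNetwork, np.ndarray]) -> np.ndarray:
    if isinstance(W, MarkovNetwork):
        return W.weights
    return np.asarray(W, dtype=float)


def ordering_cost(W: Union[MarkovNetwork, np.ndarray], order: np.ndarray) -> float:
    """Distance-to-diagonal cost of a node ordering.

    ``C(pi) = (1/N) * sum_{u,v} W[pi(u), pi(v)] * |u - v|`` where
    ``order[u]`` is the node placed at position ``u``.  Invariant under
    reversal of the ordering.
    """
    M = _as_weights(W)
    order = np.asarray(order, dtype=np.int64)
    N = M.shape[0]
    if order.size != N or np.any(np.sort(order) != np.arange(N)):
        raise ValueError("order must be a permutation of 0..N-1")
    pos = np.arange(N)
    dist = np.abs(pos[:, None] - pos[None, :])
    return float((M[np.ix_(order, order)] * dist).sum() / N)


def propose_segment_move(
    order: np.ndarray,
    theta_rel: float,
    rng: np.random.Generator,
    segment_width_scale: float = 1.0,
) -> np.ndarray:
    """Propose a new ordering by relocating a segment of contiguous nodes.

    The segment start and the new position of its first node are uniform;
    the segment width is ``1 + floor(|g|)`` with ``g`` zero-mean Gaussian
    of variance ``scale * theta_rel * N``, clipped to ``[1, N-1]`` — at low
    temperature only single-node moves are proposed.  The segment is cut
    out cyclically, the remainder closed up, and the segment reinserted
    keeping internal order.
    """
    order = np.asarray(order, dtype=np.int64)
    N = order.size
    if N < 2:
        return order.copy()
    var = max(segment_width_scale * theta_rel * N, 0.0)
    g = rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0
    width = int(min(max(1 + math.floor(abs(g)), 1), N - 1))

    start = int(rng.integers(N))
    idx = (start + np.arange(width)) % N
    segment = order[idx]
    keep = np.delete(order, idx)
    new_pos = int(rng.integers(keep.size + 1))
    return np.concatenate([keep[:new_pos], segment, keep[new_pos:]])


def _calibrate_temperature(
    W: np.ndarray,
    order: np.ndarray,
    rng: np.random.Generator,
    schedule: AnnealingSchedule,
) -> float:
    """Pick a starting temperature accepting ~50% of uphill probe moves."""
    base = ordering_cost(W, order)
    uphill = []
    probe = order
    for _ in range(schedule.calibration_moves):
        cand = propose_segment_move(probe, 1.0, rng, schedule.segment_width_scale)
        delta = ordering_cost(W, cand) - base
        if delta > 0:
            uphill.append(delta)
    if not uphill:
        return 1.0
    # exp(-mean_delta / theta0) = 0.5
    return float(np.mean(uphill) / math.log(2.0))


def anneal_ordering(
    W: Union[MarkovNetwork, np.ndarray],
    schedule: Optional[AnnealingSchedule] = None,
    initial_order: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Minimize the distance-to-diagonal cost by simulated annealing.

    Metropolis acceptance (always accept downhill, uphill with probability
    ``exp(-dC / theta)``), geometric cooling, N^2 attempted segment moves
    per temperature level.  Stops when the temperature drops below
    ``min_temperature_ratio * theta0`` or a full level passes with no
    accepted move.  Returns the best-ever ordering and its cost;
    deterministic given the schedule seed.
    """
    M = _as_weights(W)
    N = M.shape[0]
    if N < 2:
        raise ValueError("need at least 2 nodes to order")
    if schedule is None:
        schedule = AnnealingSchedule()
    rng = np.random.default_rng(schedule.seed)

    if initial_order is None:
        order = rng.permutation(N)
    else:
        order = np.asarray(initial_order, dtype=np.int64).copy()
    cost = ordering_cost(M, order)
    best_order, best_cost = order.copy(), cost
    initial_best = best_cost

    theta0 = schedule.initial_temperature
    if theta0 is None:
        theta0 = _calibrate_temperature(M, order, rng, schedule)
    moves = schedule.moves_per_level or N * N
    theta = theta0
    theta_min = schedule.min_temperature_ratio * theta0

    pos = np.arange(N)
    dist = np.abs(pos[:, None] - pos[None, :]).astype(float)
    scale = schedule.segment_width_scale

    level = 0
    while theta >= theta_min:
        accepted = 0
        for _ in range(moves):
            cand = propose_segment_move(order, theta / theta0, rng, scale)
            cand_cost = float((M[np.ix_(cand, cand)] * dist).sum()) / N
            delta = cand_cost - cost
            if delta <= 0 or rng.random() < math.exp(-delta / theta):
                order, cost = cand, cand_cost
                # lateral (delta == 0) moves keep the chain mixing but do
                # not count toward the freeze criterion
                if delta != 0:
                    accepted += 1
                if cost < best_cost:
                    best_order, best_cost = order.copy(), cost
        level += 1
        if level % 200 == 0:
            logger.debug(
                "level %d theta=%.3g cost=%.6g best=%.6g accept=%.2f",
                level, theta, cost, best_cost, accepted / moves,
            )
        if accepted == 0:
            break
        theta *= schedule.cooling_factor

    if best_cost > initial_best:  # pragma: no cover - best-ever tracking guard
        raise AssertionError("best cost exceeded initial cost")
    return best_order, best_cost


def random_walk(
    W: Union[MarkovNetwork, np.ndarray],
    L: int,
    seed_or_rng: Union[int, np.random.Generator] = 0,
    start: Optional[int] = None,
) -> np.ndarray:
    """Sample an ``L``-step node path from a row-stochastic matrix.

    The start node is uniform over nodes unless given.  Reaching a row of
    all-zero weight raises, naming the node.
    """
    M = _as_weights(W)
    N = M.shape[0]
    if L < 1:
        raise ValueError("walk length must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    row_sums = M.sum(axis=1)
    cum = np.cumsum(M, axis=1)

    path = np.empty(L, dtype=np.int64)
    node = int(rng.integers(N)) if start is None else int(start)
    if not 0 <= node < N:
        raise ValueError(f"start node {node} outside [0, {N})")
    path[0] = node
    draws = rng.random(L - 1)
    for t in range(1, L):
        if row_sums[node] <= 0:
            raise ValueError(f"random walk stuck at dangling node {node}")
        node = int(np.searchsorted(cum[node], draws[t - 1] * row_sums[node], side="right"))
        node = min(node, N - 1)
        path[t] = node
    return path


def emit_series(
    path: np.ndarray,
    partition: Optional[QuantilePartition] = None,
    seed_or_rng: Union[int, np.random.Generator] = 0,
    Q: Optional[int] = None,
) -> np.ndarray:
    """Emit one value per walked node, uniform within the node's bin.

    Without a partition, the uniform partition of [0, 1) into ``Q`` bins is
    used (``Q`` defaults to ``max(path) + 1``).  A zero-width bin emits its
    boundary value.
    """
    path = np.asarray(path, dtype=np.int64)
    if partition is None:
        partition = QuantilePartition.uniform(Q if Q is not None else int(path.max()) + 1)
    if path.min() < 0 or path.max() >= partition.Q:
        raise ValueError("path visits nodes outside the partition")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    lo = partition.boundaries[path]
    hi = partition.boundaries[path + 1]
    return lo + rng.random(path.size) * (hi - lo)


def inverse_map(
    network: Union[MarkovNetwork, np.ndarray],
    L: int,
    seed: int = 0,
    schedule: Optional[AnnealingSchedule] = None,
    partition: Optional[QuantilePartition] = None,
    reorder: bool = True,
    start: Optional[int] = None,
    dangling_policy: DanglingPolicy = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Full inverse map: normalize, order nodes, walk, emit.

    When a node <-> quantile correspondence is already known (``partition``
    given, or node indices already meaningful), pass ``reorder=False`` to
    skip the annealing stage and keep the identity ordering.  The master
    ``seed`` is split deterministically into independent annealing /
    start-node / walk / emission streams.

    Returns ``(series, order)`` where ``order[u]`` is the node assigned to
    quantile ``u``.
    """
    if isinstance(network, MarkovNetwork):
        net = network
        if not net.is_row_stochastic(atol=1e-9):
            net = normalize_adjacency(net.weights, dangling_policy)
            net.partition = network.partition
    else:
        net = normalize_adjacency(network, dangling_policy)
    if partition is None:
        partition = net.partition
    N = net.n_nodes

    ss = np.random.SeedSequence(seed)
    anneal_seed, start_seed, walk_seed, emit_seed = ss.spawn(4)

    if reorder:
        if schedule is None:
            schedule = AnnealingSchedule()
        schedule = replace(
            schedule, seed=int(anneal_seed.generate_state(1)[0])
        )
        order, final_cost = anneal_ordering(net, schedule)
        logger.info("annealed ordering cost: %.6g", final_cost)
    else:
        order = np.arange(N)

    if start is None:
        start = int(np.random.default_rng(start_seed).integers(N))
    path = random_walk(net, L, np.random.default_rng(walk_seed), start=start)

    # quantile index of each walked node under the recovered ordering
    node_to_quantile = np.empty(N, dtype=np.int64)
    node_to_quantile[order] = np.arange(N)
    quantile_path = node_to_quantile[path]
    series = emit_series(
        quantile_path, partition, np.random.default_rng(emit_seed), Q=N
    )
    return series, order
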