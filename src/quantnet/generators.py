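"""Generators for every input family used in the validation experiments.

Provides the tunable periodic-to-random toy ensemble, Lorenz and Rossler
trajectories (fixed-step RK4), synthetic network fixtures (ring, modular,
star-with-hubs) and the value-shuffle used for modularity null models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mapping import MarkovNetwork, normalize_rows

__all__ = [
    "ToyParams",
    "LorenzParams",
    "RosslerParams",
    "toy_series",
    "lorenz_series",
    "rossler_series",
    "fixture_network",
    "shuffle_series",
]


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the periodic-to-random toy ensemble.

    ``k`` is the per-step increment (cycles per step) of the periodic
    skeleton; ``p`` the probability that a step is replaced by uniform
    noise on [0, 1).
    """

    k: float = 0.125
    p: float = 0.0
    L: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if not (0.0 < self.k < 1.0):
            raise ValueError("k must lie in (0, 1)")
        if self.L < 2:
            raise ValueError("L must be >= 2")


@dataclass(frozen=True)
class LorenzParams:
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.01
    L: int = 10_000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    discard: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.discard < 0:
            raise ValueError("discard must be non-negative")


@dataclass(frozen=True)
class RosslerParams:
    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    dt: float = 0.01
    L: int = 10_000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    discard: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.discard < 0:
            raise ValueError("discard must be non-negative")


def toy_series(params: ToyParams) -> np.ndarray:
    """Generate one realization of the periodic-to-random ensemble.

    ``x_0 = eta_0``; for ``t >= 1`` with probability ``1 - p`` the step is
    deterministic, ``x_t = (x_{t-1} + k) mod 1``, and with probability
    ``p`` the value is replaced by fresh uniform noise ``eta_t``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    eta = rng.random(params.L)
    noisy = rng.random(params.L) < params.p
    x = np.empty(params.L)
    x[0] = eta[0]
    for t in range(1, params.L):
        x[t] = eta[t] if noisy[t] else (x[t - 1] + params.k) % 1.0
    return x


def _rk4(deriv, state: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Fixed-step RK4; returns the trajectory including the initial state."""
    out = np.empty((n_steps + 1, state.size))
    out[0] = state
    y = state.astype(float)
    for i in range(n_steps):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"trajectory diverged at step {i + 1}")
        out[i + 1] = y
    return out


def lorenz_series(params: LorenzParams) -> np.ndarray:
    """First coordinate of a Lorenz trajectory, burn-in discarded."""
    s, r, b = params.sigma, params.rho, params.beta

    def deriv(y: np.ndarray) -> np.ndarray:
        x1, x2, x3 = y
        return np.array([s * (x2 - x1), x1 * (r - x3) - x2, x1 * x2 - b * x3])

    n = params.discard + params.L
    traj = _rk4(deriv, np.asarray(params.initial_state, dtype=float), params.dt, n - 1)
    return traj[params.discard:, 0]


def rossler_series(params: RosslerParams) -> np.ndarray:
    """First coordinate of a Rossler trajectory, burn-in discarded."""
    a, b, c = params.a, params.b, params.c

    def deriv(y: np.ndarray) -> np.ndarray:
        x1, x2, x3 = y
        return np.array([-x2 - x3, x1 + a * x2, b + x3 * (x1 - c)])

    n = params.discard + params.L
    traj = _rk4(deriv, np.asarray(params.initial_state, dtype=float), params.dt, n - 1)
    return traj[params.discard:, 0]


def _is_weakly_connected(A: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components(A + A.T, directed=False)
    return n == 1


def _modular_adjacency(
    N: int, m: int, p_in: float, p_out: float, rng: np.random.Generator
) -> np.ndarray:
    blocks = np.array_split(np.arange(N), m)
    A = np.zeros((N, N))
    member = np.empty(N, dtype=np.int64)
    for b, idx in enumerate(blocks):
        member[idx] = b
    same = member[:, None] == member[None, :]
    draw = rng.random((N, N))
    A[same & (draw < p_in)] = 1.0
    A[~same & (draw < p_out)] = 1.0
    np.fill_diagonal(A, 0.0)
    # guarantee every node can leave: chain each block internally
    for idx in blocks:
        for i in range(len(idx)):
            A[idx[i], idx[(i + 1) % len(idx)]] = 1.0
    return A


def _star_hubs_adjacency(N: int, h: int, rng: np.random.Generator) -> np.ndarray:
    if h < 1 or h >= N:
        raise ValueError("need 1 <= h < N hubs")
    A = np.zeros((N, N))
    # each leaf attaches to two random hubs; overlapping hub neighborhoods
    # keep the graph non-seriable, as in real star-like networks
    n_attach = min(2, h)
    for leaf in range(h, N):
        for hub in rng.choice(h, size=n_attach, replace=False):
            A[hub, leaf] = 1.0
            A[leaf, hub] = 1.0
    # hub-hub clique so the walker can change branches
    for i in range(h):
        for j in range(h):
            if i != j:
                A[i, j] = 1.0
    return A


def fixture_network(
    kind: str,
    N: int,
    seed: int = 0,
    m: int = 2,
    p_in: float = 0.8,
    p_out: float = 0.05,
    h: int = 3,
    require_connected: bool = True,
    max_tries: int = 100,
) -> MarkovNetwork:
    """Build a row-normalized synthetic network fixture.

    kind ``"ring"``: the N-cycle permutation matrix.  ``"modular"``: ``m``
    dense blocks with intra-block arc probability ``p_in`` and inter-block
    probability ``p_out`` (blocks occupy contiguous index ranges, so the
    identity ordering is already seriation-friendly).  ``"star_hubs"``:
    ``h`` hubs with disjoint leaf sets plus hub-hub arcs.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)

    if kind == "ring":
        A = np.zeros((N, N))
        A[np.arange(N), (np.arange(N) + 1) % N] = 1.0
        return normalize_rows(A, "error")
    if kind == "modular":
        for attempt in range(max_tries):
            A = _modular_adjacency(N, m, p_in, p_out, rng)
            if not require_connected or p_out == 0 or _is_weakly_connected(A):
                return normalize_rows(A, "error")
        raise RuntimeError(f"no connected modular network in {max_tries} tries")
    if kind == "star_hubs":
        A = _star_hubs_adjacency(N, h, rng)
        return normalize_rows(A, "error")
    raise ValueError(f"unknown fixture kind {kind!r}")


def shuffle_series(series: np.ndarray, seed: int = 0) -> np.ndarray:
    """Uniform random permutation of the series values (multiset preserved)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must contain at least 2 points")
    rng = np.random.default_rng(seed)
    return rng.permutation(x)
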