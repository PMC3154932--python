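"""Readers and writers for the canonical on-disk formats.

Plain-text series (one value per line, or single-column CSV with a
header), TSV weighted edge lists, JSON partition metadata.  All writes
are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .mapping import QuantilePartition

__all__ = [
    "read_series",
    "write_series",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
]

PathLike = Union[str, Path]


def _atomic_write(path: PathLike, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_series(path: PathLike) -> np.ndarray:
    """Read a series from one-value-per-line text or single-column CSV.

    Lines starting with ``#`` are comments; a single non-numeric first
    line is treated as a CSV header.
    """
    values = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        token = line.split(",")[0].strip()
        try:
            values.append(float(token))
        except ValueError:
            if lineno == 1 and not values:
                continue  # header
            raise ValueError(f"{path}: non-numeric token {token!r} on line {lineno}") from None
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return np.asarray(values, dtype=float)


def write_series(path: PathLike, series: np.ndarray) -> None:
    """Write one value per line at 17 significant digits."""
    x = np.asarray(series, dtype=float)
    _atomic_write(path, "".join(f"{v:.17g}\n" for v in x))


def read_network(
    path: PathLike, undirected: bool = False
) -> tuple[np.ndarray, list]:
    """Read a TSV edge list into a dense adjacency matrix.

    Columns are ``source  target  [weight]``; the weight defaults to 1
    (required unless ``undirected``).  Node ids are remapped to dense
    0-based integers in first-appearance order; the original labels are
    returned alongside.  Undirected input is symmetrized.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: need at least 2 columns")
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    if lineno == 1 and not edges:
                        continue  # header
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            elif undirected:
                w = 1.0
            else:
                raise ValueError(f"{path}: line {lineno}: missing weight column")
            if w < 0:
                raise ValueError(f"{path}: line {lineno}: negative weight {w}")
            edges.append((parts[0], parts[1], w))
    if not edges:
        raise ValueError(f"{path}: no edges found")

    labels: list = []
    index: dict = {}
    for s, t, _ in edges:
        for v in (s, t):
            if v not in index:
                index[v] = len(labels)
                labels.append(v)
    N = len(labels)
    A = np.zeros((N, N))
    seen = set()
    for s, t, w in edges:
        i, j = index[s], index[t]
        if (i, j) in seen:
            raise ValueError(f"{path}: duplicate arc {s!r} -> {t!r}")
        seen.add((i, j))
        A[i, j] = w
        if undirected:
            A[j, i] = w
    return A, labels


def write_network(
    path: PathLike, W: np.ndarray, labels: Optional[list] = None
) -> None:
    """Write nonzero arcs as a ``source<TAB>target<TAB>weight`` TSV.

    A node-id mapping table is written beside the edge list
    (``<path>.nodes``) since downstream semantics depend on node order.
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    if labels is None:
        labels = list(range(N))
    rows, cols = np.nonzero(W)
    body = "".join(
        f"{labels[i]}\t{labels[j]}\t{W[i, j]:.17g}\n" for i, j in zip(rows, cols)
    )
    _atomic_write(path, body)
    mapping = "".join(f"{idx}\t{lab}\n" for idx, lab in enumerate(labels))
    _atomic_write(str(path) + ".nodes", mapping)


def write_partition(path: PathLike, partition: QuantilePartition) -> None:
    payload = {
        "boundaries": [float(b) for b in partition.boundaries],
        "occupancy": [int(o) for o in partition.occupancy],
    }
    _atomic_write(path, json.dumps(payload, indent=2) + "\n")


def read_partition(path: PathLike) -> QuantilePartition:
    with open(path) as fh:
        payload = json.load(fh)
    return QuantilePartition(
        np.asarray(payload["boundaries"], dtype=float),
        np.asarray(payload["occupancy"], dtype=np.int64),
    )
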