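"""Shared periodic-boundary geometry helpers (orthorhombic boxes only)."""

from __future__ import annotations

from collections import deque

import numpy as np

from .trajectory_io import Topology


def minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Min-image distance matrix, shape ``(len(a), len(b))``."""
    disp = a[:, None, :] - b[None, :, :]
    disp = minimum_image(disp, box)
    return np.sqrt(np.sum(disp * disp, axis=-1))


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, box)``."""
    return coords - box * np.floor(coords / box)


def make_whole(
    coords: np.ndarray, box: np.ndarray | None, topology: Topology
) -> np.ndarray:
    """Unwrap bonded components across periodic images.

    Walks each bonded connected component breadth-first from its lowest atom
    index, placing every neighbour at the minimum-image position relative to
    its already-placed parent.  Unbonded atoms are left untouched.  With no
    box the input is returned unchanged.
    """
    if box is None:
        return coords
    out = coords.copy()
    n = len(coords)
    adjacency: dict = {}
    for i, j in topology.bonds:
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)
    visited = np.zeros(n, dtype=bool)
    for start in sorted(adjacency):
        if visited[start]:
            continue
        visited[start] = True
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in adjacency.get(i, ()):
                if visited[j]:
                    continue
                disp = minimum_image(out[j] - out[i], box)
                out[j] = out[i] + disp
                visited[j] = True
                queue.append(j)
    return out


def backbone_path(topology: Topology, backbone_indices: np.ndarray) -> np.ndarray:
    """Order backbone atoms head-to-tail along their induced bond path.

    The bond subgraph induced on ``backbone_indices`` must be a simple path
    (two endpoints, no branches, fully connected); otherwise a
    ``ValueError`` names the defect.  Returns the indices in path order,
    starting from the lower-index endpoint.
    """
    idx = [int(i) for i in backbone_indices]
    idx_set = set(idx)
    if not idx:
        raise ValueError("empty backbone selection")
    if len(idx) == 1:
        return np.array(idx, dtype=int)
    adjacency: dict = {i: [] for i in idx}
    for i, j in topology.bonds:
        if i in idx_set and j in idx_set:
            adjacency[i].append(j)
            adjacency[j].append(i)
    degrees = {i: len(v) for i, v in adjacency.items()}
    branches = [i for i, d in degrees.items() if d > 2]
    if branches:
        raise ValueError(f"backbone is branched at atoms {sorted(branches)}")
    endpoints = sorted(i for i, d in degrees.items() if d == 1)
    if len(endpoints) != 2:
        isolated = sorted(i for i, d in degrees.items() if d == 0)
        raise ValueError(
            "backbone bond path is disconnected"
            + (f"; atoms without backbone bonds: {isolated}" if isolated else "")
        )
    order = [endpoints[0]]
    prev = None
    while len(order) < len(idx):
        nxt = [j for j in adjacency[order[-1]] if j != prev]
        if not nxt:
            missing = sorted(idx_set - set(order))
            raise ValueError(
                f"backbone path breaks after atom {order[-1]}; unreachable: {missing}"
            )
        prev = order[-1]
        order.append(nxt[0])
    return np.array(order, dtype=int)
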