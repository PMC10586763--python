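"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest

from lspprn.align import ResidueNetwork
from lspprn.geometry import ResidueGeometry, StructureFrame


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_frame(rng: np.random.Generator, n: int = 20, spread: float = 14.0,
                 frame_index: int = 0) -> StructureFrame:
    """A cloud of residues with random Cα positions and random unit Cβ
    offsets (1.5 Å)."""
    ca = rng.uniform(-spread, spread, size=(n, 3))
    off = rng.normal(size=(n, 3))
    off = 1.5 * off / np.linalg.norm(off, axis=1, keepdims=True)
    residues = [
        ResidueGeometry(i + 1, f"A{i + 1}", ca[i], ca[i] + off[i])
        for i in range(n)
    ]
    return StructureFrame(residues, frame_index=frame_index)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def contact_pairs_bruteforce(frame, cutoff):
    """O(n²) double loop over all residue pairs."""
    out = set()
    res = frame.residues
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            if np.linalg.norm(res[a].ca - res[b].ca) < cutoff:
                i, j = res[a].residue_index, res[b].residue_index
                out.add((min(i, j), max(i, j)))
    return out


def betweenness_bruteforce(net: ResidueNetwork) -> dict[int, float]:
    """Exhaustive simple-path enumeration betweenness oracle.

    For every unordered node pair, enumerates all simple paths, finds the
    lexicographic minimum of (total D = −ln(W), hop count), and splits one
    unit of credit over the interior vertices of every minimal path.
    """
    dist = {e: -math.log(w) for e, w in net.weights.items()}
    nodes = sorted(net.residue_indices or {i for e in net.weights for i in e})
    adj = {v: set() for v in nodes}
    for i, j in dist:
        adj[i].add(j)
        adj[j].add(i)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []

        def dfs(v, visited, length, path):
            if v == t:
                paths.append((length, list(path)))
                return
            for u in sorted(adj[v]):
                if u not in visited:
                    key = (min(v, u), max(v, u))
                    visited.add(u)
                    path.append(u)
                    dfs(u, visited, length + dist[key], path)
                    path.pop()
                    visited.remove(u)

        dfs(s, {s}, 0.0, [s])
        if not paths:
            continue
        best = min(l for l, _ in paths)
        near = [(l, p) for l, p in paths if l <= best + 1e-12]
        min_hops = min(len(p) for _, p in near)
        minimal = [p for _, p in near if len(p) == min_hops]
        for p in minimal:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(minimal)
    return bc


def random_network(rng: np.random.Generator, n: int, p: float = 0.5) -> ResidueNetwork:
    """Random weighted network with W ~ U(0.05, 1)."""
    weights = {}
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if rng.random() < p:
                weights[(i, j)] = float(rng.uniform(0.05, 1.0))
    return ResidueNetwork(
        n_residues=n,
        weights=weights,
        residue_indices=tuple(range(1, n + 1)),
        residue_labels=tuple(f"A{i}" for i in range(1, n + 1)),
    )
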