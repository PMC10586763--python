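"""Centrality analysis of weighted residue networks.

Degree centrality (DC) is the unnormalized weighted degree (node strength):
high DC marks residues whose local contacts are conserved across most frame
pairs, i.e. locally rigid context.  Betweenness centrality (BC) is computed
on edge distances D = −ln(W), so strongly conserved edges are short and BC
counts shortest paths through a residue — high BC marks "communicator"
residues bridging rigid communities.  Both are unnormalized: the analysis
only ever compares residues within a construct or the same residue across
constructs, where normalization constants cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .align import ResidueNetwork

__all__ = [
    "CentralityProfile",
    "ComparisonReport",
    "HubPartition",
    "to_networkx",
    "degree_centrality",
    "edge_distances",
    "betweenness_centrality",
    "aggregate_windows",
    "percent_difference",
    "detect_hubs",
]


# ---------------------------------------------------------------------------
# graph view
# ---------------------------------------------------------------------------

def to_networkx(net: ResidueNetwork) -> nx.Graph:
    """networkx view of a residue network, with ``weight`` (W) and
    ``distance`` (D = −ln W) edge attributes.  Nodes are added in roster
    order so downstream algorithms are deterministic."""
    g = nx.Graph()
    nodes = net.residue_indices or sorted({i for e in net.weights for i in e})
    labels = net.residue_labels or tuple(str(i) for i in nodes)
    for idx, lab in zip(nodes, labels):
        g.add_node(idx, residue_label=lab)
    for (i, j), w in sorted(net.weights.items()):
        g.add_edge(i, j, weight=w, distance=-math.log(w))
    return g


def degree_centrality(net: ResidueNetwork) -> dict[int, float]:
    """Weighted degree DC(v) = Σ_u W(u, v); residues with no retained edge
    get 0."""
    nodes = net.residue_indices or sorted({i for e in net.weights for i in e})
    dc = {int(i): 0.0 for i in nodes}
    for (i, j), w in net.weights.items():
        dc[i] += w
        dc[j] += w
    return dc


def edge_distances(net: ResidueNetwork) -> dict[tuple[int, int], float]:
    """D(e) = −ln W(e).  W = 1 gives D = 0; absent edges have no distance."""
    for e, w in net.weights.items():
        if not (0.0 < w <= 1.0):
            raise ValueError(f"edge {e} weight {w} outside (0, 1]")
    return {e: -math.log(w) for e, w in net.weights.items()}


def betweenness_centrality(net: ResidueNetwork) -> dict[int, float]:
    """Unnormalized shortest-path betweenness on distances D = −ln(W).

    BC(v) = Σ over unordered pairs {s, t}, s ≠ v ≠ t, of σ_st(v)/σ_st where
    σ_st counts minimum-total-distance paths.  Pairs in different components
    contribute nothing.  Zero-distance edges (W = 1) are legal: ties in
    total distance are refined by hop count (fewest edges), which keeps
    path counting well-posed on zero-distance cycles — predecessor-based
    counting is otherwise undefined there, and enumerating *all*
    zero-length simple paths through a fully conserved clique would be
    combinatorial noise, not signal.
    """
    dist = edge_distances(net)
    nodes = [int(v) for v in (net.residue_indices
                              or sorted({i for e in net.weights for i in e}))]
    adj: dict[int, list[tuple[int, float]]] = {v: [] for v in nodes}
    for (i, j), d in sorted(dist.items()):
        adj[i].append((j, d))
        adj[j].append((i, d))
    bc = _brandes_lexicographic(nodes, adj)
    return {v: bc[v] / 2.0 for v in nodes}  # undirected: each pair counted twice


def _brandes_lexicographic(
    nodes: Sequence[int], adj: Mapping[int, Sequence[tuple[int, float]]]
) -> dict[int, float]:
    """Brandes' algorithm with Dijkstra on lexicographic (Σ D, hops) path
    lengths.  Exact float comparisons: equal-distance equal-hop paths all
    count with multiplicity."""
    import heapq

    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        S: list[int] = []
        pred: dict[int, list[int]] = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        final: dict[int, tuple[float, int]] = {}
        seen: dict[int, tuple[float, int]] = {s: (0.0, 0)}
        heap: list[tuple[tuple[float, int], int]] = [((0.0, 0), s)]
        while heap:
            d, v = heapq.heappop(heap)
            if v in final:
                continue
            final[v] = d
            S.append(v)
            for u, w in adj[v]:
                if u in final:
                    continue
                cand = (d[0] + w, d[1] + 1)
                if u not in seen or cand < seen[u]:
                    seen[u] = cand
                    heapq.heappush(heap, (cand, u))
                    sigma[u] = sigma[v]
                    pred[u] = [v]
                elif cand == seen[u]:
                    sigma[u] += sigma[v]
                    pred[u].append(v)
        delta = {v: 0.0 for v in S}
        while S:
            w = S.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

@dataclass
class CentralityProfile:
    """Per-residue DC and BC across windows, with mean and standard error.

    ``dc_values``/``bc_values`` are (n_windows, n_residues) arrays in roster
    order.  SE is the sample standard deviation over windows divided by
    √n_windows.
    """

    construct_label: str
    residue_indices: tuple[int, ...]
    residue_labels: tuple[str, ...]
    dc_values: np.ndarray
    bc_values: np.ndarray
    window_ids: tuple[int, ...] = ()

    def __post_init__(self):
        self.dc_values = np.asarray(self.dc_values, float)
        self.bc_values = np.asarray(self.bc_values, float)
        m, n = self.dc_values.shape
        if self.bc_values.shape != (m, n) or n != len(self.residue_indices):
            raise ValueError("window-value array shapes disagree with roster")
        if m < 2:
            raise ValueError("need ≥ 2 windows to form a standard error")

    @property
    def n_windows(self) -> int:
        return self.dc_values.shape[0]

    @property
    def dc_mean(self) -> np.ndarray:
        return self.dc_values.mean(axis=0)

    @property
    def bc_mean(self) -> np.ndarray:
        return self.bc_values.mean(axis=0)

    @property
    def dc_se(self) -> np.ndarray:
        return self.dc_values.std(axis=0, ddof=1) / np.sqrt(self.n_windows)

    @property
    def bc_se(self) -> np.ndarray:
        return self.bc_values.std(axis=0, ddof=1) / np.sqrt(self.n_windows)

    def per_residue(self) -> dict[int, dict]:
        out = {}
        for k, idx in enumerate(self.residue_indices):
            out[idx] = {
                "residue_label": self.residue_labels[k],
                "dc_values": self.dc_values[:, k].tolist(),
                "bc_values": self.bc_values[:, k].tolist(),
                "dc_mean": float(self.dc_mean[k]),
                "dc_se": float(self.dc_se[k]),
                "bc_mean": float(self.bc_mean[k]),
                "bc_se": float(self.bc_se[k]),
            }
        return out


def aggregate_windows(
    per_window: Sequence[tuple[int, Mapping[int, float], Mapping[int, float]]],
    construct_label: str = "",
    residue_labels: Mapping[int, str] | None = None,
) -> CentralityProfile:
    """Collect per-window (window_id, DC map, BC map) triples into a
    profile with per-residue means and standard errors."""
    if len(per_window) < 2:
        raise ValueError("need ≥ 2 windows to aggregate")
    roster = sorted(per_window[0][1].keys())
    for wid, dc, bc in per_window:
        for m in (dc, bc):
            if sorted(m.keys()) != roster:
                missing = set(roster).symmetric_difference(m.keys())
                raise ValueError(
                    f"window {wid}: residue roster mismatch (differs at {sorted(missing)})"
                )
    dc_values = np.array([[dc[i] for i in roster] for _, dc, _ in per_window])
    bc_values = np.array([[bc[i] for i in roster] for _, _, bc in per_window])
    labels = tuple(
        (residue_labels or {}).get(i, str(i)) for i in roster
    )
    return CentralityProfile(
        construct_label=construct_label,
        residue_indices=tuple(roster),
        residue_labels=labels,
        dc_values=dc_values,
        bc_values=bc_values,
        window_ids=tuple(wid for wid, _, _ in per_window),
    )


# ---------------------------------------------------------------------------
# construct comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-residue percent difference of a centrality between a mutant and a
    reference construct: 100 × (mut − ref)/ref of the window means.

    Residues whose reference mean is 0 are *flagged* (``undefined``), not
    dropped: their percent difference is NaN.
    """

    reference_label: str
    mutant_label: str
    metric: str
    residue_indices: tuple[int, ...]
    residue_labels: tuple[str, ...]
    pct_diff: np.ndarray
    undefined: tuple[int, ...]

    def as_dict(self) -> dict[int, float]:
        return {i: float(v) for i, v in zip(self.residue_indices, self.pct_diff)}


def percent_difference(
    mutant: CentralityProfile,
    reference: CentralityProfile,
    metric: Literal["DC", "BC"] = "DC",
) -> ComparisonReport:
    """Percent difference from the reference of each residue's mean DC
    (or BC)."""
    if mutant.residue_indices != reference.residue_indices:
        raise ValueError("mutant and reference rosters differ")
    ref = reference.dc_mean if metric == "DC" else reference.bc_mean
    mut = mutant.dc_mean if metric == "DC" else mutant.bc_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mut - ref) / ref
    undefined = tuple(
        int(i) for i, r in zip(reference.residue_indices, ref) if r == 0
    )
    pct = np.where(ref == 0, np.nan, pct)
    return ComparisonReport(
        reference_label=reference.construct_label,
        mutant_label=mutant.construct_label,
        metric=metric,
        residue_indices=reference.residue_indices,
        residue_labels=reference.residue_labels,
        pct_diff=pct,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# hub communities
# ---------------------------------------------------------------------------

@dataclass
class HubPartition:
    """Residue communities ranked by mean DC (rank 0 = most rigid hub)."""

    communities: tuple[frozenset[int], ...]
    community_mean_dc: tuple[float, ...]
    labels: dict[int, int]  # residue_index -> community rank


def detect_hubs(net: ResidueNetwork) -> HubPartition:
    """Partition residues into communities by greedy modularity
    maximization on W and rank them by mean DC.

    Deterministic: the graph is built in sorted roster/edge order and ties
    in the ranking are broken by the lowest residue index in the community.
    """
    g = to_networkx(net)
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    core = g.subgraph([v for v in g.nodes if v not in isolated])
    if core.number_of_nodes() > 0:
        comms = nx.community.greedy_modularity_communities(core, weight="weight")
    else:
        comms = []
    communities = [frozenset(int(v) for v in c) for c in comms]
    communities += [frozenset([int(v)]) for v in isolated]
    dc = degree_centrality(net)
    mean_dc = [float(np.mean([dc[v] for v in c])) for c in communities]
    order = sorted(
        range(len(communities)),
        key=lambda k: (-mean_dc[k], min(communities[k])),
    )
    communities = [communities[k] for k in order]
    mean_dc = [mean_dc[k] for k in order]
    labels = {v: rank for rank, c in enumerate(communities) for v in sorted(c)}
    return HubPartition(
        communities=tuple(communities),
        community_mean_dc=tuple(mean_dc),
        labels=labels,
    )
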