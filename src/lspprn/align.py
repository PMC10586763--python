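"""Pairwise local-spatial-pattern (LSP) alignment and window aggregation.

Two conformations of the same chain are compared residue-pair by
residue-pair: a pair is "retained" when its four-number link descriptor
(three Cα/Cβ cross-distances and the dihedral θ) agrees between the two
frames within the similarity tolerances.  Aggregating all C(n_frames, 2)
pairwise alignments of a window and dividing by the pair count yields a
weighted residue network whose edge weight W ∈ (0, 1] is the fraction of
frame pairs in which the local orientation of that residue pair was
conserved — a retention probability.  With the standard 100-frame window
this is an average over 4950 adjacency matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import (
    LspCutoffs,
    StructureEnsemble,
    StructureFrame,
    circular_difference_deg,
    pair_descriptors,
)

__all__ = [
    "AlignmentGraph",
    "ResidueNetwork",
    "WindowingScheme",
    "Window",
    "descriptors_match",
    "align_pair",
    "window_network",
    "split_windows",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentGraph:
    """Result of one pairwise LSP alignment: the set of residue-index pairs
    whose orientation was conserved between the two frames."""

    edges: frozenset[tuple[int, int]]
    n_residues: int


@dataclass
class ResidueNetwork:
    """Weighted residue network for one window.

    ``weights`` maps unordered residue-index pairs (i < j) to the retention
    fraction W ∈ (0, 1]; pairs never retained carry no entry.
    """

    n_residues: int
    weights: dict[tuple[int, int], float]
    window_id: int = 0
    n_pairs_aggregated: int = 0
    construct_label: str = ""
    residue_indices: tuple[int, ...] = ()
    residue_labels: tuple[str, ...] = ()

    def __post_init__(self):
        for (i, j), w in self.weights.items():
            if i >= j:
                raise ValueError(f"edge ({i},{j}) not in i<j order")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({i},{j}) weight {w} outside (0, 1]")


@dataclass(frozen=True)
class WindowingScheme:
    """Consecutive, non-overlapping blocks of frames taken per trajectory.

    The reference design splits three 50 ns trajectories into 10 ns
    intervals of 100 frames each, i.e. 15 windows in total.
    """

    frames_per_window: int = 100

    def __post_init__(self):
        if self.frames_per_window < 2:
            raise ValueError("frames_per_window must be ≥ 2")


@dataclass
class Window:
    trajectory_id: int
    window_id: int
    frames: list[StructureFrame]


# ---------------------------------------------------------------------------
# descriptor matching
# ---------------------------------------------------------------------------

def descriptors_match(a, b, cutoffs: LspCutoffs) -> bool:
    """True iff two link descriptors agree within the similarity tolerances
    (all comparisons strict; Δθ is the circular difference)."""
    return bool(
        abs(a.d_caca - b.d_caca) < cutoffs.tol_caca
        and abs(a.d_ca1cb2 - b.d_ca1cb2) < cutoffs.tol_cross
        and abs(a.d_ca2cb1 - b.d_ca2cb1) < cutoffs.tol_cross
        and circular_difference_deg(a.theta, b.theta) < cutoffs.tol_theta
    )


def _match_rows(da: np.ndarray, db: np.ndarray, cutoffs: LspCutoffs) -> np.ndarray:
    """Vectorized descriptors_match over (m, 4) descriptor tables."""
    ok = (
        (np.abs(da[:, 0] - db[:, 0]) < cutoffs.tol_caca)
        & (np.abs(da[:, 1] - db[:, 1]) < cutoffs.tol_cross)
        & (np.abs(da[:, 2] - db[:, 2]) < cutoffs.tol_cross)
        & (circular_difference_deg(da[:, 3], db[:, 3]) < cutoffs.tol_theta)
    )
    # NaN θ (degenerate dihedral) never matches
    return ok & ~np.isnan(da[:, 3]) & ~np.isnan(db[:, 3])


# ---------------------------------------------------------------------------
# frame preprocessing
# ---------------------------------------------------------------------------

def _check_rosters(frames: Sequence[StructureFrame]) -> None:
    roster = frames[0].roster
    for f in frames[1:]:
        if f.roster != roster:
            for a, b in zip(roster, f.roster):
                if a != b:
                    raise ValueError(
                        f"residue roster mismatch: {a} vs {b} "
                        f"(frame {f.frame_index})"
                    )
            raise ValueError("residue roster length mismatch")


class _FrameTables:
    """Per-frame condensed contact masks and descriptor tables over the
    union of contact pairs, shared by align_pair and window_network."""

    def __init__(self, frames: Sequence[StructureFrame], cutoffs: LspCutoffs):
        _check_rosters(frames)
        n = len(frames[0])
        self.n_residues = n
        self.indices = np.array([r.residue_index for r in frames[0].residues])
        self.labels = tuple(r.residue_label for r in frames[0].residues)
        # condensed upper-triangle contact masks per frame
        contact = np.stack(
            [pdist(f.ca_array) < cutoffs.contact_cutoff for f in frames]
        )
        union = np.any(contact, axis=0)
        pos_i, pos_j = np.triu_indices(n, k=1)
        self.pos_i = pos_i[union]
        self.pos_j = pos_j[union]
        self.contact = contact[:, union]  # (n_frames, n_union)
        self.desc = np.stack(
            [
                pair_descriptors(f.ca_array, f.cb_array, self.pos_i, self.pos_j)
                for f in frames
            ]
        )  # (n_frames, n_union, 4)

    def pair_edges_mask(self, a: int, b: int, cutoffs: LspCutoffs) -> np.ndarray:
        """Boolean mask over the union pair list: retained edges of the
        alignment of frames a and b."""
        cand = self.contact[a] & self.contact[b]
        return cand & _match_rows(self.desc[a], self.desc[b], cutoffs)

    def edge_key(self, mask: np.ndarray) -> list[tuple[int, int]]:
        ii = self.indices[self.pos_i[mask]]
        jj = self.indices[self.pos_j[mask]]
        return [(int(min(a, b)), int(max(a, b))) for a, b in zip(ii, jj)]


# ---------------------------------------------------------------------------
# alignment operations
# ---------------------------------------------------------------------------

def align_pair(
    f1: StructureFrame, f2: StructureFrame, cutoffs: LspCutoffs | None = None
) -> AlignmentGraph:
    """LSP-align two frames.

    Candidate pairs are the intersection of the two frames' contact graphs;
    a candidate is retained iff its descriptors match within tolerances.
    Symmetric in (f1, f2).
    """
    cutoffs = cutoffs or LspCutoffs()
    t = _FrameTables([f1, f2], cutoffs)
    mask = t.pair_edges_mask(0, 1, cutoffs)
    return AlignmentGraph(edges=frozenset(t.edge_key(mask)), n_residues=t.n_residues)


def window_network(
    window_frames: Sequence[StructureFrame],
    cutoffs: LspCutoffs | None = None,
    window_id: int = 0,
    construct_label: str = "",
) -> ResidueNetwork:
    """Aggregate all C(n, 2) pairwise alignments of a window into one
    weighted residue network; W(i,j) = retained-pair count / C(n, 2)."""
    cutoffs = cutoffs or LspCutoffs()
    m = len(window_frames)
    if m < 2:
        raise ValueError("a window needs at least 2 frames")
    t = _FrameTables(window_frames, cutoffs)
    counts = np.zeros(t.contact.shape[1], dtype=np.int64)
    for a, b in combinations(range(m), 2):
        counts += t.pair_edges_mask(a, b, cutoffs)
    n_pairs = m * (m - 1) // 2
    mask = counts > 0
    weights = {
        key: float(c) / n_pairs
        for key, c in zip(t.edge_key(mask), counts[mask])
    }
    logger.debug(
        "window %d (%s): %d frames, %d frame pairs, %d edges",
        window_id, construct_label or "-", m, n_pairs, len(weights),
    )
    return ResidueNetwork(
        n_residues=t.n_residues,
        weights=weights,
        window_id=window_id,
        n_pairs_aggregated=n_pairs,
        construct_label=construct_label,
        residue_indices=tuple(int(i) for i in t.indices),
        residue_labels=t.labels,
    )


def split_windows(
    ensembles: StructureEnsemble | Iterable[StructureEnsemble],
    scheme: WindowingScheme | None = None,
) -> list[Window]:
    """Split one or more trajectories into consecutive, non-overlapping
    windows of ``frames_per_window`` frames (windows never span trajectory
    boundaries; trailing remainder frames are dropped with a warning)."""
    scheme = scheme or WindowingScheme()
    if isinstance(ensembles, StructureEnsemble):
        ensembles = [ensembles]
    w = scheme.frames_per_window
    windows: list[Window] = []
    window_id = 0
    for traj_id, ens in enumerate(ensembles):
        n = len(ens.frames)
        if n < w:
            raise ValueError(
                f"trajectory {traj_id} ({ens.construct_label!r}) has {n} frames, "
                f"fewer than one window of {w}"
            )
        n_win, rem = divmod(n, w)
        if rem:
            logger.warning(
                "trajectory %d (%s): dropping %d trailing frames "
                "(not a full window of %d)",
                traj_id, ens.construct_label or "-", rem, w,
            )
        for k in range(n_win):
            windows.append(
                Window(
                    trajectory_id=traj_id,
                    window_id=window_id,
                    frames=list(ens.frames[k * w : (k + 1) * w]),
                )
            )
            window_id += 1
    return windows
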