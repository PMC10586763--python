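"""Residue geometry layer: coordinate containers, virtual-Cβ construction,
Cα contact graphs, and the four-number local-spatial-pattern link descriptor.

Every quantity here is an *internal* coordinate of a residue pair — three
inter-atom distances and one dihedral — so descriptors are invariant under
global rigid motion of a structure and need no superposition step.
Coordinates are in Å throughout; angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DegenerateGeometryError",
    "ResidueGeometry",
    "StructureFrame",
    "StructureEnsemble",
    "LinkDescriptor",
    "LspCutoffs",
    "build_virtual_cb",
    "contact_pairs",
    "link_descriptor",
    "pair_descriptors",
    "circular_difference_deg",
]

# Cα–Cβ bond and tetrahedral angle used when a Cβ has to be constructed
# (glycine).  1.521 Å / 110.5° are the standard ideal values for the
# N–Cα–Cβ and C–Cα–Cβ angles of an L-amino acid.
IDEAL_CA_CB_BOND = 1.521
IDEAL_N_CA_CB_ANGLE = 110.5

_CB_BOND_MIN = 0.5
_CB_BOND_MAX = 3.0


class DegenerateGeometryError(ValueError):
    """Raised when backbone atoms are collinear/coincident or a dihedral
    is undefined (a Cβ lying on the Cα–Cα axis)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueGeometry:
    """Cα/Cβ coordinates of one residue in one conformation.

    ``residue_index`` is the 1-based ordinal in the chain; ``residue_label``
    is free text (e.g. ``"R42"``) carrying whatever numbering convention the
    user prefers — it never enters any computation.
    """

    residue_index: int
    residue_label: str
    ca: np.ndarray
    cb: np.ndarray
    cb_is_virtual: bool = False

    def __post_init__(self):
        ca = np.asarray(self.ca, dtype=float)
        cb = np.asarray(self.cb, dtype=float)
        if ca.shape != (3,) or cb.shape != (3,):
            raise ValueError(f"residue {self.residue_label}: ca/cb must be 3-vectors")
        if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cb))):
            raise ValueError(f"residue {self.residue_label}: non-finite coordinates")
        d = float(np.linalg.norm(ca - cb))
        if not (_CB_BOND_MIN <= d <= _CB_BOND_MAX):
            raise ValueError(
                f"residue {self.residue_label}: Cα–Cβ distance {d:.3f} Å outside "
                f"[{_CB_BOND_MIN}, {_CB_BOND_MAX}] Å sanity bounds"
            )
        object.__setattr__(self, "ca", ca)
        object.__setattr__(self, "cb", cb)

    def __eq__(self, other):
        if not isinstance(other, ResidueGeometry):
            return NotImplemented
        return (
            self.residue_index == other.residue_index
            and self.residue_label == other.residue_label
            and np.array_equal(self.ca, other.ca)
            and np.array_equal(self.cb, other.cb)
            and self.cb_is_virtual == other.cb_is_virtual
        )


@dataclass
class StructureFrame:
    """One conformation: an ordered list of residues plus frame metadata."""

    residues: list[ResidueGeometry]
    frame_index: int = 0
    time: float | None = None  # ns, optional

    _ca: np.ndarray | None = field(default=None, repr=False, compare=False)
    _cb: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        idx = [r.residue_index for r in self.residues]
        if len(set(idx)) != len(idx):
            dup = sorted({i for i in idx if idx.count(i) > 1})
            raise ValueError(f"duplicate residue_index values: {dup}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def roster(self) -> tuple[tuple[int, str], ...]:
        return tuple((r.residue_index, r.residue_label) for r in self.residues)

    @property
    def ca_array(self) -> np.ndarray:
        if self._ca is None:
            self._ca = np.array([r.ca for r in self.residues], dtype=float)
        return self._ca

    @property
    def cb_array(self) -> np.ndarray:
        if self._cb is None:
            self._cb = np.array([r.cb for r in self.residues], dtype=float)
        return self._cb

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        """Return a copy with every atom mapped through x → R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [
            ResidueGeometry(r.residue_index, r.residue_label,
                            R @ r.ca + t, R @ r.cb + t, r.cb_is_virtual)
            for r in self.residues
        ]
        return StructureFrame(new, frame_index=self.frame_index, time=self.time)


@dataclass
class StructureEnsemble:
    """An ordered set of conformations of one construct."""

    frames: list[StructureFrame]
    construct_label: str = ""
    source: str = ""

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        roster = self.frames[0].roster
        for f in self.frames[1:]:
            if f.roster != roster:
                for a, b in zip(roster, f.roster):
                    if a != b:
                        raise ValueError(
                            f"residue roster drift at frame {f.frame_index}: "
                            f"{a} vs {b}"
                        )
                raise ValueError(
                    f"residue roster length drift at frame {f.frame_index}: "
                    f"{len(roster)} vs {len(f.roster)}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def roster(self) -> tuple[tuple[int, str], ...]:
        return self.frames[0].roster


@dataclass(frozen=True)
class LinkDescriptor:
    """Four internal coordinates of a residue pair: three distances (Å) and
    the signed dihedral θ of the atom sequence Cβ1–Cα1–Cα2–Cβ2 (degrees,
    IUPAC sign convention, range (−180, 180])."""

    d_caca: float
    d_ca1cb2: float
    d_ca2cb1: float
    theta: float

    def __post_init__(self):
        if min(self.d_caca, self.d_ca1cb2, self.d_ca2cb1) <= 0:
            raise ValueError("link descriptor distances must be positive")
        if not (-180.0 < self.theta <= 180.0):
            raise ValueError(f"theta {self.theta} outside (-180, 180]")


@dataclass(frozen=True)
class LspCutoffs:
    """Contact cutoff and similarity tolerances.

    Defaults are the standard published operating point: Cα–Cα contact at
    <12 Å; a pair's orientation counts as conserved between two frames when
    ΔCα1–Cα2 < 0.2 Å, ΔCα1–Cβ2 < 0.45 Å, ΔCα2–Cβ1 < 0.45 Å and the circular
    Δθ < 10°.  All comparisons are strict.
    """

    contact_cutoff: float = 12.0
    tol_caca: float = 0.2
    tol_cross: float = 0.45
    tol_theta: float = 10.0

    def __post_init__(self):
        if min(self.contact_cutoff, self.tol_caca, self.tol_cross, self.tol_theta) <= 0:
            raise ValueError("all cutoffs must be strictly positive")
        if self.tol_theta > 180:
            raise ValueError("tol_theta cannot exceed 180°")


# ---------------------------------------------------------------------------
# virtual Cβ
# ---------------------------------------------------------------------------

def build_virtual_cb(
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    bond_length: float = IDEAL_CA_CB_BOND,
    residue: str = "",
) -> np.ndarray:
    """Place an ideal-geometry Cβ from backbone N/Cα/C.

    The Cβ direction makes equal angles (110.5°) with the Cα→N and Cα→C
    bonds and leaves the N–Cα–C plane on the side consistent with
    L-amino-acid chirality.  |result − ca| equals ``bond_length`` exactly
    (up to float rounding).
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    who = f" (residue {residue})" if residue else ""
    v1 = n - ca
    v2 = c - ca
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-6 or n2 < 1e-6:
        raise DegenerateGeometryError(f"coincident backbone atoms{who}")
    u1, u2 = v1 / n1, v2 / n2
    perp = np.cross(u1, u2)
    np_ = np.linalg.norm(perp)
    if np_ < 1e-6:
        raise DegenerateGeometryError(f"collinear backbone atoms N/Cα/C{who}")
    perp /= np_
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    # d·u1 = d·u2 = cos(110.5°); decompose d = −a·bis + b·perp
    a = -np.cos(np.radians(IDEAL_N_CA_CB_ANGLE)) / float(bis @ u1)
    a = min(a, 1.0)
    b = np.sqrt(max(0.0, 1.0 - a * a))
    d = -a * bis + b * perp
    d /= np.linalg.norm(d)
    return ca + bond_length * d


# ---------------------------------------------------------------------------
# contacts and descriptors
# ---------------------------------------------------------------------------

def contact_pairs(frame: StructureFrame, cutoffs: LspCutoffs) -> set[tuple[int, int]]:
    """Unordered residue-index pairs whose Cα–Cα distance is strictly below
    the contact cutoff.  Sequence-adjacent pairs are *not* excluded."""
    ca = frame.ca_array
    idx = np.array([r.residue_index for r in frame.residues])
    d = squareform(pdist(ca))
    ii, jj = np.nonzero(np.triu(d < cutoffs.contact_cutoff, k=1))
    return {(int(min(a, b)), int(max(a, b))) for a, b in zip(idx[ii], idx[jj])}


def _dihedral_deg(p0, p1, p2, p3):
    """Signed dihedral of the atom sequence p0–p1–p2–p3, vectorized over
    leading axes.  Range (−180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(c12 * c23, axis=-1)
    y = np.sum(np.cross(c12, c23) * b2, axis=-1) / np.where(b2n == 0, 1.0, b2n)
    theta = np.degrees(np.arctan2(y, x))
    return np.where(theta <= -180.0, theta + 360.0, theta)


def pair_descriptors(
    ca: np.ndarray, cb: np.ndarray, i: np.ndarray, j: np.ndarray
) -> np.ndarray:
    """Descriptor table for position pairs (i, j) of one frame.

    ``ca``/``cb``: (n, 3) coordinate arrays; ``i``/``j``: integer position
    arrays.  Returns an (m, 4) array of [d_caca, d_ca1cb2, d_ca2cb1, θ].
    Undefined dihedrals (Cβ on the Cα–Cα axis) yield NaN θ — callers that
    need a hard error use :func:`link_descriptor`.
    """
    ca1, ca2 = ca[i], ca[j]
    cb1, cb2 = cb[i], cb[j]
    out = np.empty((len(i), 4), float)
    out[:, 0] = np.linalg.norm(ca1 - ca2, axis=-1)
    out[:, 1] = np.linalg.norm(ca1 - cb2, axis=-1)
    out[:, 2] = np.linalg.norm(ca2 - cb1, axis=-1)
    # degenerate: cross products vanish when a Cβ sits on the Cα–Cα axis
    c12 = np.cross(ca1 - cb1, ca2 - ca1)
    c23 = np.cross(ca2 - ca1, cb2 - ca2)
    bad = (np.linalg.norm(c12, axis=-1) < 1e-9) | (np.linalg.norm(c23, axis=-1) < 1e-9)
    theta = _dihedral_deg(cb1, ca1, ca2, cb2)
    out[:, 3] = np.where(bad, np.nan, theta)
    return out


def link_descriptor(r1: ResidueGeometry, r2: ResidueGeometry) -> LinkDescriptor:
    """The four-number orientation signature of one residue pair."""
    if r1.residue_index == r2.residue_index:
        raise ValueError("link descriptor requires two distinct residues")
    ca = np.stack([r1.ca, r2.ca])
    cb = np.stack([r1.cb, r2.cb])
    if np.linalg.norm(ca[0] - ca[1]) < 1e-9:
        raise DegenerateGeometryError(
            f"coincident Cα atoms for residues {r1.residue_label}/{r2.residue_label}"
        )
    row = pair_descriptors(ca, cb, np.array([0]), np.array([1]))[0]
    if np.isnan(row[3]):
        raise DegenerateGeometryError(
            f"dihedral undefined (Cβ on the Cα–Cα axis) for residues "
            f"{r1.residue_label}/{r2.residue_label}"
        )
    return LinkDescriptor(*map(float, row))


def circular_difference_deg(a, b):
    """Circular absolute difference of two angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)
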