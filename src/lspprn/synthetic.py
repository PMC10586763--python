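"""Seeded generator of structural ensembles with planted rigidity structure.

The generator emulates, at the level of *statistical geometry*, what a
molecular-dynamics ensemble of a small zinc-finger-like domain looks like
to a local-spatial-pattern analysis: two internally rigid residue
communities (the "Zn²⁺ hubs"), a flexible surface loop, optional coupling
of that loop into a rigid core (the proline-stiffening analog), and
arbitrary per-frame global rigid-body motion.  The noise model is Gaussian
coordinate jitter with per-residue orientation jitter — deliberately not a
force field: the target is the statistical behaviour of the LSP residue
network pipeline, not MD realism.

All randomness flows from ``EnsembleSpec.seed``; identical spec + seed
gives a bit-identical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import (
    IDEAL_CA_CB_BOND,
    ResidueGeometry,
    StructureEnsemble,
    StructureFrame,
)

__all__ = [
    "EnsembleSpec",
    "generate",
    "apply_coupling",
    "remove_coupling",
    "default_wt_spec",
    "default_coupling",
    "base_geometry",
]

_CA_CA_SPACING = 3.8  # Å, consecutive Cα along the chain


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of one synthetic ensemble.

    ``rigid_blocks`` and ``flexible_set`` partition a subset of the
    1-based residue indices; remaining residues jitter with
    ``sigma_background``.  ``coupling`` is ``(loop_residues, block_id)``:
    when set, those residues move with the target block's shared per-frame
    transform and jitter with ``sigma_rigid`` — the loop is stiffened into
    the core.  Jitter is applied before global motion, and each residue's
    Cβ moves rigidly with its local frame (translation + small random
    rotation about Cα), so descriptors degrade through genuine orientation
    change.
    """

    n_residues: int = 50
    rigid_blocks: tuple[frozenset[int], ...] = (
        frozenset(range(5, 15)),   # hub 1 (Zn-site analog)
        frozenset(range(33, 43)),  # hub 2
    )
    flexible_set: frozenset[int] = frozenset(range(18, 27))  # surface loop
    coupling: Optional[tuple[frozenset[int], int]] = None
    sigma_rigid: float = 0.15       # Å, per-residue jitter inside blocks
    sigma_flex: float = 1.2         # Å, independent loop jitter
    sigma_background: float = 0.4   # Å, everything else
    rot_jitter_deg_per_ang: float = 8.0   # local-frame rotation, deg per Å of σ
    block_wobble_deg: float = 2.0   # shared per-block rotation std
    block_wobble_trans: float = 0.1  # Å, shared per-block translation std
    global_motion: bool = True
    global_translation: float = 20.0  # Å, uniform range of per-frame drift
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        # coerce plain lists (e.g. from YAML) into the canonical set types
        object.__setattr__(
            self, "rigid_blocks", tuple(frozenset(b) for b in self.rigid_blocks)
        )
        object.__setattr__(self, "flexible_set", frozenset(self.flexible_set))
        if self.coupling is not None:
            residues, block_id = self.coupling
            object.__setattr__(self, "coupling", (frozenset(residues), int(block_id)))
        all_res = set(range(1, self.n_residues + 1))
        claimed: set[int] = set()
        for b in self.rigid_blocks:
            if b & claimed:
                raise ValueError("rigid blocks overlap")
            claimed |= b
        if claimed & self.flexible_set:
            raise ValueError("rigid blocks overlap the flexible set")
        claimed |= self.flexible_set
        if not claimed <= all_res:
            raise ValueError("block/flexible residues outside 1..n_residues")
        if not (self.sigma_rigid < self.sigma_flex
                or self.sigma_rigid == self.sigma_flex == 0.0):
            raise ValueError("sigma_rigid must be smaller than sigma_flex")
        if self.coupling is not None:
            residues, block_id = self.coupling
            if not 0 <= block_id < len(self.rigid_blocks):
                raise ValueError(f"coupling targets unknown block {block_id}")
            in_blocks = set().union(*self.rigid_blocks)
            hit = sorted(set(residues) & in_blocks)
            if hit:
                raise ValueError(f"cannot couple residues already in a block: {hit}")
            if not set(residues) <= self.flexible_set:
                raise ValueError("coupled residues must belong to the flexible set")

    @property
    def sigma_per_residue(self) -> np.ndarray:
        """Positional jitter σ (Å) per residue, index 0 = residue 1."""
        sig = np.full(self.n_residues, self.sigma_background)
        for b in self.rigid_blocks:
            sig[[i - 1 for i in b]] = self.sigma_rigid
        sig[[i - 1 for i in self.flexible_set]] = self.sigma_flex
        if self.coupling is not None:
            sig[[i - 1 for i in self.coupling[0]]] = self.sigma_rigid
        return sig

    @property
    def block_of_residue(self) -> np.ndarray:
        """Per-residue block id (−1 = none); coupled residues carry their
        target block's id."""
        blk = np.full(self.n_residues, -1, dtype=int)
        for k, b in enumerate(self.rigid_blocks):
            blk[[i - 1 for i in b]] = k
        if self.coupling is not None:
            residues, block_id = self.coupling
            blk[[i - 1 for i in residues]] = block_id
        return blk


# ---------------------------------------------------------------------------
# base geometry: deterministic self-avoiding curve on a sphere
# ---------------------------------------------------------------------------

def base_geometry(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic compact backbone: Cα positions along a spherical
    spiral with 3.8 Å spacing, Cβ offset radially outward.

    The sphere radius is scaled so the chain exactly fits, giving a
    globular fold ~25–30 Å across for 50 residues: consecutive turns sit
    6–8 Å apart, so the 12 Å contact graph is non-trivial but sparse.
    Returns (ca, cb) arrays of shape (n, 3).
    """
    n_turns = 6.5
    t0 = 0.35
    t = np.linspace(t0, np.pi - t0, 20001)
    # unit-radius spiral and its cumulative arc length
    xyz = np.stack(
        [np.sin(t) * np.cos(n_turns * t), np.sin(t) * np.sin(n_turns * t), np.cos(t)],
        axis=1,
    )
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    radius = (n_residues - 1) * _CA_CA_SPACING / cum[-1]
    targets = np.arange(n_residues) * _CA_CA_SPACING / radius
    ca = np.stack([np.interp(targets, cum, xyz[:, k]) for k in range(3)], axis=1)
    ca *= radius
    outward = ca / np.linalg.norm(ca, axis=1, keepdims=True)
    cb = ca + IDEAL_CA_CB_BOND * outward
    return ca, cb


# ---------------------------------------------------------------------------
# random rigid transforms
# ---------------------------------------------------------------------------

def _rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
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


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: EnsembleSpec) -> StructureEnsemble:
    """Generate the ensemble defined by ``spec``.

    Per frame: each rigid block receives a shared small rigid wobble about
    its centroid; every residue then receives positional jitter (σ by
    class) and a small random rotation of its Cα→Cβ vector; finally an
    arbitrary global rigid motion is applied if enabled.  Jitter draws come
    from a stream independent of the global-motion stream, so toggling
    global motion changes nothing internal.
    """
    n = spec.n_residues
    ca0, cb0 = base_geometry(n)
    cbvec0 = cb0 - ca0
    sig = spec.sigma_per_residue
    blk = spec.block_of_residue
    rot_sig = spec.rot_jitter_deg_per_ang * sig
    centroids = [
        ca0[[i - 1 for i in sorted(b)]].mean(axis=0) for b in spec.rigid_blocks
    ]
    jitter_rng, global_rng = np.random.default_rng(spec.seed).spawn(2)

    frames = []
    for f in range(spec.n_frames):
        ca = ca0.copy()
        cbvec = cbvec0.copy()
        # shared block wobble (coupled residues ride along)
        for k in range(len(spec.rigid_blocks)):
            axis = jitter_rng.normal(size=3)
            angle = jitter_rng.normal(0.0, spec.block_wobble_deg)
            trans = jitter_rng.normal(0.0, spec.block_wobble_trans, size=3)
            R = _rotation_from_axis_angle(axis, angle)
            members = blk == k
            ca[members] = (ca[members] - centroids[k]) @ R.T + centroids[k] + trans
            cbvec[members] = cbvec[members] @ R.T
        # per-residue positional + orientational jitter
        ca += jitter_rng.normal(size=(n, 3)) * sig[:, None]
        axes = jitter_rng.normal(size=(n, 3))
        angles = jitter_rng.normal(size=n) * rot_sig
        for r in range(n):
            if rot_sig[r] > 0:
                cbvec[r] = _rotation_from_axis_angle(axes[r], angles[r]) @ cbvec[r]
        # nuisance global motion
        Rg = _uniform_rotation(global_rng)
        tg = global_rng.uniform(-spec.global_translation, spec.global_translation, 3)
        if spec.global_motion:
            center = ca.mean(axis=0)
            ca = (ca - center) @ Rg.T + center + tg
            cbvec = cbvec @ Rg.T
        residues = [
            ResidueGeometry(r + 1, f"A{r + 1}", ca[r], ca[r] + cbvec[r])
            for r in range(n)
        ]
        frames.append(StructureFrame(residues, frame_index=f, time=0.1 * f))
    return StructureEnsemble(
        frames=frames,
        construct_label="synthetic",
        source=f"lspprn.synthetic seed={spec.seed}",
    )


def apply_coupling(
    spec: EnsembleSpec, coupling: tuple[frozenset[int], int]
) -> EnsembleSpec:
    """Stiffen loop residues into a rigid block (the proline-stiffening
    analog).  The coupled residues must currently be flexible; the
    operation is exactly inverted by :func:`remove_coupling`."""
    residues, block_id = coupling
    residues = frozenset(residues)
    if not residues <= spec.flexible_set:
        outside = sorted(residues - spec.flexible_set)
        raise ValueError(f"cannot couple residues not in the flexible set: {outside}")
    return replace(spec, coupling=(residues, block_id))


def remove_coupling(spec: EnsembleSpec) -> EnsembleSpec:
    """Release a coupled loop (the rescue analog); restores the original
    spec exactly."""
    return replace(spec, coupling=None)


def default_wt_spec(seed: int = 0, n_frames: int = 100) -> EnsembleSpec:
    """The default wild-type-like condition: two rigid hubs, one flexible
    loop, global motion on."""
    return EnsembleSpec(seed=seed, n_frames=n_frames)


def default_coupling(spec: EnsembleSpec) -> tuple[frozenset[int], int]:
    """Couple the whole flexible loop into the first rigid block."""
    return (frozenset(spec.flexible_set), 0)
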