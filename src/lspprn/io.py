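"""Readers and writers: multi-model PDB ingestion, residue renumbering,
network (GraphML/GEXF) and table (TSV) serialization.

Multi-model PDB is the canonical ensemble exchange format here — one MODEL
per frame, with at least Cα (plus Cβ, or N/C backbone so a virtual Cβ can
be constructed for glycine).  Binary MD trajectory formats are deliberately
outside the core contract; convert to multi-model PDB first.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .align import ResidueNetwork
from .geometry import (
    IDEAL_CA_CB_BOND,
    ResidueGeometry,
    StructureEnsemble,
    StructureFrame,
    build_virtual_cb,
)
from .metrics import CentralityProfile, ComparisonReport, HubPartition

__all__ = [
    "ReaderConfig",
    "RenumberingMap",
    "read_ensemble",
    "write_ensemble",
    "write_network",
    "write_tables",
]

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class ReaderConfig:
    """How to turn a multi-model PDB into a StructureEnsemble.

    ``model_start``/``model_stop`` select a half-open [start, stop) range
    of 0-based model positions before ``stride`` is applied.  Glycine
    handling: ``"virtual"`` constructs an ideal-geometry Cβ from N/Cα/C,
    ``"drop"`` removes glycine nodes entirely (sensitivity analysis).
    """

    chain: str | None = None
    model_start: int = 0
    model_stop: int | None = None
    stride: int = 1
    glycine_mode: str = "virtual"  # or "drop"
    atom_ca: str = "CA"
    atom_cb: str = "CB"
    atom_n: str = "N"
    atom_c: str = "C"

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be ≥ 1")
        if self.glycine_mode not in ("virtual", "drop"):
            raise ValueError("glycine_mode must be 'virtual' or 'drop'")


@dataclass(frozen=True)
class RenumberingMap:
    """Display-label mapping (e.g. file numbering → PKCβII-style labels).

    Label-only: computations operate on chain ordinals and never see the
    map.  The mapping must be injective; residues it does not cover pass
    through unchanged.
    """

    mapping: Mapping[str, str]

    def __post_init__(self):
        vals = list(self.mapping.values())
        if len(set(vals)) != len(vals):
            raise ValueError("renumbering map is not injective")

    def apply_label(self, label: str) -> str:
        return self.mapping.get(label, label)

    def relabel_profile(self, profile: CentralityProfile) -> CentralityProfile:
        return CentralityProfile(
            construct_label=profile.construct_label,
            residue_indices=profile.residue_indices,
            residue_labels=tuple(self.apply_label(l) for l in profile.residue_labels),
            dc_values=profile.dc_values,
            bc_values=profile.bc_values,
            window_ids=profile.window_ids,
        )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_ensemble(
    path: str | Path,
    cfg: ReaderConfig | None = None,
    construct_label: str = "",
) -> StructureEnsemble:
    """Read a multi-model PDB file into a StructureEnsemble.

    One StructureFrame per retained MODEL; altlocs resolve to the highest
    occupancy (first on ties); every model must present an identical
    residue roster.
    """
    cfg = cfg or ReaderConfig()
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    stop = n_models if cfg.model_stop is None else min(cfg.model_stop, n_models)
    selected = list(range(cfg.model_start, stop, cfg.stride))
    if not selected:
        raise ValueError(f"{path}: model selection is empty ({n_models} models)")
    frames = []
    for out_idx, m in enumerate(selected):
        atoms = pdb.get_structure(model=m + 1, altloc="occupancy")
        frames.append(_frame_from_atoms(atoms, cfg, out_idx, path))
    if len(frames) < 2:
        raise ValueError(f"{path}: an ensemble needs ≥ 2 frames, got {len(frames)}")
    return StructureEnsemble(
        frames=frames,
        construct_label=construct_label or path.stem,
        source=str(path),
    )


def _frame_from_atoms(
    atoms: "struc.AtomArray", cfg: ReaderConfig, frame_index: int, path: Path
) -> StructureFrame:
    mask = atoms.hetero == False  # noqa: E712  (numpy elementwise)
    atoms = atoms[mask]
    if cfg.chain is not None:
        atoms = atoms[atoms.chain_id == cfg.chain]
    elif len(atoms) > 0:
        atoms = atoms[atoms.chain_id == atoms.chain_id[0]]
    if len(atoms) == 0:
        raise ValueError(f"{path}: empty selection (chain {cfg.chain!r})")
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    residues: list[ResidueGeometry] = []
    ordinal = 0
    for s, e in zip(starts[:-1], starts[1:]):
        res = atoms[s:e]
        res_name = str(res.res_name[0])
        res_id = int(res.res_id[0])
        one = _THREE_TO_ONE.get(res_name, "X")
        label = f"{one}{res_id}"
        if res_name == "GLY" and cfg.glycine_mode == "drop":
            continue
        names = list(res.atom_name)
        def _coord(atom: str):
            try:
                return np.array(res.coord[names.index(atom)], float)
            except ValueError:
                return None
        ca = _coord(cfg.atom_ca)
        if ca is None:
            raise ValueError(f"{path}: residue {label} has no {cfg.atom_ca} atom")
        cb = _coord(cfg.atom_cb)
        virtual = False
        if cb is None:
            if res_name != "GLY":
                raise ValueError(
                    f"{path}: non-glycine residue {label} lacks a {cfg.atom_cb} atom"
                )
            n = _coord(cfg.atom_n)
            c = _coord(cfg.atom_c)
            if n is None or c is None:
                raise ValueError(
                    f"{path}: glycine {label} lacks backbone N/C for virtual Cβ"
                )
            cb = build_virtual_cb(n, ca, c, residue=label)
            virtual = True
        ordinal += 1
        residues.append(ResidueGeometry(ordinal, label, ca, cb, cb_is_virtual=virtual))
    return StructureFrame(residues, frame_index=frame_index)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Za-z])(-?\d+)$")


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB (one MODEL per frame, CA and
    CB atoms only).  Residue labels of the form ``R42`` round-trip as
    residue name + number; anything else is written as ALA with the chain
    ordinal as the residue number."""
    path = Path(path)
    roster = ensemble.roster
    res_names, res_ids = [], []
    for idx, label in roster:
        m = _LABEL_RE.match(label)
        if m:
            res_names.append(_ONE_TO_THREE.get(m.group(1).upper(), "ALA"))
            res_ids.append(int(m.group(2)))
        else:
            res_names.append("ALA")
            res_ids.append(idx)
    n_res = len(roster)
    n_atoms = 2 * n_res
    coords = np.zeros((len(ensemble.frames), n_atoms, 3))
    for f, frame in enumerate(ensemble.frames):
        coords[f, 0::2] = frame.ca_array
        coords[f, 1::2] = frame.cb_array
    stack = struc.AtomArrayStack(len(ensemble.frames), n_atoms)
    stack.coord = coords
    stack.chain_id = np.array(["A"] * n_atoms)
    stack.res_id = np.repeat(res_ids, 2)
    stack.res_name = np.repeat(res_names, 2)
    stack.atom_name = np.array(["CA", "CB"] * n_res)
    stack.element = np.array(["C"] * n_atoms)
    stack.hetero = np.zeros(n_atoms, bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(
    net: ResidueNetwork,
    profile: CentralityProfile,
    path: str | Path,
    hubs: HubPartition | None = None,
) -> tuple[Path, Path]:
    """Export a residue network as GraphML and GEXF for graph tools
    (e.g. Gephi, where node diameter is typically mapped to DC).

    Nodes carry residue_label, dc_mean, bc_mean and community; edges carry
    W and D = −ln(W).  Every roster residue appears as a node even when
    isolated.  Returns (graphml_path, gexf_path).
    """
    if net.residue_indices and tuple(net.residue_indices) != tuple(profile.residue_indices):
        raise ValueError("network and profile rosters differ")
    g = nx.Graph()
    dc_mean = profile.dc_mean
    bc_mean = profile.bc_mean
    labels = {} if hubs is None else hubs.labels
    for k, idx in enumerate(profile.residue_indices):
        g.add_node(
            int(idx),
            residue_label=profile.residue_labels[k],
            dc_mean=float(dc_mean[k]),
            bc_mean=float(bc_mean[k]),
            community=int(labels.get(idx, -1)),
        )
    for (i, j), w in sorted(net.weights.items()):
        g.add_edge(i, j, W=float(w), D=float(-np.log(w)))
    path = Path(path)
    graphml = path.with_suffix(".graphml")
    gexf = path.with_suffix(".gexf")
    try:
        nx.write_graphml(g, str(graphml))
        nx.write_gexf(g, str(gexf))
    except OSError as err:
        raise OSError(f"cannot write network files at {path}: {err}") from err
    return graphml, gexf


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return format(float(x), ".6g")


def _safe(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", label) or "construct"


def write_tables(
    profiles: Sequence[CentralityProfile],
    reports: Sequence[ComparisonReport],
    out_dir: str | Path,
) -> list[Path]:
    """Write per-construct centrality TSVs and per-mutant comparison TSVs.

    Columns are fixed; floats use 6 significant digits; undefined percent
    differences (reference mean 0) are written as ``NA``.  Output is
    byte-deterministic for identical inputs.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for p in profiles:
        path = out_dir / f"centrality_{_safe(p.construct_label)}.tsv"
        with open(path, "w") as fh:
            fh.write("residue_index\tresidue_label\tdc_mean\tdc_se\tbc_mean\tbc_se\n")
            for k, idx in enumerate(p.residue_indices):
                fh.write(
                    f"{idx}\t{p.residue_labels[k]}\t{_fmt(p.dc_mean[k])}\t"
                    f"{_fmt(p.dc_se[k])}\t{_fmt(p.bc_mean[k])}\t{_fmt(p.bc_se[k])}\n"
                )
        written.append(path)
    # group DC/BC reports of the same construct pair into one file
    grouped: dict[tuple[str, str], dict[str, ComparisonReport]] = {}
    for r in reports:
        grouped.setdefault((r.mutant_label, r.reference_label), {})[r.metric] = r
    for (mut, ref), by_metric in grouped.items():
        any_r = next(iter(by_metric.values()))
        path = out_dir / f"comparison_{_safe(mut)}_vs_{_safe(ref)}.tsv"
        metrics = [m for m in ("DC", "BC") if m in by_metric]
        cols = "".join(f"\tpct_diff_{m.lower()}" for m in metrics)
        with open(path, "w") as fh:
            fh.write(f"residue_index\tresidue_label{cols}\n")
            for k, idx in enumerate(any_r.residue_indices):
                vals = "".join(f"\t{_fmt(by_metric[m].pct_diff[k])}" for m in metrics)
                fh.write(f"{idx}\t{any_r.residue_labels[k]}{vals}\n")
        written.append(path)
    return written
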