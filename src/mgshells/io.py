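"""Topology and trajectory I/O.

Structures and multi-model PDB trajectories are read and written through
``biotite``; binary trajectory formats (DCD/XTC/TRR), when encountered, are
delegated to ``MDAnalysis``.  Nonbonded parameters (partial charges,
Lennard-Jones Rmin/2 and epsilon, generalized-Born radii) come from a
plain-text tab-separated table keyed on (residue name, atom name), so no
binary force-field format is ever required:

    residue atom    charge  rmin_half   epsilon born_radius

``born_radius`` may be empty or ``NA`` for atoms without a GB radius.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import AtomRecord, Frame, Role, Topology, Trajectory, role_for_residue

__all__ = [
    "read_parameter_table",
    "write_parameter_table",
    "read_topology",
    "read_trajectory",
    "write_trajectory_pdb",
]

PARAM_COLUMNS = ["residue", "atom", "charge", "rmin_half", "epsilon", "born_radius"]

_BINARY_TRAJ_SUFFIXES = {".dcd", ".xtc", ".trr"}


def read_parameter_table(path) -> dict[tuple[str, str], tuple[float, float, float, float | None]]:
    """Parse the parameter TSV into {(residue, atom): (q, rmin/2, eps, born)}."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PARAM_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table {path} lacks columns: {sorted(missing)}")
    table: dict[tuple[str, str], tuple[float, float, float, float | None]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.residue).strip(), str(row.atom).strip())
        if key in table:
            raise ValueError(f"duplicate parameter entry for {key}")
        born = getattr(row, "born_radius", None)
        if born is None or (isinstance(born, float) and np.isnan(born)) or str(born) == "NA":
            born_val: float | None = None
        else:
            born_val = float(born)
        table[key] = (float(row.charge), float(row.rmin_half), float(row.epsilon), born_val)
    return table


def write_parameter_table(topology: Topology, path) -> None:
    """Write one parameter row per distinct (residue name, atom name)."""
    rows = []
    seen = set()
    for a in topology.atoms:
        key = (a.residue_name, a.atom_name)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "residue": a.residue_name,
                "atom": a.atom_name,
                "charge": a.charge,
                "rmin_half": a.lj_rmin_half,
                "epsilon": a.lj_epsilon,
                "born_radius": "NA" if a.born_radius is None else a.born_radius,
            }
        )
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, sep="\t", index=False)


def _element_of(atom_name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().upper()
    # fall back on the leading letter(s) of the atom name
    name = atom_name.strip()
    if name[:2].upper() in {"MG", "NA", "CL"} and len(name) <= 3:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_topology(path, params=None) -> Topology:
    """Build a :class:`Topology` from a PDB file plus optional parameter table.

    Every atom is assigned a role from its residue name.  Atoms without an
    entry in the parameter table get zero charge and LJ parameters (and a
    single summary warning lists them).
    """
    pdb = PDBFile.read(str(path))
    structure = pdb.get_structure(model=1)
    if structure.array_length() == 0:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    table = read_parameter_table(params) if params is not None else {}
    atoms: list[AtomRecord] = []
    unparameterised: list[tuple[str, str]] = []
    for i in range(structure.array_length()):
        res_name = str(structure.res_name[i]).strip()
        atom_name = str(structure.atom_name[i]).strip()
        key = (res_name, atom_name)
        if key in table:
            q, rmin, eps, born = table[key]
        else:
            q, rmin, eps, born = 0.0, 0.0, 0.0, None
            if params is not None and key not in unparameterised:
                unparameterised.append(key)
        atoms.append(
            AtomRecord(
                atom_name=atom_name,
                element=_element_of(atom_name, str(structure.element[i])),
                residue_index=int(structure.res_id[i]),
                residue_name=res_name,
                role=role_for_residue(res_name),
                charge=q,
                lj_rmin_half=rmin,
                lj_epsilon=eps,
                born_radius=born,
            )
        )
    if unparameterised:
        warnings.warn(
            f"{len(unparameterised)} (residue, atom) pairs missing from parameter "
            f"table; zero charge/LJ assigned: {unparameterised[:8]}"
            + ("..." if len(unparameterised) > 8 else ""),
            stacklevel=2,
        )
    return Topology(atoms)


def _boxes_from_stack(stack) -> np.ndarray | None:
    if stack.box is None:
        return None
    boxes = np.atleast_3d(stack.box)
    return np.stack([np.diag(b) for b in boxes])


def read_trajectory(topology: Topology, path, stride: int = 1, frame_interval: float = 1.0) -> Trajectory:
    """Read a coordinate trajectory, keeping every ``stride``-th frame.

    Multi-model PDB is the primary (text) format; ``.dcd``/``.xtc``/``.trr``
    are read through MDAnalysis when present.  Frame times are assigned as
    ``original_frame_index * frame_interval`` (ps) because PDB carries no
    time information.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    suffix = Path(str(path)).suffix.lower()
    if suffix in _BINARY_TRAJ_SUFFIXES:
        return _read_binary_trajectory(topology, path, stride, frame_interval)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    n_models, n_atoms = coords.shape[0], coords.shape[1]
    if n_models == 0:
        raise ValueError(f"no frames in {path}")
    if n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {n_atoms} atoms per frame, topology has {topology.n_atoms}"
        )
    boxes = _boxes_from_stack(stack)
    frames = [
        Frame(
            coordinates=coords[i],
            box=None if boxes is None else boxes[min(i, len(boxes) - 1)],
            time=i * frame_interval,
        )
        for i in range(0, n_models, stride)
    ]
    return Trajectory(topology, frames)


def _read_binary_trajectory(topology, path, stride, frame_interval) -> Trajectory:
    import MDAnalysis as mda

    universe = mda.Universe.empty(topology.n_atoms, trajectory=True)
    universe.load_new(str(path))
    frames = []
    for i, ts in enumerate(universe.trajectory):
        if i % stride:
            continue
        if ts.positions.shape[0] != topology.n_atoms:
            raise ValueError("trajectory atom count does not match topology")
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float)
        frames.append(Frame(coordinates=ts.positions.astype(float), box=box, time=i * frame_interval))
    if not frames:
        raise ValueError(f"no frames in {path}")
    return Trajectory(topology, frames)


def _stack_from_trajectory(traj: Trajectory) -> struc.AtomArrayStack:
    top = traj.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords()
    stack.atom_name = np.array([a.atom_name for a in top.atoms])
    stack.res_id = np.array([a.residue_index for a in top.atoms])
    stack.res_name = np.array([a.residue_name for a in top.atoms])
    stack.element = np.array([a.element for a in top.atoms])
    stack.chain_id = np.array(["A"] * n)
    stack.hetero = np.array([a.role is not Role.RNA for a in top.atoms])
    boxes = traj.boxes()
    if boxes is not None:
        stack.box = np.stack([np.diag(b) for b in boxes])
    return stack


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame).

    Coordinates are stored at the PDB's printed precision (1e-3 Angstrom);
    a read/write round trip reproduces them to that precision.
    """
    pdb = PDBFile()
    pdb.set_structure(_stack_from_trajectory(traj))
    pdb.write(str(path))


def write_topology_pdb(topology: Topology, coordinates: np.ndarray, path, box=None) -> None:
    """Write a single-model PDB snapshot of the topology."""
    traj = Trajectory(topology, [Frame(coordinates=coordinates, box=box)])
    write_trajectory_pdb(traj, path)
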