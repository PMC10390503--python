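"""Domain types shared by every analysis stage.

The in-memory model is deliberately small: a :class:`Topology` (atoms with
force-field parameters and residue bookkeeping), a :class:`Trajectory`
(ordered frames of Cartesian coordinates with optional orthorhombic boxes),
and a :class:`Selection` (validated atom-index sets).  All distance
arithmetic under periodic boundaries goes through
:func:`min_image_distance` / :func:`min_image_displacement`.

Indexing convention: atom and residue indices are 0-based internally;
user-facing residue numbers (``residue_index`` on :class:`AtomRecord`,
selection helpers, output tables) are 1-based, matching the serial
nucleotide numbering used for RNA (G1, A6, C14, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Role",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "role_for_residue",
    "min_image_displacement",
    "min_image_distance",
    "ATOMIC_MASSES",
]


class Role(str, Enum):
    """Coarse chemical role of an atom, derived from its residue name."""

    RNA = "rna"
    LIGAND = "ligand"
    ION = "ion"
    WATER = "water"


#: Residue names mapped to non-RNA roles.  Anything not listed is treated as
#: RNA (the analyses target RNA systems; unknown polymer residues behave as
#: RNA residues, which is the safe default for distance-based statistics).
ION_RESIDUES = {"MG", "MG2", "NA", "NA+", "K", "K+", "CL", "CL-", "CA", "ZN", "MN"}
WATER_RESIDUES = {"HOH", "WAT", "SOL", "TIP3", "SPC", "T3P"}
LIGAND_RESIDUES = {"SAM", "SAH", "LIG", "UNL"}

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "MG": 24.305,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}


def role_for_residue(residue_name: str) -> Role:
    """Map a residue name to a :class:`Role`.

    Metal/halide residues -> ion, water models -> water, the SAM/SAH ligands
    (and generic LIG/UNL) -> ligand, everything else -> rna.
    """
    name = residue_name.strip().upper()
    if name in ION_RESIDUES:
        return Role.ION
    if name in WATER_RESIDUES:
        return Role.WATER
    if name in LIGAND_RESIDUES:
        return Role.LIGAND
    return Role.RNA


@dataclass
class AtomRecord:
    """One atom with its bookkeeping and nonbonded parameters.

    ``charge`` is in elementary charges, ``lj_rmin_half`` (Rmin/2) in
    Angstrom, ``lj_epsilon`` in kcal/mol, ``born_radius`` in Angstrom
    (``None`` when no generalized-Born radius was supplied).
    """

    atom_name: str
    element: str
    residue_index: int  # 1-based serial residue number
    residue_name: str
    role: Role
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    born_radius: float | None = None

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")


class Topology:
    """Ordered atom list plus residue partition.

    ``residues`` is a list of ``(residue_index, residue_name, (start, stop))``
    where ``[start, stop)`` is the contiguous 0-based atom-index range of the
    residue; the ranges partition the atom list in order.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        if len(atoms) == 0:
            raise ValueError("Topology requires at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        self.residues: list[tuple[int, str, tuple[int, int]]] = []
        start = 0
        for i in range(1, len(self.atoms) + 1):
            end_of_res = i == len(self.atoms) or (
                self.atoms[i].residue_index != self.atoms[start].residue_index
            )
            if end_of_res:
                first = self.atoms[start]
                self.residues.append((first.residue_index, first.residue_name, (start, i)))
                start = i
        # cached per-atom arrays for vectorised analyses
        self.residue_of_atom = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.born_radii = np.array(
            [np.nan if a.born_radius is None else a.born_radius for a in self.atoms],
            dtype=float,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(a.element.upper(), 12.0) for a in self.atoms], dtype=float
        )

    def residue_name(self, residue_index: int) -> str:
        for idx, name, _ in self.residues:
            if idx == residue_index:
                return name
        raise KeyError(f"no residue with index {residue_index}")

    def select(
        self,
        *,
        residue: int | Iterable[int] | None = None,
        atom_name: str | Iterable[str] | None = None,
        role: Role | str | None = None,
        element: str | None = None,
    ) -> "Selection":
        """Select atoms by residue number (1-based), atom name, role, element.

        All supplied criteria must hold (logical AND).
        """
        residues = None
        if residue is not None:
            residues = {residue} if isinstance(residue, int) else set(residue)
        names = None
        if atom_name is not None:
            names = {atom_name} if isinstance(atom_name, str) else set(atom_name)
        want_role = Role(role) if role is not None else None
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (residues is None or a.residue_index in residues)
            and (names is None or a.atom_name in names)
            and (want_role is None or a.role is want_role)
            and (element is None or a.element.upper() == element.upper())
        ]
        return Selection(idx, n_atoms=self.n_atoms)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """0-based index of the unique atom (residue, name); KeyError if absent."""
        sel = self.select(residue=residue_index, atom_name=atom_name)
        if len(sel) != 1:
            raise KeyError(
                f"expected exactly one atom {atom_name} in residue {residue_index}, "
                f"found {len(sel)}"
            )
        return int(sel.indices[0])


class Selection:
    """Validated, ordered set of 0-based atom indices."""

    def __init__(self, indices: Iterable[int], n_atoms: int | None = None):
        arr = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices)
        arr = arr.astype(int).ravel()
        if arr.size != np.unique(arr).size:
            raise ValueError("selection indices must be unique")
        if arr.size and arr.min() < 0:
            raise ValueError("selection indices must be non-negative")
        if n_atoms is not None and arr.size and arr.max() >= n_atoms:
            raise ValueError(f"selection index {arr.max()} out of range (n_atoms={n_atoms})")
        self.indices = arr

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self):
        return iter(self.indices.tolist())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Selection({self.indices.tolist()!r})"


def as_indices(sel) -> np.ndarray:
    """Accept a Selection, array-like, or single int; return an int array."""
    if isinstance(sel, Selection):
        return sel.indices
    if isinstance(sel, (int, np.integer)):
        return np.array([int(sel)])
    return np.asarray(sel, dtype=int).ravel()


@dataclass
class Frame:
    """One trajectory frame: N x 3 coordinates (Angstrom), optional box, time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N x 3")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).ravel()
            if self.box.shape != (3,):
                raise ValueError("box must be 3 orthorhombic edge lengths")
            if np.any(self.box <= 0):
                raise ValueError("box edges must be positive")


class Trajectory:
    """A topology plus an ordered list of frames consistent with it."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        if len(frames) == 0:
            raise ValueError("Trajectory requires at least one frame")
        for f in frames:
            if f.coordinates.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} atoms, topology has "
                    f"{topology.n_atoms}"
                )
        times = [f.time for f in frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        self.topology = topology
        self.frames: list[Frame] = list(frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def boxes(self) -> np.ndarray | None:
        """(n_frames, 3) box edges, or None when any frame lacks a box."""
        if any(f.box is None for f in self.frames):
            return None
        return np.stack([f.box for f in self.frames])


def min_image_displacement(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``diff`` is (..., 3); ``box`` is 3 orthorhombic edge lengths or None
    (no periodic wrapping).  Triclinic cells are not supported; externally
    produced non-orthorhombic trajectories must be re-imaged first.
    """
    diff = np.asarray(diff, dtype=float)
    if box is None:
        return diff
    box = np.asarray(box, dtype=float)
    return diff - box * np.round(diff / box)


def min_image_distance(a, b, box=None) -> float:
    """Euclidean distance between points a and b under minimum image.

    Plain Euclidean distance when ``box`` is None.  Symmetric in (a, b); for
    an orthorhombic box the result never exceeds half the box diagonal.
    """
    d = min_image_displacement(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), box)
    return float(np.linalg.norm(d))


def pair_distances(
    coords: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    boxes: np.ndarray | None,
) -> np.ndarray:
    """(F, len(a), len(b)) min-image distances for all frames at once.

    ``coords`` is (F, N, 3); ``boxes`` is (F, 3) or None.
    """
    pa = coords[:, idx_a, :][:, :, None, :]  # (F, A, 1, 3)
    pb = coords[:, idx_b, :][:, None, :, :]  # (F, 1, B, 3)
    diff = pb - pa
    if boxes is not None:
        b = boxes[:, None, None, :]
        diff = diff - b * np.round(diff / b)
    return np.sqrt(np.einsum("fabc,fabc->fab", diff, diff))
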