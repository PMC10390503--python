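"""Seedable synthetic topologies and trajectories with planted ground truth.

The generator emulates just enough of an RNA/Mg2+/ligand system to exercise
the analysis stages: a helix-like pseudo-RNA chain carrying the backbone and
base atoms the analyses address (P, OP1, OP2, O3', O5', C1', a donor/H pair
and an acceptor per base), Mg2+ ions planted at inner-shell (~2.0 A) or
outer-shell (~4.3 A) distances with per-frame Bernoulli occupancies,
bridging waters geometrically interposed between ion and the adjacent
phosphate, a two-state (U/L shape) ligand following a first-order Markov
chain, and explicit hydrogen-bond plans.  All placed atoms receive isotropic
Gaussian jitter.  Every random choice flows from a single seeded generator,
so identical specs give bit-identical trajectories.

No structural realism is attempted beyond the inter-atom distances and
angles the analyses consume; see the methods note for what this does and
does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtomRecord, Frame, Role, Topology, Trajectory
from .io import write_parameter_table, write_topology_pdb, write_trajectory_pdb

__all__ = [
    "IonPlan",
    "LigandPlan",
    "HBondPlan",
    "SyntheticSpec",
    "GroundTruth",
    "build_pseudo_rna_topology",
    "generate_trajectory",
    "write_fixture",
    "uniform_ion_trajectory",
    "default_fixture_spec",
]

# ---------------------------------------------------------------------------
# plans and spec

RNA_ATOMS = ["P", "OP1", "OP2", "O5'", "O3'", "C1'", "N1", "H1", "O4"]
LIGAND_ATOMS = ["N1", "H11", "H12", "S", "CM", "A1", "A2", "CC", "OC1", "OC2"]
WATER_ATOMS = ["O", "H1", "H2"]

#: built-in toy nonbonded parameters: (charge e, Rmin/2 A, epsilon kcal/mol, Born A)
TOY_PARAMS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("rna", "P"): (1.1659, 2.10, 0.2000, 1.85),
    ("rna", "OP1"): (-0.7760, 1.6612, 0.2100, 1.50),
    ("rna", "OP2"): (-0.7760, 1.6612, 0.2100, 1.50),
    ("rna", "O5'"): (-0.4989, 1.6837, 0.1700, 1.50),
    ("rna", "O3'"): (-0.4989, 1.6837, 0.1700, 1.50),
    ("rna", "C1'"): (0.0394, 1.9080, 0.1094, 1.70),
    ("rna", "N1"): (-0.7000, 1.8240, 0.1700, 1.55),
    ("rna", "H1"): (0.4100, 0.6000, 0.0157, 1.20),
    ("rna", "O4"): (-0.5700, 1.6612, 0.2100, 1.50),
    ("ion", "MG"): (2.0000, 0.7926, 0.8947, 1.45),
    ("water", "O"): (-0.8340, 1.7683, 0.1520, 1.50),
    ("water", "H1"): (0.4170, 0.0000, 0.0000, 1.20),
    ("water", "H2"): (0.4170, 0.0000, 0.0000, 1.20),
    ("ligand", "N1"): (-0.8000, 1.8240, 0.1700, 1.55),
    ("ligand", "H11"): (0.4000, 0.6000, 0.0157, 1.20),
    ("ligand", "H12"): (0.4000, 0.6000, 0.0157, 1.20),
    ("ligand", "S"): (0.5000, 2.0000, 0.2500, 1.80),
    ("ligand", "CM"): (0.1000, 1.9080, 0.1094, 1.70),
    ("ligand", "A1"): (0.2000, 1.9080, 0.1094, 1.70),
    ("ligand", "A2"): (0.2000, 1.9080, 0.1094, 1.70),
    ("ligand", "CC"): (0.7000, 1.9080, 0.0860, 1.70),
    ("ligand", "OC1"): (-0.8000, 1.6612, 0.2100, 1.50),
    ("ligand", "OC2"): (-0.8000, 1.6612, 0.2100, 1.50),
}


@dataclass
class IonPlan:
    """One planted Mg2+ ion.

    ``mode`` frames (drawn i.i.d. at ``occupancy``) place the ion at
    ``inner_distance`` or ``outer_distance`` from ``target_atom`` of
    ``target_residue``; the rest of the frames the ion is in bulk solvent.
    A ``bidentate_partner`` residue makes the ion equidistant from the
    target atom of both residues.  ``bridging_waters`` (0/1/2) interposes
    waters between the ion and the adjacent phosphate's OP2/OP1.
    """

    ion_id: str
    target_residue: int
    target_atom: str = "OP2"
    mode: str = "inner"
    occupancy: float = 1.0
    inner_distance: float = 2.0
    outer_distance: float = 4.3
    bidentate_partner: int | None = None
    bridging_waters: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("inner", "outer", "bulk"):
            raise ValueError(f"unknown ion mode {self.mode!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if not self.inner_distance < 2.5:
            raise ValueError("inner_distance must be < 2.5 A")
        if not 2.5 <= self.outer_distance < 5.0:
            raise ValueError("outer_distance must be in [2.5, 5.0) A")
        if self.bridging_waters not in (0, 1, 2):
            raise ValueError("bridging_waters must be 0, 1 or 2")

    @property
    def planted_distance(self) -> float:
        return self.inner_distance if self.mode == "inner" else self.outer_distance


@dataclass
class LigandPlan:
    """Two-state (U/L) ligand conformer plan.

    The conformer follows a first-order Markov chain with stationary
    U-shape probability ``u_shape_occupancy``; ``switch_rate`` scales the
    per-frame transition probabilities (1.0 makes frames independent).  In
    the U shape the ligand amino N1 donates a hydrogen bond to
    ``amino_acceptor`` and the carboxyl oxygen pair sits in the outer shell
    of ``carboxyl_partner_ion``; in the L shape both contacts are broken.
    """

    u_shape_occupancy: float = 0.5
    switch_rate: float = 1.0
    carboxyl_partner_ion: str | None = None
    amino_acceptor: tuple[int, str] | None = None
    bound_hbond_distance: float = 2.9
    unbound_hbond_distance: float = 5.5
    bound_carboxyl_distance: float = 3.5
    unbound_carboxyl_distance: float = 7.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_shape_occupancy <= 1.0:
            raise ValueError("u_shape_occupancy must be in [0, 1]")
        if not 0.0 < self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in (0, 1]")


@dataclass
class HBondPlan:
    """Planted hydrogen bond between RNA residues.

    In "formed" frames (Bernoulli at ``occupancy``) the donor atom sits at
    ``bound_distance`` from the acceptor with its hydrogen on the
    donor-acceptor line; otherwise at ``unbound_distance``.
    """

    donor: tuple[int, str]
    hydrogen: str
    acceptor: tuple[int, str]
    occupancy: float = 1.0
    bound_distance: float = 2.9
    unbound_distance: float = 5.5

    def __post_init__(self) -> None:
        if not self.bound_distance < 3.5 < self.unbound_distance:
            raise ValueError("need bound_distance < 3.5 < unbound_distance")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.donor[0]}:{self.donor[1]}->{self.acceptor[0]}:{self.acceptor[1]}"


@dataclass
class SyntheticSpec:
    n_nucleotides: int = 43
    n_ions: int = 0
    n_frames: int = 100
    frame_interval: float = 100.0  # ps
    box_edge: float | None = None  # A; None -> sized to fit the chain
    noise_sigma: float = 0.05  # A
    ion_plans: list[IonPlan] = field(default_factory=list)
    ligand_plan: LigandPlan | None = None
    hbond_plans: list[HBondPlan] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nucleotides < 2:
            raise ValueError("need at least 2 nucleotides")
        if self.n_frames < 1:
            raise ValueError("need at least 1 frame")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_ions < len(self.ion_plans):
            self.n_ions = len(self.ion_plans)

    @property
    def resolved_box_edge(self) -> float:
        if self.box_edge is not None:
            return float(self.box_edge)
        return max(40.0, 2.81 * self.n_nucleotides + 26.0)


@dataclass
class GroundTruth:
    """Planted per-frame labels: ion modes, H-bond formation, ligand conformer."""

    ion_modes: dict[str, np.ndarray]  # per ion_id: array of 'inner'/'outer'/'bulk'
    hbond_formed: dict[str, np.ndarray]  # per HBondPlan.key: bool array
    ligand_conformer: np.ndarray | None  # 'U'/'L' per frame, or None

    def n_frames(self) -> int:
        for arr in self.ion_modes.values():
            return len(arr)
        for arr in self.hbond_formed.values():
            return len(arr)
        if self.ligand_conformer is not None:
            return len(self.ligand_conformer)
        return 0


# ---------------------------------------------------------------------------
# geometry helpers

_HELIX_RADIUS = 9.0
_HELIX_RISE = 2.81
_P_SPACING = 5.9  # A between consecutive phosphorus atoms

# local-frame offsets (radial, tangential, axial) for each pseudo-nucleotide atom
_LOCAL_OFFSETS = {
    "P": (0.0, 0.0, 0.0),
    "OP1": (1.48, 0.0, 0.0),
    "O5'": (0.0, 1.6, 0.0),
    "O3'": (0.0, -1.6, 0.0),
    "C1'": (-3.0, 0.8, 0.5),
    "N1": (-4.8, 0.3, 0.8),
    "O4": (-4.6, -1.8, 1.0),
}
_OP2_DIRECTION = (-0.6, 0.2, 0.6)  # unit-normalised, scaled to the P-O bond length
_PO_BOND = 1.48


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _two_sphere_point(c1, r1, c2, r2, prefer) -> np.ndarray:
    """A point at distance r1 from c1 and r2 from c2, biased toward ``prefer``.

    The intersection circle of the two spheres is parameterised and the
    point maximising the projection on ``prefer`` is returned.
    """
    c1, c2, prefer = map(np.asarray, (c1, c2, prefer))
    d = float(np.linalg.norm(c2 - c1))
    if not abs(r1 - r2) < d < r1 + r2:
        raise ValueError(
            f"sphere constraint infeasible: |c1-c2|={d:.2f}, r1={r1}, r2={r2}"
        )
    u = _unit(c2 - c1)
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    center = c1 + a * u
    w = prefer - np.dot(prefer, u) * u
    if np.linalg.norm(w) < 1e-9:
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, [1.0, 0.0, 0.0])
    return center + h * _unit(w)


class _Builder:
    """Shared construction of topology, reference coordinates and index maps."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.box = spec.resolved_box_edge
        self.center = np.array([self.box / 2.0, self.box / 2.0, 0.0])
        n = spec.n_nucleotides
        # chord geometry: P-P spacing fixed at _P_SPACING on a helix
        chord_sq = _P_SPACING**2 - _HELIX_RISE**2
        self.dtheta = 2.0 * np.arcsin(np.sqrt(chord_sq) / (2.0 * _HELIX_RADIUS))
        z0 = (self.box - (n - 1) * _HELIX_RISE) / 2.0
        self.z0 = z0
        self._build_topology()
        self._build_reference()

    # ---- topology -------------------------------------------------------
    def _build_topology(self) -> None:
        spec = self.spec
        atoms: list[AtomRecord] = []
        names = "AUGC"
        self.rna_index: dict[tuple[int, str], int] = {}
        for res in range(1, spec.n_nucleotides + 1):
            res_name = names[(res - 1) % 4]
            for name in RNA_ATOMS:
                self.rna_index[(res, name)] = len(atoms)
                atoms.append(self._record(name, res, res_name, "rna"))
        next_res = spec.n_nucleotides + 1
        self.ligand_index: dict[str, int] = {}
        if spec.ligand_plan is not None:
            for name in LIGAND_ATOMS:
                self.ligand_index[name] = len(atoms)
                atoms.append(self._record(name, next_res, "SAM", "ligand"))
            next_res += 1
        self.ion_index: dict[str, int] = {}
        plan_ids = [p.ion_id for p in spec.ion_plans]
        for k in range(spec.n_ions):
            ion_id = plan_ids[k] if k < len(plan_ids) else f"B{k - len(plan_ids) + 1}"
            self.ion_index[ion_id] = len(atoms)
            atoms.append(self._record("MG", next_res, "MG", "ion"))
            next_res += 1
        self.water_slots: dict[str, list[int]] = {}
        for plan in spec.ion_plans:
            slots = []
            for _ in range(plan.bridging_waters):
                slots.append(len(atoms))
                for name in WATER_ATOMS:
                    atoms.append(self._record(name, next_res, "HOH", "water"))
                next_res += 1
            self.water_slots[plan.ion_id] = slots
        self.topology = Topology(atoms)

    @staticmethod
    def _record(name: str, res: int, res_name: str, role_key: str) -> AtomRecord:
        q, rmin, eps, born = TOY_PARAMS[(role_key, name)]
        element = "MG" if name == "MG" else ("S" if name == "S" else name[0])
        if name in ("H1", "H2", "H11", "H12"):
            element = "H"
        if role_key == "water":
            element = "O" if name == "O" else "H"
        return AtomRecord(
            atom_name=name,
            element=element,
            residue_index=res,
            residue_name=res_name,
            role=Role(role_key if role_key != "rna" else "rna"),
            charge=q,
            lj_rmin_half=rmin,
            lj_epsilon=eps,
            born_radius=born,
        )

    # ---- reference geometry --------------------------------------------
    def _frame_vectors(self, res: int):
        theta = (res - 1) * self.dtheta
        r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
        t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        p = self.center + _HELIX_RADIUS * r_hat + np.array([0, 0, self.z0 + (res - 1) * _HELIX_RISE])
        return p, r_hat, t_hat, z_hat

    def outward(self, pos: np.ndarray) -> np.ndarray:
        """Horizontal unit vector pointing away from the helix axis."""
        v = pos - self.center
        v = np.array([v[0], v[1], 0.0])
        return _unit(v)

    def _build_reference(self) -> None:
        spec = self.spec
        coords = np.zeros((self.topology.n_atoms, 3))
        for res in range(1, spec.n_nucleotides + 1):
            p, r_hat, t_hat, z_hat = self._frame_vectors(res)
            basis = np.stack([r_hat, t_hat, z_hat])
            for name, off in _LOCAL_OFFSETS.items():
                coords[self.rna_index[(res, name)]] = p + np.asarray(off) @ basis
            op2_dir = _unit(np.asarray(_OP2_DIRECTION) @ basis)
            coords[self.rna_index[(res, "OP2")]] = p + _PO_BOND * op2_dir
            n1 = coords[self.rna_index[(res, "N1")]]
            coords[self.rna_index[(res, "H1")]] = n1 - 1.0 * r_hat
        # bidentate pairs: tilt both residues' target atoms toward a shared
        # outward midpoint so one ion can reach both (non-realistic on purpose)
        for plan in spec.ion_plans:
            if plan.bidentate_partner is None:
                continue
            i, j = plan.target_residue, plan.bidentate_partner
            pi = coords[self.rna_index[(i, "P")]]
            pj = coords[self.rna_index[(j, "P")]]
            mid = 0.5 * (pi + pj)
            mid = mid + 1.2 * self.outward(mid)
            coords[self.rna_index[(i, plan.target_atom)]] = pi + _PO_BOND * _unit(mid - pi)
            coords[self.rna_index[(j, plan.target_atom)]] = pj + _PO_BOND * _unit(mid - pj)
        self.reference = coords
        self.rna_coords = coords[: spec.n_nucleotides * len(RNA_ATOMS)]

    # ---- planted positions ---------------------------------------------
    def adjacent_residue(self, plan: IonPlan) -> int:
        res = plan.target_residue
        exclude = {res, plan.bidentate_partner}
        cand = res + 1 if res + 1 <= self.spec.n_nucleotides and res + 1 not in exclude else res - 1
        if cand < 1 or cand in exclude:
            raise ValueError(f"no adjacent residue available for plan {plan.ion_id}")
        return cand

    def ion_mode_position(self, plan: IonPlan) -> np.ndarray:
        """Deterministic in-mode ion position for a plan."""
        x0 = self.reference[self.rna_index[(plan.target_residue, plan.target_atom)]]
        p = self.reference[self.rna_index[(plan.target_residue, "P")]]
        d = plan.planted_distance
        if plan.bidentate_partner is not None:
            x1 = self.reference[self.rna_index[(plan.bidentate_partner, plan.target_atom)]]
            return _two_sphere_point(x0, d, x1, d, self.outward(0.5 * (x0 + x1)))
        if plan.bridging_waters > 0:
            adj = self.adjacent_residue(plan)
            a1 = self.reference[self.rna_index[(adj, "OP2")]]
            a2 = self.reference[self.rna_index[(adj, "OP1")]]
            amid = 0.5 * (a1 + a2)
            return _two_sphere_point(x0, d, amid, 4.0, self.outward(x0))
        return x0 + d * _unit(x0 - p)

    def bridging_water_positions(self, plan: IonPlan, ion_pos: np.ndarray) -> list[np.ndarray]:
        """Water oxygens on the ion->adjacent-OP axes, inside the first shell."""
        adj = self.adjacent_residue(plan)
        targets = [
            self.reference[self.rna_index[(adj, "OP2")]],
            self.reference[self.rna_index[(adj, "OP1")]],
        ][: plan.bridging_waters]
        return [ion_pos + 2.1 * _unit(t - ion_pos) for t in targets]

    def water_park_position(self, slot: int) -> np.ndarray:
        # corner grid, far from the chain (box is sized so the corner is clear)
        return np.array([2.5 + 3.0 * (slot % 8), 2.5 + 3.0 * (slot // 8), 2.5])

    def ion_park_position(self, k: int) -> np.ndarray:
        return np.array([self.box - 2.5, 2.5 + 3.0 * k, 2.5])


def build_pseudo_rna_topology(spec: SyntheticSpec) -> Topology:
    """Topology for the spec: pseudo-RNA chain + optional ligand + ions + waters."""
    return _Builder(spec).topology


def _water_geometry(oxygen: np.ndarray) -> np.ndarray:
    """3 x 3 coordinates of one water given its oxygen position."""
    h1 = oxygen + np.array([0.9572, 0.0, 0.0])
    h2 = oxygen + np.array([-0.2399, 0.9266, 0.0])
    return np.stack([oxygen, h1, h2])


def _simulate_conformers(plan: LigandPlan, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """First-order Markov chain over {U, L} with stationary P(U) = occupancy."""
    p, s = plan.u_shape_occupancy, plan.switch_rate
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype="<U1")
    state = "U" if u[0] < p else "L"
    states[0] = state
    for f in range(1, n_frames):
        if state == "U":
            state = "L" if u[f] < s * (1.0 - p) else "U"
        else:
            state = "U" if u[f] < s * p else "L"
        states[f] = state
    return states


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate the planted trajectory and its ground-truth labels.

    Placement order per frame: ions (in-mode position or bulk), bridging
    waters, ligand conformer, H-bond donors; then a single Gaussian jitter
    pass over all atoms.  In-mode positions are deterministic functions of
    the reference geometry, so everything vectorises over frames.
    """
    builder = _Builder(spec)
    rng = np.random.default_rng(spec.seed)
    F, N = spec.n_frames, builder.topology.n_atoms
    coords = np.tile(builder.reference, (F, 1, 1))
    box = np.full(3, builder.box)

    ion_modes: dict[str, np.ndarray] = {}
    park_slot = 0
    water_slot = 0
    for plan in spec.ion_plans:
        idx = builder.ion_index[plan.ion_id]
        in_mode = rng.random(F) < plan.occupancy
        if plan.mode == "bulk":
            in_mode = np.zeros(F, dtype=bool)
        modes = np.where(in_mode, plan.mode, "bulk").astype("<U5")
        ion_modes[plan.ion_id] = modes
        pos = builder.ion_mode_position(plan)
        coords[in_mode, idx, :] = pos
        n_bulk = int((~in_mode).sum())
        if n_bulk:
            coords[~in_mode, idx, :] = _draw_bulk(rng, n_bulk, box, builder.rna_coords)
        # bridging waters follow the ion in its mode frames, else park
        waters = builder.water_slots.get(plan.ion_id, [])
        if waters:
            w_positions = builder.bridging_water_positions(plan, pos)
            for w_atom_start, w_oxygen in zip(waters, w_positions):
                w_coords = _water_geometry(w_oxygen)
                park = _water_geometry(builder.water_park_position(water_slot))
                water_slot += 1
                coords[in_mode, w_atom_start : w_atom_start + 3, :] = w_coords
                coords[~in_mode, w_atom_start : w_atom_start + 3, :] = park
    # unplanned ions stay in bulk
    for ion_id, idx in builder.ion_index.items():
        if ion_id in ion_modes:
            continue
        ion_modes[ion_id] = np.full(F, "bulk", dtype="<U5")
        coords[:, idx, :] = _draw_bulk(rng, F, box, builder.rna_coords)
        park_slot += 1

    conformers = None
    if spec.ligand_plan is not None:
        conformers = _simulate_conformers(spec.ligand_plan, F, rng)
        lig_u, lig_l = _ligand_state_coords(builder, spec.ligand_plan)
        is_u = conformers == "U"
        lig_idx = np.array([builder.ligand_index[n] for n in LIGAND_ATOMS])
        coords[np.ix_(is_u, lig_idx)] = lig_u
        coords[np.ix_(~is_u, lig_idx)] = lig_l

    hbond_formed: dict[str, np.ndarray] = {}
    for plan in spec.hbond_plans:
        formed = rng.random(F) < plan.occupancy
        hbond_formed[plan.key] = formed
        d_idx = builder.rna_index[plan.donor]
        h_idx = builder.rna_index[(plan.donor[0], plan.hydrogen)]
        acc = builder.reference[builder.rna_index[plan.acceptor]]
        donor_nat = builder.reference[d_idx]
        direction = _unit(donor_nat - acc)
        for dist, mask in ((plan.bound_distance, formed), (plan.unbound_distance, ~formed)):
            coords[mask, d_idx, :] = acc + dist * direction
            coords[mask, h_idx, :] = acc + (dist - 1.0) * direction

    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    frames = [
        Frame(coordinates=coords[f], box=box.copy(), time=f * spec.frame_interval)
        for f in range(F)
    ]
    truth = GroundTruth(ion_modes=ion_modes, hbond_formed=hbond_formed, ligand_conformer=conformers)
    return Trajectory(builder.topology, frames), truth


def _draw_bulk(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    rna_coords: np.ndarray,
    min_dist: float = 6.0,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform positions in the box, rejected within ``min_dist`` of the chain."""
    out = np.empty((n, 3))
    need = n
    filled = 0
    for _ in range(max_rounds):
        cand = rng.random((max(2 * need, 16), 3)) * box
        d2 = ((cand[:, None, :] - rna_coords[None, :, :]) ** 2).sum(axis=2)
        ok = cand[np.sqrt(d2.min(axis=1)) >= min_dist]
        take = min(len(ok), need)
        out[filled : filled + take] = ok[:take]
        filled += take
        need -= take
        if need == 0:
            return out
    raise RuntimeError("bulk ion placement failed: box too crowded")


def _ligand_state_coords(builder: _Builder, plan: LigandPlan) -> tuple[np.ndarray, np.ndarray]:
    """Fixed 10-atom ligand coordinates for the U and L states.

    The amino group approaches its acceptor and the carboxyl pair its
    partner ion along directions chosen from a small deterministic
    candidate set to maximise the clearance between the remaining ligand
    atoms and the chain; a clearance below tolerance is a placement
    failure.
    """
    if plan.amino_acceptor is None:
        raise ValueError("LigandPlan requires amino_acceptor")
    acc = builder.reference[builder.rna_index[plan.amino_acceptor]]
    acc_res = plan.amino_acceptor[0]
    z = np.array([0.0, 0.0, 1.0])
    if plan.carboxyl_partner_ion is not None:
        ion_plan = next(
            p for p in builder.spec.ion_plans if p.ion_id == plan.carboxyl_partner_ion
        )
        ion_pos = builder.ion_mode_position(ion_plan)
        anchor = builder.reference[
            builder.rna_index[(ion_plan.target_residue, ion_plan.target_atom)]
        ]
    else:
        ion_pos = acc + 8.0 * builder.outward(acc)
        anchor = acc

    out_acc = builder.outward(acc)
    out_ion = builder.outward(ion_pos)
    u_candidates = [out_acc, _unit(out_acc + z), _unit(out_acc - z),
                    _unit(out_acc + np.cross(z, out_acc)), _unit(out_acc - np.cross(z, out_acc))]
    v_candidates = [_unit(ion_pos - anchor), out_ion, _unit(_unit(ion_pos - anchor) + out_ion),
                    _unit(_unit(ion_pos - anchor) + z), _unit(out_ion + z)]
    # atoms whose short distances are designed contacts, not clashes
    contact_ok = {"N1", "H11", "H12", "OC1", "OC2", "CC"}
    rna = builder.rna_coords
    acc_atoms = np.array(
        [builder.rna_index[(acc_res, n)] for n in RNA_ATOMS], dtype=int
    )
    rna_mask = np.ones(len(rna), dtype=bool)

    def build(u_dir: np.ndarray, v: np.ndarray, n1_dist: float, carboxyl_dist: float) -> np.ndarray:
        t_perp = _unit(np.cross(u_dir, z)) if abs(u_dir[2]) < 0.99 else _unit(np.cross(u_dir, [1, 0, 0]))
        pos: dict[str, np.ndarray] = {}
        pos["N1"] = acc + n1_dist * u_dir
        pos["H11"] = acc + (n1_dist - 1.0) * u_dir
        pos["H12"] = pos["N1"] + 1.0 * t_perp
        pos["S"] = pos["N1"] + 2.5 * u_dir + 1.0 * z
        pos["CM"] = pos["S"] + 1.8 * z
        pos["A1"] = pos["S"] + 2.2 * t_perp
        pos["A2"] = pos["A1"] + 1.5 * t_perp
        w = _unit(np.cross(v, t_perp)) if abs(abs(np.dot(v, t_perp)) - 1.0) > 1e-6 else z
        pos["OC1"] = ion_pos + carboxyl_dist * v
        pos["OC2"] = pos["OC1"] + 2.2 * w
        pos["CC"] = 0.5 * (pos["OC1"] + pos["OC2"]) + 0.7 * v
        return np.stack([pos[n] for n in LIGAND_ATOMS])

    def clearance(lig: np.ndarray) -> float:
        d = np.linalg.norm(lig[:, None, :] - rna[None, :, :], axis=2)
        score = np.inf
        for k, name in enumerate(LIGAND_ATOMS):
            dk = d[k].copy()
            if name in ("N1", "H11", "H12"):
                dk[acc_atoms] = np.inf  # designed amino-acceptor contact
            score = min(score, float(dk.min()))
        return score

    best = None
    for u_dir in u_candidates:
        for v in v_candidates:
            lig_u = build(u_dir, v, plan.bound_hbond_distance, plan.bound_carboxyl_distance)
            lig_l = build(u_dir, v, plan.unbound_hbond_distance, plan.unbound_carboxyl_distance)
            score = min(clearance(lig_u), clearance(lig_l))
            if best is None or score > best[0]:
                best = (score, lig_u, lig_l)
    if best is None or best[0] < 2.2:
        raise RuntimeError(
            f"ligand placement failed: best clearance {0.0 if best is None else best[0]:.2f} A"
        )
    return best[1], best[2]


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(trajectory: Trajectory, ground_truth: GroundTruth, out_dir, spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Write topology.pdb, traj.pdb, params.tsv, truth.tsv (and spec.txt).

    The files are re-readable through :mod:`mgshells.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "topology": out / "topology.pdb",
        "trajectory": out / "traj.pdb",
        "params": out / "params.tsv",
        "truth": out / "truth.tsv",
    }
    first = trajectory.frames[0]
    write_topology_pdb(trajectory.topology, first.coordinates, paths["topology"], box=first.box)
    write_trajectory_pdb(trajectory, paths["trajectory"])
    write_parameter_table(trajectory.topology, paths["params"])
    truth_cols: dict[str, object] = {"frame": np.arange(trajectory.n_frames)}
    for ion_id, modes in ground_truth.ion_modes.items():
        truth_cols[f"ion_{ion_id}_mode"] = modes
    for key, formed in ground_truth.hbond_formed.items():
        truth_cols[f"hbond_{key}"] = formed.astype(int)
    if ground_truth.ligand_conformer is not None:
        truth_cols["ligand_conformer"] = ground_truth.ligand_conformer
    pd.DataFrame(truth_cols).to_csv(paths["truth"], sep="\t", index=False)
    if spec is not None:
        paths["spec"] = out / "spec.txt"
        with open(paths["spec"], "w") as fh:
            for line in _spec_to_lines(spec):
                fh.write(line + "\n")
    return paths


def _spec_to_lines(spec: SyntheticSpec) -> list[str]:
    lines = []
    for key, value in asdict(spec).items():
        lines.append(f"{key} = {value!r}")
    return lines


# ---------------------------------------------------------------------------
# ready-made fixtures

def uniform_ion_trajectory(
    n_ions: int = 50,
    n_frames: int = 1000,
    box_edge: float = 40.0,
    seed: int = 0,
) -> Trajectory:
    """Ideal-gas calibration fixture: one center atom, ions uniform in the box.

    Used to verify the uniform-density normalisation of the radial
    distribution function (g(r) -> 1).
    """
    atoms = [_Builder._record("P", 1, "A", "rna")]
    for k in range(n_ions):
        atoms.append(_Builder._record("MG", 2 + k, "MG", "ion"))
    top = Topology(atoms)
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_edge))
    center = box / 2.0
    frames = []
    for f in range(n_frames):
        c = np.empty((n_ions + 1, 3))
        c[0] = center
        c[1:] = rng.random((n_ions, 3)) * box
        frames.append(Frame(coordinates=c, box=box.copy(), time=float(f)))
    return Trajectory(top, frames)


def default_fixture_spec(seed: int = 0, n_frames: int = 2000, noise_sigma: float = 0.05) -> SyntheticSpec:
    """The package's default synthetic study system.

    A 43-nucleotide pseudo-RNA with eleven stably bound inner-shell Mg2+
    ions (occupancy 1.0) -- one bidentate pair, one single-phosphate site,
    sites with one and two bridging waters -- an OP2:OP1 target ratio of
    8:3, a two-state ligand whose carboxyl coordinates an ion in 77.7% of
    frames, and an RNA-RNA hydrogen bond formed in 88.8% of frames.  The
    occupancy magnitudes mirror the coordination statistics regime of the
    Mg2+-riboswitch systems this package is aimed at.
    """
    ion_plans = [
        IonPlan("M1", 5, "OP2"),
        IonPlan("M2", 6, "OP2"),
        IonPlan("M3", 7, "OP2", bidentate_partner=8),
        IonPlan("M4", 12, "OP1"),
        IonPlan("M5", 13, "OP2", bridging_waters=2),
        IonPlan("M6", 15, "OP2"),
        IonPlan("M7", 18, "OP1"),
        IonPlan("M8", 20, "OP2"),
        IonPlan("M9", 26, "OP2"),
        IonPlan("M10", 37, "OP2", bridging_waters=1),
        IonPlan("M11", 39, "OP1"),
    ]
    ligand_plan = LigandPlan(
        u_shape_occupancy=0.777,
        switch_rate=1.0,
        carboxyl_partner_ion="M6",
        amino_acceptor=(16, "O4"),
    )
    hbond_plans = [HBondPlan(donor=(14, "N1"), hydrogen="H1", acceptor=(40, "O4"), occupancy=0.888)]
    return SyntheticSpec(
        n_nucleotides=43,
        n_ions=11,
        n_frames=n_frames,
        noise_sigma=noise_sigma,
        ion_plans=ion_plans,
        ligand_plan=ligand_plan,
        hbond_plans=hbond_plans,
        seed=seed,
    )
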