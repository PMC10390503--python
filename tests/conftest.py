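"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use plain Python loops and
scalar arithmetic so they stay independent of the vectorised library code
they are checking.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from mgshells.core import AtomRecord, Frame, Role, Topology, Trajectory

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# hand-built toy systems

def make_atom(
    name: str,
    res: int,
    res_name: str = "A",
    role: str = "rna",
    charge: float = 0.0,
    rmin: float = 1.7,
    eps: float = 0.1,
    born: float | None = 1.5,
) -> AtomRecord:
    element = "MG" if name == "MG" else ("H" if name.startswith("H") else name[0])
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_index=res,
        residue_name=res_name,
        role=Role(role),
        charge=charge,
        lj_rmin_half=rmin,
        lj_epsilon=eps,
        born_radius=born,
    )


def make_trajectory(atoms, frames_coords, box=None, times=None):
    top = Topology(atoms)
    frames = [
        Frame(coordinates=np.asarray(c, dtype=float), box=box, time=(times[i] if times else float(i)))
        for i, c in enumerate(frames_coords)
    ]
    return Trajectory(top, frames)


@pytest.fixture
def two_atom_pair():
    """One oxygen and one Mg ion at an exactly known separation, 4 frames."""
    atoms = [make_atom("OP2", 1, charge=-0.776), make_atom("MG", 2, "MG", "ion", charge=2.0)]

    def build(distance, n_frames=4, box=None):
        coords = [[[0.0, 0.0, 0.0], [distance, 0.0, 0.0]] for _ in range(n_frames)]
        return make_trajectory(atoms, coords, box=box)

    return build


# ---------------------------------------------------------------------------
# brute-force oracles

def min_image_scalar(a, b, box):
    total = 0.0
    for d in range(3):
        diff = b[d] - a[d]
        if box is not None:
            diff -= box[d] * round(diff / box[d])
        total += diff * diff
    return math.sqrt(total)


def brute_shell_assignments(traj, oxygen_idx, ion_idx, inner=2.5, outer=5.0):
    """Triple-loop shell classification; returns a set of tuples."""
    out = set()
    for f, frame in enumerate(traj.frames):
        box = None if frame.box is None else list(frame.box)
        for o in oxygen_idx:
            for i in ion_idx:
                d = min_image_scalar(frame.coordinates[o], frame.coordinates[i], box)
                if d < inner:
                    out.add((f, int(i), int(o), "inner"))
                elif d < outer:
                    out.add((f, int(i), int(o), "outer"))
    return out


def brute_fractions(traj, oxygen_idx, ion_idx, inner=2.5, outer=5.0):
    """Residue-level inner/outer frame fractions with per-frame de-duplication."""
    frames_inner: dict[int, set[int]] = {}
    frames_outer: dict[int, set[int]] = {}
    for f, frame in enumerate(traj.frames):
        box = None if frame.box is None else list(frame.box)
        for o in oxygen_idx:
            res = traj.topology.atoms[o].residue_index
            for i in ion_idx:
                d = min_image_scalar(frame.coordinates[o], frame.coordinates[i], box)
                if d < inner:
                    frames_inner.setdefault(res, set()).add(f)
                elif d < outer:
                    frames_outer.setdefault(res, set()).add(f)
    n = traj.n_frames
    result = {}
    for res_idx, _, _ in traj.topology.residues:
        result[res_idx] = (
            len(frames_inner.get(res_idx, ())) / n,
            len(frames_outer.get(res_idx, ())) / n,
        )
    return result


def brute_hbond(traj, d_idx, h_idx, a_idx, dist_cut=3.5, ang_cut=120.0):
    """Per-frame H-bond booleans by scalar arithmetic."""
    def mi_vec(a, b, box):
        out = []
        for k in range(3):
            diff = b[k] - a[k]
            if box is not None:
                diff -= box[k] * round(diff / box[k])
            out.append(diff)
        return out

    formed = []
    for frame in traj.frames:
        c = frame.coordinates
        box = None if frame.box is None else list(frame.box)
        dist = min_image_scalar(c[d_idx], c[a_idx], box)
        v1 = mi_vec(c[h_idx], c[d_idx], box)
        v2 = mi_vec(c[h_idx], c[a_idx], box)
        dot = sum(x * y for x, y in zip(v1, v2))
        n1 = math.sqrt(sum(x * x for x in v1))
        n2 = math.sqrt(sum(x * x for x in v2))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))
        formed.append(dist < dist_cut and ang > ang_cut)
    return formed


def brute_energy(traj, rna_idx, lig_idx, window, ke=332.0637, eps_in=1.0, eps_w=78.5):
    """Double-loop per-residue Coulomb + LJ + GB cross energies, frame-averaged."""
    top = traj.topology
    residues = sorted({top.atoms[i].residue_index for i in rna_idx})
    sums = {res: [0.0, 0.0, 0.0] for res in residues}
    frames = range(*window)
    for f in frames:
        c = traj.frames[f].coordinates
        for i in rna_idx:
            ai = top.atoms[i]
            res = ai.residue_index
            for j in lig_idx:
                aj = top.atoms[j]
                r = math.dist(c[i], c[j])
                e_c = ke * ai.charge * aj.charge / (eps_in * r)
                rmin = ai.lj_rmin_half + aj.lj_rmin_half
                eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                x6 = (rmin / r) ** 6
                e_v = eps * (x6 * x6 - 2 * x6)
                aa = ai.born_radius * aj.born_radius
                fgb = math.sqrt(r * r + aa * math.exp(-r * r / (4 * aa)))
                e_g = -ke * (1 / eps_in - 1 / eps_w) * ai.charge * aj.charge / fgb
                sums[res][0] += e_c
                sums[res][1] += e_v
                sums[res][2] += e_g
    n = len(list(frames))
    return {res: tuple(v / n for v in s) for res, s in sums.items()}


def classify_ion_frames(assignments, ion_atom, n_frames):
    """Per-frame ion label (inner/outer/bulk) from a list of shell assignments."""
    labels = ["bulk"] * n_frames
    for a in assignments:
        if a.ion != ion_atom:
            continue
        if a.shell == "inner":
            labels[a.frame] = "inner"
        elif labels[a.frame] == "bulk":
            labels[a.frame] = "outer"
    return labels
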