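"""Per-nucleotide ligand interaction-energy decomposition.

For every frame in an analysis window and every RNA residue, the
residue-ligand interaction energy is the pairwise sum over (residue atom,
ligand atom) pairs of three terms:

* Coulomb:  ``k_e q_i q_j / (eps_in r)`` with ``k_e`` = 332.0637
  kcal A / (mol e^2);
* Lennard-Jones 12-6: ``eps_ij [(rmin_ij/r)^12 - 2 (rmin_ij/r)^6]`` with
  the Lorentz-Berthelot-style combining rules ``rmin_ij = rmin_i/2 +
  rmin_j/2`` and ``eps_ij = sqrt(eps_i eps_j)``;
* generalized-Born polar-screening cross term:
  ``-k_e (1/eps_in - 1/eps_w) q_i q_j / f_GB`` with
  ``f_GB = sqrt(r^2 + a_i a_j exp(-r^2 / (4 a_i a_j)))``.

Born radii are fixed per-atom inputs from the parameter table (no per-frame
effective-radii integration and no nonpolar surface term); the result is an
interaction-energy decomposition, not a binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Role, Trajectory, as_indices

__all__ = [
    "COULOMB_CONSTANT",
    "GBSettings",
    "EnergyDecomposition",
    "coulomb_energy",
    "lj_energy",
    "gb_cross_energy",
    "per_residue_interaction",
    "combine_decompositions",
    "call_major_nucleotides",
    "profile_correlation",
    "block_convergence",
]

COULOMB_CONSTANT = 332.0637  # kcal A / (mol e^2)


@dataclass
class GBSettings:
    """Dielectric model for the generalized-Born screening term."""

    epsilon_interior: float = 1.0
    epsilon_solvent: float = 78.5
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not self.epsilon_solvent > self.epsilon_interior >= 1.0:
            raise ValueError("need eps_solvent > eps_interior >= 1")

    @property
    def screening_prefactor(self) -> float:
        return self.coulomb_constant * (1.0 / self.epsilon_interior - 1.0 / self.epsilon_solvent)


@dataclass
class EnergyDecomposition:
    """Per-residue mean/SD of E_coul, E_vdw, dG_GB and their total (kcal/mol).

    ``per_residue`` columns: residue, e_coul, e_vdw, e_gb, total, sd.  ``sd``
    is over frames for a single trajectory and across replicates when
    decompositions are combined.
    """

    per_residue: pd.DataFrame
    window: str = ""
    n_replicates: int = 1

    def total(self, residue: int) -> float:
        row = self.per_residue[self.per_residue["residue"] == residue]
        if row.empty:
            raise KeyError(f"no residue {residue} in decomposition")
        return float(row.iloc[0]["total"])


def coulomb_energy(q1: float, q2: float, r: float, epsilon: float = 1.0) -> float:
    """Point-charge Coulomb energy, kcal/mol (charges in e, r in A)."""
    if r <= 0:
        raise ValueError("r must be positive")
    return COULOMB_CONSTANT * q1 * q2 / (epsilon * r)


def lj_energy(rmin: float, eps_lj: float, r: float) -> float:
    """12-6 Lennard-Jones energy; minimum of depth -eps_lj at r = rmin."""
    if r <= 0:
        raise ValueError("r must be positive")
    x6 = (rmin / r) ** 6
    return eps_lj * (x6 * x6 - 2.0 * x6)


def f_gb(r, alpha_i, alpha_j):
    """Generalized-Born effective distance: smoothly bridges alpha (r=0) and r."""
    aa = alpha_i * alpha_j
    r2 = np.square(r)
    return np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))


def gb_cross_energy(
    charges: np.ndarray,
    coords: np.ndarray,
    born_radii: np.ndarray,
    settings: GBSettings,
    group_a,
    group_b,
) -> float:
    """Cross-group GB polar-solvation screening energy (kcal/mol).

    ``dG = -k_e (1/eps_in - 1/eps_w) sum_{i in A, j in B} q_i q_j / f_GB``.
    Born radii are inputs; a missing (NaN) radius in either group raises.
    """
    ia, ib = as_indices(group_a), as_indices(group_b)
    alpha_a = np.asarray(born_radii, dtype=float)[ia]
    alpha_b = np.asarray(born_radii, dtype=float)[ib]
    if np.any(~(alpha_a > 0)) or np.any(~(alpha_b > 0)):
        raise ValueError("all atoms in both groups need a positive Born radius")
    qa = np.asarray(charges, dtype=float)[ia]
    qb = np.asarray(charges, dtype=float)[ib]
    xyz = np.asarray(coords, dtype=float)
    r = np.linalg.norm(xyz[ia][:, None, :] - xyz[ib][None, :, :], axis=2)
    f = f_gb(r, alpha_a[:, None], alpha_b[None, :])
    return float(-settings.screening_prefactor * np.sum(qa[:, None] * qb[None, :] / f))


def _single_trajectory_decomposition(
    traj: Trajectory,
    ligand_idx: np.ndarray,
    window: tuple[int, int],
    settings: GBSettings,
    cutoff: float | None,
    chunk: int,
) -> pd.DataFrame:
    top = traj.topology
    rna_idx = np.array([i for i, a in enumerate(top.atoms) if a.role is Role.RNA], dtype=int)
    if np.intersect1d(rna_idx, ligand_idx).size:
        raise ValueError("ligand selection overlaps RNA residues")
    start, stop = window
    frames = np.arange(traj.n_frames)[start:stop]
    if frames.size == 0:
        raise ValueError("empty analysis window")
    q = top.charges
    rmin_ij = top.lj_rmin_half[rna_idx][:, None] + top.lj_rmin_half[ligand_idx][None, :]
    eps_ij = np.sqrt(top.lj_epsilon[rna_idx][:, None] * top.lj_epsilon[ligand_idx][None, :])
    qq = q[rna_idx][:, None] * q[ligand_idx][None, :]
    alpha = top.born_radii
    if np.any(np.isnan(alpha[rna_idx])) or np.any(np.isnan(alpha[ligand_idx])):
        raise ValueError("Born radius missing for an atom in the interaction groups")
    aa = alpha[rna_idx][:, None] * alpha[ligand_idx][None, :]
    residues = sorted({top.atoms[i].residue_index for i in rna_idx})
    res_of = top.residue_of_atom[rna_idx]
    res_pos = {res: k for k, res in enumerate(residues)}
    row_group = np.array([res_pos[r] for r in res_of])
    coords = traj.coords()
    n_res = len(residues)
    acc = np.zeros((3, frames.size, n_res))  # coul, vdw, gb per frame per residue
    ke = settings.coulomb_constant
    pref = settings.screening_prefactor
    for c0 in range(0, frames.size, chunk):
        f_chunk = frames[c0 : c0 + chunk]
        pa = coords[f_chunk][:, rna_idx, :]
        pb = coords[f_chunk][:, ligand_idx, :]
        r = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=3)
        with np.errstate(divide="ignore"):
            e_coul = ke * qq / (settings.epsilon_interior * r)
            x6 = (rmin_ij / r) ** 6
        e_vdw = eps_ij * (x6 * x6 - 2.0 * x6)
        e_gb = -pref * qq / np.sqrt(r**2 + aa * np.exp(-(r**2) / (4.0 * aa)))
        if cutoff is not None:
            mask = r <= cutoff
            e_coul = np.where(mask, e_coul, 0.0)
            e_vdw = np.where(mask, e_vdw, 0.0)
            e_gb = np.where(mask, e_gb, 0.0)
        for t, e in enumerate((e_coul, e_vdw, e_gb)):
            per_atom = e.sum(axis=2)  # (C, A)
            for k in range(n_res):
                acc[t, c0 : c0 + f_chunk.size, k] = per_atom[:, row_group == k].sum(axis=1)
    total = acc.sum(axis=0)  # (F, n_res)
    return pd.DataFrame(
        {
            "residue": residues,
            "e_coul": acc[0].mean(axis=0),
            "e_vdw": acc[1].mean(axis=0),
            "e_gb": acc[2].mean(axis=0),
            "total": total.mean(axis=0),
            "sd": total.std(axis=0, ddof=0),
        }
    )


def per_residue_interaction(
    traj: Trajectory | Sequence[Trajectory],
    ligand,
    window: tuple[int, int] | None = None,
    settings: GBSettings | None = None,
    cutoff: float | None = None,
    chunk: int = 200,
) -> EnergyDecomposition:
    """Per-residue RNA-ligand interaction energies over a frame window.

    The window defaults to the second half of the trajectory, mirroring the
    convention of analysing equilibrated production frames.  Passing a list
    of trajectories averages within each first and then across replicates
    (replicate SD reported).
    """
    settings = settings or GBSettings()
    if not isinstance(traj, Trajectory):
        decomps = [
            per_residue_interaction(t, ligand, window, settings, cutoff, chunk) for t in traj
        ]
        return combine_decompositions(decomps)
    lig_idx = as_indices(ligand)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    if window is None:
        window = (traj.n_frames // 2, traj.n_frames)
    table = _single_trajectory_decomposition(traj, lig_idx, window, settings, cutoff, chunk)
    return EnergyDecomposition(
        per_residue=table, window=f"frames [{window[0]}, {window[1]})", n_replicates=1
    )


def combine_decompositions(decomps: Sequence[EnergyDecomposition]) -> EnergyDecomposition:
    """Mean across replicate decompositions; SD of the per-replicate totals."""
    if not decomps:
        raise ValueError("no decompositions to combine")
    base = decomps[0].per_residue["residue"]
    stacked = {
        col: np.stack([d.per_residue[col].to_numpy() for d in decomps])
        for col in ("e_coul", "e_vdw", "e_gb", "total")
    }
    out = pd.DataFrame({"residue": base})
    for col, arr in stacked.items():
        out[col] = arr.mean(axis=0)
    out["sd"] = (
        stacked["total"].std(axis=0, ddof=1) if len(decomps) > 1 else decomps[0].per_residue["sd"]
    )
    return EnergyDecomposition(
        per_residue=out,
        window=decomps[0].window,
        n_replicates=sum(d.n_replicates for d in decomps),
    )


def call_major_nucleotides(
    decomp: EnergyDecomposition, threshold: float = -2.0
) -> list[int]:
    """Residues whose mean total interaction energy lies below the threshold.

    -2.0 kcal/mol is the conventional line separating pocket-lining
    nucleotides from the rest of the profile; results are sorted from most
    to least favourable.
    """
    table = decomp.per_residue
    hits = table[table["total"] < threshold].sort_values("total")
    return [int(r) for r in hits["residue"]]


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson correlation between two paired per-residue energy profiles."""
    a = np.asarray(profile_a, dtype=float).ravel()
    b = np.asarray(profile_b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("profiles must be paired and of length >= 3")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class BlockConvergence:
    """Contiguous-block means of a series and their maximum pairwise spread."""

    block_means: np.ndarray
    max_deviation: float
    block_length: int


def block_convergence(series, n_blocks: int = 4) -> BlockConvergence:
    """Split a per-frame series into equal contiguous blocks and compare means.

    The maximum absolute difference between any two block means is the
    convergence diagnostic (0 for a converged, stationary series in the
    limit of long blocks).  Trailing frames that do not fill a block are
    dropped.
    """
    values = np.asarray(series, dtype=float).ravel()
    if values.size < n_blocks:
        raise ValueError(f"need at least {n_blocks} frames for {n_blocks} blocks")
    block_len = values.size // n_blocks
    used = values[: block_len * n_blocks].reshape(n_blocks, block_len)
    means = used.mean(axis=1)
    dev = float(np.max(np.abs(means[:, None] - means[None, :])))
    return BlockConvergence(block_means=means, max_deviation=dev, block_length=block_len)
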