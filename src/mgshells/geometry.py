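"""Geometric order parameters, hydrogen bonds, superposition, RMSF and ion
density grids.

Order parameters are named scalar per-frame observables (groove-width type
P-P distances, pocket-center distances, ligand-carboxyl-ion distances,
base-pair donor-acceptor distances).  A hydrogen bond requires
donor-acceptor distance < 3.5 A and a donor-H-acceptor angle (measured at
the hydrogen) > 120 degrees.  RMSF uses iterative least-squares alignment
to a converged mean structure.  Densities are binned in the aligned
reference frame and can be written as OpenDX grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Selection, Trajectory, as_indices

__all__ = [
    "OrderParameterSeries",
    "HBondSeries",
    "FlexibilityProfile",
    "DensityGrid",
    "distance_series",
    "min_group_distance",
    "carboxyl_ion_distance",
    "pocket_center_distance",
    "hbond_fraction",
    "basepair_donor_acceptor_distances",
    "superpose",
    "rmsf_profile",
    "ion_density",
]

HBOND_DISTANCE = 3.5  # A, donor-acceptor heavy-atom cutoff
HBOND_ANGLE = 120.0  # degrees, donor-H-acceptor


@dataclass
class OrderParameterSeries:
    """A named per-frame scalar observable with its summary statistics."""

    name: str
    values: np.ndarray  # per frame, A
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, edges) with uniform ``bin_width`` bins; mass = n_frames."""
        lo = np.floor(self.values.min() / self.bin_width) * self.bin_width
        hi = np.ceil(self.values.max() / self.bin_width) * self.bin_width
        if hi <= lo:
            hi = lo + self.bin_width
        edges = np.arange(lo, hi + self.bin_width / 2, self.bin_width)
        counts, _ = np.histogram(self.values, bins=edges)
        return counts, edges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)), self.name: self.values})


@dataclass
class HBondSeries:
    """Per-frame hydrogen-bond formation for one donor/hydrogen/acceptor triple."""

    donor: int
    hydrogen: int
    acceptor: int
    formed: np.ndarray  # bool per frame
    distances: np.ndarray  # donor-acceptor, A
    angles: np.ndarray  # donor-H-acceptor, degrees

    @property
    def fraction(self) -> float:
        return float(np.mean(self.formed))


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (quadratic mean over each residue's measured atoms)."""

    per_residue: pd.DataFrame  # residue, rmsf
    per_atom: pd.DataFrame  # atom, rmsf
    n_iterations: int


@dataclass
class DensityGrid:
    """3D occupancy counts of ion positions on a regular grid."""

    origin: np.ndarray  # A
    spacing: float  # A
    counts: np.ndarray  # (nx, ny, nz)
    n_events: int  # (frame, ion) events inside the grid

    def to_dx(self, path) -> None:
        """Write as an OpenDX scalar field."""
        from gridData import Grid

        edges = [
            self.origin[d] + self.spacing * np.arange(self.counts.shape[d] + 1)
            for d in range(3)
        ]
        Grid(self.counts.astype(float), edges=edges).export(str(path), file_format="dx")


def _resolve_points(traj: Trajectory, sel, weighting: str = "mass") -> np.ndarray:
    """One point per frame from a selection: the atom, or a center rule."""
    idx = as_indices(sel)
    coords = traj.coords()
    if idx.size == 1:
        return coords[:, idx[0], :]
    if weighting == "mass":
        w = traj.topology.masses()[idx]
    elif weighting == "geometric":
        w = np.ones(idx.size)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return np.einsum("fas,a->fs", coords[:, idx, :], w)


def _frame_distances(traj: Trajectory, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    boxes = traj.boxes()
    out = np.empty(traj.n_frames)
    diffs = pb - pa
    if boxes is not None:
        diffs = diffs - boxes * np.round(diffs / boxes)
    return np.linalg.norm(diffs, axis=1)


def distance_series(
    traj: Trajectory,
    a,
    b,
    name: str = "d",
    weighting: str = "mass",
    bin_width: float = 0.1,
) -> OrderParameterSeries:
    """Per-frame minimum-image distance between two points.

    Each side is a single atom or a multi-atom selection reduced to its
    (mass- or geometrically-weighted) center.
    """
    pa = _resolve_points(traj, a, weighting)
    pb = _resolve_points(traj, b, weighting)
    return OrderParameterSeries(name=name, values=_frame_distances(traj, pa, pb), bin_width=bin_width)


def min_group_distance(
    traj: Trajectory, group1, group2, name: str = "d_min", bin_width: float = 0.1
) -> OrderParameterSeries:
    """Per-frame minimum distance over all cross pairs of two atom groups."""
    i1, i2 = as_indices(group1), as_indices(group2)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both groups must be non-empty")
    from .core import pair_distances

    d = pair_distances(traj.coords(), i1, i2, traj.boxes())
    return OrderParameterSeries(name=name, values=d.min(axis=(1, 2)), bin_width=bin_width)


def carboxyl_ion_distance(
    traj: Trajectory,
    carboxyl_oxygens,
    ion,
    name: str = "d_carboxyl",
    outer_window: tuple[float, float] = (2.5, 5.0),
) -> tuple[OrderParameterSeries, float]:
    """Shorter of the two carboxyl-oxygen-to-ion distances, per frame.

    Returns the series plus the fraction of frames in the outer-shell
    window ``[2.5, 5.0)``.
    """
    o_idx = as_indices(carboxyl_oxygens)
    if o_idx.size != 2:
        raise ValueError("carboxyl selection must contain exactly two oxygen atoms")
    from .core import pair_distances

    d = pair_distances(traj.coords(), o_idx, as_indices(ion), traj.boxes())
    values = d.min(axis=(1, 2))
    series = OrderParameterSeries(name=name, values=values)
    lo, hi = outer_window
    fraction = float(np.mean((values >= lo) & (values < hi)))
    return series, fraction


def pocket_center_distance(
    traj: Trajectory,
    pocket_bases,
    probe_base,
    name: str = "d_pk",
    weighting: str = "mass",
) -> OrderParameterSeries:
    """Distance between the pocket-base center and the probe-base center.

    Centers are mass-weighted by default (geometric available via
    ``weighting``); restrict both selections to nucleobase heavy atoms.
    """
    return distance_series(traj, pocket_bases, probe_base, name=name, weighting=weighting)


def hbond_fraction(
    traj: Trajectory,
    donor: int,
    hydrogen: int,
    acceptor: int,
    distance_cutoff: float = HBOND_DISTANCE,
    angle_cutoff: float = HBOND_ANGLE,
) -> HBondSeries:
    """Hydrogen-bond booleans per frame: d(D,A) < 3.5 A and D-H-A angle > 120 deg."""
    d_idx = int(as_indices(donor)[0])
    h_idx = int(as_indices(hydrogen)[0])
    a_idx = int(as_indices(acceptor)[0])
    if traj.topology.atoms[h_idx].element.upper() != "H":
        raise ValueError("hydrogen index does not point at a hydrogen atom")
    coords = traj.coords()
    boxes = traj.boxes()
    da = coords[:, a_idx] - coords[:, d_idx]
    hd = coords[:, d_idx] - coords[:, h_idx]
    ha = coords[:, a_idx] - coords[:, h_idx]
    if boxes is not None:
        da = da - boxes * np.round(da / boxes)
        hd = hd - boxes * np.round(hd / boxes)
        ha = ha - boxes * np.round(ha / boxes)
    distances = np.linalg.norm(da, axis=1)
    cosang = np.einsum("fs,fs->f", hd, ha) / (
        np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    formed = (distances < distance_cutoff) & (angles > angle_cutoff)
    return HBondSeries(
        donor=d_idx, hydrogen=h_idx, acceptor=a_idx, formed=formed, distances=distances, angles=angles
    )


def basepair_donor_acceptor_distances(
    traj: Trajectory, pairs: list[tuple[int, int]], name_prefix: str = "d"
) -> list[OrderParameterSeries]:
    """Heavy-atom donor-acceptor distance series for base-pair partner atoms."""
    out = []
    coords = traj.coords()
    boxes = traj.boxes()
    for d_idx, a_idx in pairs:
        diff = coords[:, a_idx] - coords[:, d_idx]
        if boxes is not None:
            diff = diff - boxes * np.round(diff / boxes)
        top = traj.topology
        name = (
            f"{name_prefix}_{top.atoms[d_idx].atom_name}{top.atoms[d_idx].residue_index}"
            f"-{top.atoms[a_idx].atom_name}{top.atoms[a_idx].residue_index}"
        )
        out.append(OrderParameterSeries(name=name, values=np.linalg.norm(diff, axis=1)))
    return out


def superpose(
    mobile: np.ndarray, reference: np.ndarray, align_set=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch, SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    ``align_set`` atoms (all atoms when None); ``rmsd`` is over the align
    set after fitting.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(mobile.shape[0]) if align_set is None else as_indices(align_set)
    if idx.size < 3:
        raise ValueError("need at least 3 alignment atoms")
    m = mobile[idx]
    r = reference[idx]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, trans, rmsd


def _apply(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def _iterative_mean_structure(
    coords: np.ndarray, align_idx: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> tuple[np.ndarray, int]:
    """Align all frames to a mean structure, recompute, repeat to convergence."""
    aligned = coords.copy()
    mean = aligned.mean(axis=0)
    for iteration in range(1, max_iter + 1):
        for f in range(aligned.shape[0]):
            rot, trans, _ = superpose(aligned[f], mean, align_idx)
            aligned[f] = _apply(aligned[f], rot, trans)
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return aligned, iteration


def rmsf_profile(
    traj: Trajectory,
    align_set,
    measure_sets: dict[int, "Selection | np.ndarray | list[int]"],
    tol: float = 1e-6,
    max_iter: int = 50,
) -> FlexibilityProfile:
    """Root-mean-square fluctuations after removing rigid-body motion.

    Frames are iteratively aligned on ``align_set`` (typically backbone
    atoms with flexible regions masked out) to a converged average
    structure; RMSF is then computed per measured atom and aggregated per
    residue as the quadratic mean over its ``measure_sets`` atoms.
    """
    align_idx = as_indices(align_set)
    aligned, n_iter = _iterative_mean_structure(traj.coords(), align_idx, tol, max_iter)
    mean = aligned.mean(axis=0)
    sq_dev = np.sum((aligned - mean) ** 2, axis=2)  # (F, N)
    per_atom_msf = sq_dev.mean(axis=0)  # (N,)
    atom_rows = []
    res_rows = []
    for residue, sel in sorted(measure_sets.items()):
        idx = as_indices(sel)
        for i in idx:
            atom_rows.append({"atom": int(i), "rmsf": float(np.sqrt(per_atom_msf[i]))})
        res_rows.append(
            {"residue": residue, "rmsf": float(np.sqrt(per_atom_msf[idx].mean()))}
        )
    return FlexibilityProfile(
        per_residue=pd.DataFrame(res_rows),
        per_atom=pd.DataFrame(atom_rows),
        n_iterations=n_iter,
    )


def ion_density(
    traj: Trajectory,
    ions,
    align_set,
    reference: np.ndarray | None = None,
    spacing: float = 0.5,
    padding: float = 2.0,
) -> DensityGrid:
    """Occupancy counts of ion positions on a grid in the aligned frame.

    Every frame is superposed onto ``reference`` (the first frame when
    None) using ``align_set``; ion positions are then binned.  The grid
    covers all aligned ion positions plus ``padding``, so the total count
    equals n_frames x n_ions.
    """
    i_idx = as_indices(ions)
    align_idx = as_indices(align_set)
    coords = traj.coords()
    ref = coords[0] if reference is None else np.asarray(reference, dtype=float)
    positions = np.empty((traj.n_frames, i_idx.size, 3))
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(coords[f], ref, align_idx)
        positions[f] = _apply(coords[f, i_idx], rot, trans)
    flat = positions.reshape(-1, 3)
    lo = flat.min(axis=0) - padding
    hi = flat.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    bins = (flat - lo) / spacing
    ijk = np.minimum(bins.astype(int), shape - 1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)
    return DensityGrid(origin=lo, spacing=spacing, counts=counts, n_events=flat.shape[0])
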