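"""Ion shell analysis: RDFs, inner/outer classification, coordination
fractions, persistent site identification, bidentate and water-bridged
coordination, and OP1/OP2 preference statistics.

Shell conventions: the inner shell is ``d < inner_cutoff`` (strict) and the
outer shell is ``inner_cutoff <= d < outer_cutoff``, so the two classes
partition ``[0, outer_cutoff)``.  The default cutoffs of 2.5 and 5.0 A sit
in the valleys around the first-shell (~2.0 A) and second-shell (~4.3 A)
peaks of the Mg2+-phosphate-oxygen radial distribution function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Selection, Topology, Trajectory, as_indices, pair_distances

__all__ = [
    "RDFResult",
    "ShellAssignment",
    "CoordinationProfile",
    "IonSite",
    "CutoffSuggestion",
    "compute_rdf",
    "suggest_cutoffs",
    "assign_shells",
    "coordination_fractions",
    "op2_op1_preference",
    "identify_ion_sites",
    "detect_bridging_waters",
]

INNER_CUTOFF = 2.5
OUTER_CUTOFF = 5.0


@dataclass
class RDFResult:
    """Radial distribution function of ions around a set of center atoms."""

    center_atom_label: str
    bin_edges: np.ndarray  # length n_bins + 1, uniform width
    g: np.ndarray  # dimensionless, per bin
    counts: np.ndarray  # raw ion tallies per bin (summed over frames/centers)
    n_frames: int
    n_centers: int = 1
    ion_density: float = 0.0  # ions per A^3 used for normalisation

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def expected_counts(self) -> np.ndarray:
        """Uniform-density expectation per bin (same scale as ``counts``)."""
        shell_vol = 4.0 * np.pi * self.r_mid**2 * self.bin_width
        return self.ion_density * shell_vol * self.n_frames * self.n_centers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_mid": self.r_mid, "g": self.g, "counts": self.counts})


@dataclass(slots=True)
class ShellAssignment:
    """One (frame, ion, coordinated atom) contact within the outer cutoff."""

    frame: int
    ion: int  # 0-based atom index of the ion
    atom: int  # 0-based atom index of the coordinated atom
    shell: str  # 'inner' | 'outer'
    distance: float


@dataclass
class CoordinationProfile:
    """Per-residue fractions of frames with inner/outer-shell coordination.

    ``per_residue`` columns: residue, inner, outer (and inner_sd/outer_sd
    when multiple trajectories were combined).
    """

    per_residue: pd.DataFrame
    n_trajectories: int = 1

    def fraction(self, residue: int, shell: str = "inner") -> float:
        row = self.per_residue[self.per_residue["residue"] == residue]
        if row.empty:
            return 0.0
        return float(row.iloc[0][shell])


@dataclass
class IonSite:
    """A persistent coordination site of one ion.

    Partner lists hold ``(residue, atom_name, frame_fraction)`` tuples;
    ``stable`` means the dominant inner partner is present in at least the
    stability threshold fraction of frames; ``bidentate`` means two
    adjacent-residue inner partners co-occur in at least half the frames.
    """

    label: str
    ion: int
    inner_partners: list[tuple[int, str, float]]
    outer_partners: list[tuple[int, str, float]]
    stable: bool
    bidentate: bool

    @property
    def dominant_residue(self) -> int:
        return max(self.inner_partners, key=lambda p: p[2])[0]


class CutoffSuggestion(NamedTuple):
    inner_cutoff: float
    outer_cutoff: float
    fallback: bool  # True when the RDF peaks could not be resolved


def compute_rdf(
    traj: Trajectory,
    centers: Selection,
    ions: Selection,
    bin_width: float = 0.05,
    r_max: float = 10.0,
    label: str = "",
) -> RDFResult:
    """g(r) of ions around center atoms, normalised to uniform ion density.

    ``g(r) = <count in bin> / (rho_ion * 4 pi r_mid^2 dr)`` averaged over
    frames and centers, with ``rho_ion = n_ions / box volume``.  Raw counts
    are kept alongside, so Poisson uncertainty bands can be formed.
    """
    c_idx, i_idx = as_indices(centers), as_indices(ions)
    if c_idx.size == 0 or i_idx.size == 0:
        raise ValueError("empty selection")
    boxes = traj.boxes()
    if boxes is None:
        raise ValueError("RDF normalisation requires a periodic box on every frame")
    coords = traj.coords()
    dists = pair_distances(coords, c_idx, i_idx, boxes)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(dists.ravel(), bins=edges)
    volume = float(np.mean(np.prod(boxes, axis=1)))
    rho = i_idx.size / volume
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * r_mid**2 * bin_width
    norm = rho * shell_vol * traj.n_frames * c_idx.size
    g = counts / norm
    return RDFResult(
        center_atom_label=label or "+".join(sorted({traj.topology.atoms[i].atom_name for i in c_idx})),
        bin_edges=edges,
        g=g,
        counts=counts.astype(float),
        n_frames=traj.n_frames,
        n_centers=int(c_idx.size),
        ion_density=rho,
    )


def _plateau_center(segment: np.ndarray, tol_frac: float = 1e-6) -> int:
    """Index of the middle of the minimal plateau of a 1D segment."""
    mmin = segment.min()
    tol = tol_frac * max(segment.max(), 1.0)
    low = np.nonzero(segment <= mmin + tol)[0]
    return int(low[len(low) // 2])


def suggest_cutoffs(
    rdf: RDFResult,
    prominence: float = 1.0,
    defaults: tuple[float, float] = (INNER_CUTOFF, OUTER_CUTOFF),
) -> CutoffSuggestion:
    """Shell cutoffs from RDF structure.

    The inner cutoff is placed in the middle of the g-minimum plateau
    between the first two peaks (so it falls well inside the gap even when
    the gap is wide and flat); the outer cutoff where g falls to its
    minimum after the second peak.  When fewer than two peaks stand out
    above the absolute ``prominence`` floor (in g units), the defaults are
    returned with ``fallback=True``.
    """
    g, r = rdf.g, rdf.r_mid
    peaks, _ = find_peaks(g, prominence=prominence)
    if len(peaks) < 2:
        return CutoffSuggestion(defaults[0], defaults[1], True)
    p1, p2 = peaks[0], peaks[1]
    valley = p1 + _plateau_center(g[p1 : p2 + 1])
    after = p2 + 1
    end = peaks[2] if len(peaks) > 2 else len(g)
    if after >= end:
        return CutoffSuggestion(float(r[valley]), defaults[1], True)
    outer = after + _plateau_center(g[after:end])
    return CutoffSuggestion(float(r[valley]), float(r[outer]), False)


def assign_shells(
    traj: Trajectory,
    phosphate_oxygens: Selection,
    ions: Selection,
    inner_cutoff: float = INNER_CUTOFF,
    outer_cutoff: float = OUTER_CUTOFF,
) -> list[ShellAssignment]:
    """All (frame, ion, oxygen) contacts within the outer cutoff.

    Inner: ``d < inner_cutoff``; outer: ``inner_cutoff <= d < outer_cutoff``.
    """
    if not 0 < inner_cutoff < outer_cutoff:
        raise ValueError("need 0 < inner_cutoff < outer_cutoff")
    o_idx, i_idx = as_indices(phosphate_oxygens), as_indices(ions)
    coords = traj.coords()
    boxes = traj.boxes()
    dists = pair_distances(coords, o_idx, i_idx, boxes)  # (F, O, I)
    f_sel, o_sel, i_sel = np.nonzero(dists < outer_cutoff)
    d_sel = dists[f_sel, o_sel, i_sel]
    inner = d_sel < inner_cutoff
    return [
        ShellAssignment(
            frame=int(f),
            ion=int(i_idx[i]),
            atom=int(o_idx[o]),
            shell="inner" if isin else "outer",
            distance=float(d),
        )
        for f, o, i, d, isin in zip(f_sel, o_sel, i_sel, d_sel, inner)
    ]


def _fraction_table(
    assignments: Sequence[ShellAssignment], topology: Topology, n_frames: int
) -> pd.DataFrame:
    """Residue-level fractions with per-frame de-duplication.

    A residue counts once per frame per shell class no matter how many of
    its oxygens or how many ions participate.
    """
    residues = [idx for idx, _, _ in topology.residues]
    seen: dict[str, set[tuple[int, int]]] = {"inner": set(), "outer": set()}
    for a in assignments:
        seen[a.shell].add((a.frame, int(topology.atoms[a.atom].residue_index)))
    rows = []
    for res in residues:
        rows.append(
            {
                "residue": res,
                "inner": sum(1 for f, r in seen["inner"] if r == res) / n_frames,
                "outer": sum(1 for f, r in seen["outer"] if r == res) / n_frames,
            }
        )
    return pd.DataFrame(rows)


def coordination_fractions(
    assignments: Sequence[ShellAssignment] | Sequence[Sequence[ShellAssignment]],
    topology: Topology,
    n_frames: int | Sequence[int],
) -> CoordinationProfile:
    """Per-residue inner/outer coordination fractions.

    Pass a list of assignment lists (with matching ``n_frames`` list) to get
    the mean and standard deviation across replicate trajectories.
    """
    multi = (
        len(assignments) > 0
        and not isinstance(assignments[0], ShellAssignment)
    ) or (len(assignments) == 0 and not isinstance(n_frames, int))
    if not multi:
        table = _fraction_table(assignments, topology, int(n_frames))
        return CoordinationProfile(per_residue=table, n_trajectories=1)
    n_frames_list = list(n_frames) if not isinstance(n_frames, int) else [n_frames] * len(assignments)
    tables = [
        _fraction_table(a, topology, nf) for a, nf in zip(assignments, n_frames_list)
    ]
    stacked_inner = np.stack([t["inner"].to_numpy() for t in tables])
    stacked_outer = np.stack([t["outer"].to_numpy() for t in tables])
    out = tables[0][["residue"]].copy()
    out["inner"] = stacked_inner.mean(axis=0)
    out["outer"] = stacked_outer.mean(axis=0)
    out["inner_sd"] = stacked_inner.std(axis=0, ddof=1) if len(tables) > 1 else 0.0
    out["outer_sd"] = stacked_outer.std(axis=0, ddof=1) if len(tables) > 1 else 0.0
    return CoordinationProfile(per_residue=out, n_trajectories=len(tables))


@dataclass
class PreferenceResult:
    """OP2:OP1 inner-shell preference (frame-count ratio)."""

    global_ratio: float  # inf flagged via op1_zero
    per_residue: pd.DataFrame  # residue, op1_count, op2_count, ratio
    op1_zero: bool


def op2_op1_preference(
    assignments: Sequence[ShellAssignment], topology: Topology
) -> PreferenceResult:
    """Ratio of inner-shell frame counts through OP2 versus OP1."""
    inner = [a for a in assignments if a.shell == "inner"]
    if not inner:
        raise ValueError("no inner-shell assignments")
    counts: dict[int, dict[str, int]] = {}
    for a in inner:
        atom = topology.atoms[a.atom]
        if atom.atom_name not in ("OP1", "OP2"):
            continue
        counts.setdefault(atom.residue_index, {"OP1": 0, "OP2": 0})[atom.atom_name] += 1
    rows = []
    total = {"OP1": 0, "OP2": 0}
    for res in sorted(counts):
        c1, c2 = counts[res]["OP1"], counts[res]["OP2"]
        total["OP1"] += c1
        total["OP2"] += c2
        rows.append(
            {
                "residue": res,
                "op1_count": c1,
                "op2_count": c2,
                "ratio": (c2 / c1) if c1 else np.inf,
            }
        )
    op1_zero = total["OP1"] == 0
    ratio = np.inf if op1_zero else total["OP2"] / total["OP1"]
    return PreferenceResult(
        global_ratio=float(ratio),
        per_residue=pd.DataFrame(rows, columns=["residue", "op1_count", "op2_count", "ratio"]),
        op1_zero=op1_zero,
    )


def identify_ion_sites(
    traj: Trajectory,
    assignments: Sequence[ShellAssignment],
    stability_threshold: float = 0.99,
    bidentate_threshold: float = 0.5,
) -> list[IonSite]:
    """Persistent coordination sites, one per ion with any inner contact.

    Sites are labelled M1, M2, ... in ascending order of the dominant inner
    partner's residue number (ties broken by ion atom index), which makes
    the labels invariant under frame reordering.
    """
    top = traj.topology
    n_frames = traj.n_frames
    by_ion: dict[int, list[ShellAssignment]] = {}
    for a in assignments:
        by_ion.setdefault(a.ion, []).append(a)
    prelim = []
    for ion, ion_assignments in by_ion.items():
        frames_by_partner: dict[str, dict[tuple[int, str], set[int]]] = {
            "inner": {},
            "outer": {},
        }
        for a in ion_assignments:
            atom = top.atoms[a.atom]
            key = (atom.residue_index, atom.atom_name)
            frames_by_partner[a.shell].setdefault(key, set()).add(a.frame)
        if not frames_by_partner["inner"]:
            continue
        inner_partners = sorted(
            [(res, name, len(fr) / n_frames) for (res, name), fr in frames_by_partner["inner"].items()],
            key=lambda p: (p[0], p[1]),
        )
        outer_partners = sorted(
            [(res, name, len(fr) / n_frames) for (res, name), fr in frames_by_partner["outer"].items()],
            key=lambda p: (p[0], p[1]),
        )
        dominant_fraction = max(p[2] for p in inner_partners)
        dominant_residue = min(res for res, _, fr in inner_partners if fr == dominant_fraction)
        stable = dominant_fraction >= stability_threshold
        bidentate = _is_bidentate(frames_by_partner["inner"], n_frames, bidentate_threshold)
        prelim.append((dominant_residue, ion, inner_partners, outer_partners, stable, bidentate))
    prelim.sort(key=lambda t: (t[0], t[1]))
    return [
        IonSite(
            label=f"M{k + 1}",
            ion=ion,
            inner_partners=inner_partners,
            outer_partners=outer_partners,
            stable=stable,
            bidentate=bidentate,
        )
        for k, (_, ion, inner_partners, outer_partners, stable, bidentate) in enumerate(prelim)
    ]


def _is_bidentate(
    inner_frames: dict[tuple[int, str], set[int]], n_frames: int, threshold: float
) -> bool:
    """Two inner partners on adjacent residues co-occurring in >= threshold frames."""
    by_residue: dict[int, set[int]] = {}
    for (res, _), frames in inner_frames.items():
        by_residue.setdefault(res, set()).update(frames)
    residues = sorted(by_residue)
    for r1 in residues:
        for r2 in residues:
            if r2 - r1 == 1:
                co = len(by_residue[r1] & by_residue[r2]) / n_frames
                if co >= threshold:
                    return True
    return False


def detect_bridging_waters(
    traj: Trajectory,
    site: IonSite,
    waters: Selection,
    adjacent_phosphates: Selection,
    inner_cutoff: float = INNER_CUTOFF,
    hbond_distance: float = 3.5,
) -> pd.DataFrame:
    """Per-frame bridging-water report for one ion site.

    A water bridges when its oxygen is within ``inner_cutoff`` of the site's
    ion AND within ``hbond_distance`` of an OP1/OP2 in
    ``adjacent_phosphates``.  The criterion is distance-only so that
    hydrogen-free water models can be analysed.  Columns: frame,
    n_bridging, reaches_op1, reaches_op2.
    """
    top = traj.topology
    w_idx = np.array(
        [i for i in as_indices(waters) if top.atoms[i].element.upper() == "O"], dtype=int
    )
    if w_idx.size == 0:
        raise ValueError("no water oxygen atoms in selection")
    p_idx = as_indices(adjacent_phosphates)
    p_names = [top.atoms[i].atom_name for i in p_idx]
    coords = traj.coords()
    boxes = traj.boxes()
    d_ion = pair_distances(coords, np.array([site.ion]), w_idx, boxes)[:, 0, :]  # (F, W)
    d_phos = pair_distances(coords, w_idx, p_idx, boxes)  # (F, W, P)
    near_ion = d_ion < inner_cutoff
    near_op = d_phos < hbond_distance  # (F, W, P)
    is_op1 = np.array([n == "OP1" for n in p_names])
    is_op2 = np.array([n == "OP2" for n in p_names])
    bridges = near_ion[:, :, None] & near_op  # (F, W, P)
    bridging_water = bridges.any(axis=2)  # (F, W)
    rows = {
        "frame": np.arange(traj.n_frames),
        "n_bridging": bridging_water.sum(axis=1),
        "reaches_op1": bridges[:, :, is_op1].any(axis=(1, 2)) if is_op1.any() else np.zeros(traj.n_frames, bool),
        "reaches_op2": bridges[:, :, is_op2].any(axis=(1, 2)) if is_op2.any() else np.zeros(traj.n_frames, bool),
    }
    return pd.DataFrame(rows)
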