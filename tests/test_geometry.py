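"""Order parameters, H-bonds, superposition, RMSF and density grids."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mgshells.core import Selection
from mgshells.geometry import (
    basepair_donor_acceptor_distances,
    carboxyl_ion_distance,
    distance_series,
    hbond_fraction,
    ion_density,
    min_group_distance,
    pocket_center_distance,
    rmsf_profile,
    superpose,
)

from conftest import brute_hbond, make_atom, make_trajectory


# ---------------------------------------------------------------------------
# distance series

def test_distance_series_fixed_and_identical():
    atoms = [make_atom("P", 1), make_atom("P", 2)]
    traj = make_trajectory(atoms, [[[0, 0, 0], [10.9, 0, 0]]] * 5)
    s = distance_series(traj, Selection([0]), Selection([1]), name="d_P1-P2")
    assert s.mean == pytest.approx(10.9)
    assert s.sd == 0.0
    same = distance_series(traj, Selection([0]), Selection([0]))
    assert np.all(same.values == 0.0)


def test_histogram_mass_and_mean_consistency():
    rng = np.random.default_rng(5)
    atoms = [make_atom("P", 1), make_atom("P", 2)]
    coords = np.zeros((200, 2, 3))
    coords[:, 1, 0] = 10 + rng.normal(0, 0.4, 200)
    traj = make_trajectory(atoms, coords)
    s = distance_series(traj, Selection([0]), Selection([1]))
    counts, edges = s.histogram()
    assert counts.sum() == 200
    mids = 0.5 * (edges[:-1] + edges[1:])
    hist_mean = float(np.sum(mids * counts) / counts.sum())
    assert hist_mean == pytest.approx(s.mean, abs=s.bin_width)


def test_distance_series_translation_rotation_invariant():
    """Box-free series are unchanged by a global rigid motion of every frame."""
    rng = np.random.default_rng(11)
    atoms = [make_atom("P", 1), make_atom("OP1", 1), make_atom("P", 2)]
    coords = rng.normal(0, 3, size=(10, 3, 3))
    traj = make_trajectory(atoms, coords)
    s1 = distance_series(traj, Selection([0, 1]), Selection([2]))
    theta = 0.7
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    moved = make_trajectory(atoms, coords @ rot.T + np.array([5.0, -3.0, 2.0]))
    s2 = distance_series(moved, Selection([0, 1]), Selection([2]))
    np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)


def test_min_group_distance_reduction_and_hand_values():
    atoms = [make_atom("MG", i, "MG", "ion") for i in range(1, 5)]
    coords = [[[0, 0, 0], [1, 0, 0], [4, 0, 0], [0, 7, 0]]]
    traj = make_trajectory(atoms, coords)
    pair = min_group_distance(traj, Selection([0]), Selection([2]))
    direct = distance_series(traj, Selection([0]), Selection([2]))
    assert pair.values[0] == pytest.approx(direct.values[0])
    # 2x2 groups: min of the four hand-computed cross distances
    g = min_group_distance(traj, Selection([0, 1]), Selection([2, 3]))
    assert g.values[0] == pytest.approx(3.0)  # (1,0,0)-(4,0,0)
    # adding a far ion never increases the minimum
    g2 = min_group_distance(traj, Selection([0, 1]), Selection([2, 3, 0]))
    assert g2.values[0] <= g.values[0]


def test_carboxyl_ion_distance_window():
    atoms = [
        make_atom("OC1", 1, "SAM", "ligand"),
        make_atom("OC2", 1, "SAM", "ligand"),
        make_atom("MG", 2, "MG", "ion"),
    ]
    near = make_trajectory(atoms, [[[3, 0, 0], [6, 0, 0], [0, 0, 0]]])
    series, frac = carboxyl_ion_distance(near, Selection([0, 1]), Selection([2]))
    assert series.values[0] == pytest.approx(3.0)
    assert frac == 1.0
    far = make_trajectory(atoms, [[[5.5, 0, 0], [7, 0, 0], [0, 0, 0]]])
    _, frac_far = carboxyl_ion_distance(far, Selection([0, 1]), Selection([2]))
    assert frac_far == 0.0
    with pytest.raises(ValueError, match="two oxygen"):
        carboxyl_ion_distance(near, Selection([0]), Selection([2]))


def test_pocket_center_distance_constructed_offsets():
    """Probe at the constructed center -> 0; displaced 4.7 A -> 4.7 A."""
    pocket_atoms = [make_atom("N1", r) for r in range(1, 6)]
    probe = [make_atom("O4", 6)]
    centers = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 0]], dtype=float
    )
    center = centers.mean(axis=0)  # equal masses -> geometric center
    frames = [
        np.vstack([centers, center[None, :]]),
        np.vstack([centers, (center + [0, 0, 4.7])[None, :]]),
    ]
    traj = make_trajectory(pocket_atoms + probe, frames)
    s = pocket_center_distance(traj, Selection(range(5)), Selection([5]))
    assert s.values[0] == pytest.approx(0.0, abs=1e-12)
    assert s.values[1] == pytest.approx(4.7)


def test_two_state_pocket_distance_bimodal():
    """A 50/50 two-state probe gives a bimodal histogram at the planted offsets."""
    rng = np.random.default_rng(23)
    pocket_atoms = [make_atom("N1", r) for r in range(1, 6)] + [make_atom("O4", 6)]
    centers = rng.normal(0, 2, size=(5, 3))
    center = centers.mean(axis=0)
    n_frames = 2000
    states = rng.random(n_frames) < 0.5
    frames = []
    for in_pocket in states:
        offset = 4.7 if in_pocket else 14.4
        probe = center + np.array([0.0, 0.0, offset]) + rng.normal(0, 0.05, 3)
        frames.append(np.vstack([centers, probe[None, :]]))
    traj = make_trajectory(pocket_atoms, frames)
    s = pocket_center_distance(traj, Selection(range(5)), Selection([5]))
    counts, edges = s.histogram()
    mids = 0.5 * (edges[:-1] + edges[1:])
    near = counts[(mids > 4.2) & (mids < 5.2)].sum()
    far = counts[(mids > 13.9) & (mids < 14.9)].sum()
    assert near + far == n_frames
    # equal masses within binomial noise at 0.5 occupancy
    assert abs(near - far) < 3 * np.sqrt(n_frames * 0.25)
    # mode locations within one bin of the planted offsets
    assert abs(mids[np.argmax(counts * (mids < 10))] - 4.7) <= s.bin_width
    far_counts = np.where(mids > 10, counts, 0)
    assert abs(mids[np.argmax(far_counts)] - 14.4) <= s.bin_width


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_toy(geometries):
    """Build a donor/H/acceptor trajectory from (distance, angle_deg) pairs."""
    atoms = [make_atom("N1", 1), make_atom("H1", 1), make_atom("O4", 2)]
    frames = []
    for d, ang in geometries:
        donor = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        # acceptor at the requested donor-acceptor distance and D-H-A angle
        theta = np.radians(180.0 - ang)
        # position acceptor relative to H so that angle at H is `ang`
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # solve for acceptor on that ray with |donor-acceptor| = d
        t = np.roots(
            [1.0, 2 * np.dot(h - donor, direction), np.dot(h - donor, h - donor) - d * d]
        )
        t = float(max(t))
        frames.append(np.stack([donor, h, h + t * direction]))
    return make_trajectory(atoms, frames)


def test_hbond_distance_and_angle_criteria():
    traj = _hbond_toy([(2.9, 165.0), (2.9, 100.0), (4.0, 170.0), (3.4, 121.0)])
    hb = hbond_fraction(traj, 0, 1, 2)
    assert list(hb.formed) == [True, False, False, True]
    np.testing.assert_allclose(hb.distances, [2.9, 2.9, 4.0, 3.4], atol=1e-9)
    np.testing.assert_allclose(hb.angles, [165, 100, 170, 121], atol=1e-6)


def test_hbond_matches_manual_enumeration():
    """Five-frame toy agrees exactly with the scalar oracle."""
    traj = _hbond_toy([(2.0, 150), (3.49, 121), (3.5, 150), (2.8, 119.9), (3.0, 120.1)])
    hb = hbond_fraction(traj, 0, 1, 2)
    assert list(hb.formed) == brute_hbond(traj, 0, 1, 2)
    assert hb.fraction == pytest.approx(np.mean(brute_hbond(traj, 0, 1, 2)))


def test_hbond_requires_hydrogen():
    atoms = [make_atom("N1", 1), make_atom("C1'", 1), make_atom("O4", 2)]
    traj = make_trajectory(atoms, [np.eye(3)])
    with pytest.raises(ValueError, match="hydrogen"):
        hbond_fraction(traj, 0, 1, 2)


def test_basepair_distances_ordering():
    atoms = [make_atom("N1", 1), make_atom("O4", 2), make_atom("N1", 3), make_atom("O4", 4)]
    tight = make_trajectory(atoms, [[[0, 0, 0], [2.9, 0, 0], [0, 5, 0], [3.4, 5, 0]]] * 3)
    series = basepair_donor_acceptor_distances(tight, [(0, 1), (2, 3)])
    assert series[0].mean == pytest.approx(2.9)
    assert series[1].mean == pytest.approx(3.4)
    assert series[0].mean < series[1].mean


# ---------------------------------------------------------------------------
# superposition and RMSF

def _random_rotation(rng):
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


def test_superpose_identity_and_rotation():
    rng = np.random.default_rng(2)
    ref = rng.normal(0, 3, size=(8, 3))
    rot, trans, rmsd = superpose(ref, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
    # 90-degree rotation is removed exactly
    r90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    _, _, rmsd_rot = superpose(ref @ r90.T, ref)
    assert rmsd_rot == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_brute_force_rotation_grid():
    """Kabsch RMSD equals an exhaustive small-angle grid search to 1e-3 A."""
    rng = np.random.default_rng(4)
    ref = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4.0]])
    mobile = ref + rng.normal(0, 0.3, size=ref.shape)
    _, _, rmsd = superpose(mobile, ref)
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    best = np.inf
    angles = np.linspace(-0.35, 0.35, 29)
    for ax in angles:
        ca, sa = np.cos(ax), np.sin(ax)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        for ay in angles:
            cb, sb = np.cos(ay), np.sin(ay)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for az in angles:
                cg, sg = np.cos(az), np.sin(az)
                rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                fitted = (mobile - mc) @ (rz @ ry @ rx).T + rc
                best = min(best, float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))))
    assert rmsd <= best + 1e-9
    assert rmsd == pytest.approx(best, abs=1e-3)


@given(seed=st.integers(0, 10_000))
def test_superpose_rmsd_symmetric_nonnegative(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 2, size=(6, 3))
    b = rng.normal(0, 2, size=(6, 3))
    _, _, r_ab = superpose(a, b)
    _, _, r_ba = superpose(b, a)
    assert r_ab >= 0
    assert r_ab == pytest.approx(r_ba, abs=1e-9)


def _rigid_motion_trajectory(n_frames=12, jitter_atom=None, sigma=0.0, seed=0, loop=None):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 4, size=(10, 3))
    atoms = [make_atom("P", r) for r in range(1, 11)]
    frames = []
    for _ in range(n_frames):
        c = base.copy()
        if jitter_atom is not None:
            c[jitter_atom] += rng.normal(0, sigma, 3)
        if loop is not None:
            c[loop] += rng.normal(0, 1.0, (len(loop), 3))
        rot = _random_rotation(rng)
        frames.append(c @ rot.T + rng.normal(0, 5, 3))
    return make_trajectory(atoms, frames)


def test_rmsf_zero_under_rigid_body_motion():
    """Alignment removes global rotation+translation: RMSF < 1e-6 A."""
    traj = _rigid_motion_trajectory()
    profile = rmsf_profile(
        traj, Selection(range(10)), {r: [r - 1] for r in range(1, 11)}
    )
    assert (profile.per_residue["rmsf"] < 1e-6).all()


def test_rmsf_isotropic_jitter_closed_form():
    """One atom jittered with sigma=0.5 A has RMSF ~ sqrt(3)*0.5 A."""
    n = 4000
    traj = _rigid_motion_trajectory(n_frames=n, jitter_atom=9, sigma=0.5, seed=3)
    profile = rmsf_profile(
        traj, Selection(range(9)), {r: [r - 1] for r in range(1, 11)}
    )
    expected = np.sqrt(3) * 0.5
    # SE of the RMS of n chi-3 draws
    se = expected / np.sqrt(2 * n)
    got = float(profile.per_residue.set_index("residue").loc[10, "rmsf"])
    assert abs(got - expected) < 4 * se
    core = profile.per_residue[profile.per_residue["residue"] < 10]["rmsf"]
    assert (core < 0.05).all()


def test_rmsf_masked_loop_exceeds_core():
    """A flexible region excluded from alignment still shows elevated RMSF."""
    traj = _rigid_motion_trajectory(n_frames=60, seed=5, loop=[7, 8, 9])
    profile = rmsf_profile(
        traj, Selection(range(7)), {r: [r - 1] for r in range(1, 11)}
    )
    table = profile.per_residue.set_index("residue")["rmsf"]
    assert table.loc[8:10].min() > 5 * table.loc[1:7].max()


def test_rmsf_invariant_to_frame_order():
    traj = _rigid_motion_trajectory(n_frames=30, jitter_atom=5, sigma=0.3, seed=7)
    sel = Selection(range(4))
    measure = {r: [r - 1] for r in range(1, 11)}
    p1 = rmsf_profile(traj, sel, measure)
    order = np.random.default_rng(1).permutation(traj.n_frames)
    shuffled = make_trajectory(
        traj.topology.atoms, [traj.frames[f].coordinates for f in order]
    )
    p2 = rmsf_profile(shuffled, sel, measure)
    np.testing.assert_allclose(
        p1.per_residue["rmsf"], p2.per_residue["rmsf"], atol=1e-6
    )


# ---------------------------------------------------------------------------
# density

def test_ion_density_single_static_ion_and_conservation(tmp_path):
    atoms = [make_atom("P", 1), make_atom("P", 2), make_atom("P", 3), make_atom("MG", 4, "MG", "ion")]
    base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [1.0, 1.0, 2.0]])
    traj = make_trajectory(atoms, [base.copy() for _ in range(7)])
    grid = ion_density(traj, Selection([3]), Selection([0, 1, 2]))
    assert grid.counts.sum() == 7 == grid.n_events
    assert (grid.counts > 0).sum() == 1  # all counts in one voxel
    out = tmp_path / "d.dx"
    grid.to_dx(out)
    from gridData import Grid

    back = Grid(str(out))
    assert back.grid.sum() == pytest.approx(7.0)


def test_ion_density_two_sites():
    """Two planted sites give two disjoint density maxima at those sites."""
    rng = np.random.default_rng(9)
    atoms = [make_atom("P", r) for r in (1, 2, 3)] + [
        make_atom("MG", 4, "MG", "ion"),
        make_atom("MG", 5, "MG", "ion"),
    ]
    site_a, site_b = np.array([2.0, 2.0, 2.0]), np.array([8.0, 8.0, 8.0])
    frames = []
    for _ in range(300):
        c = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0.0], site_a, site_b])
        c[3] += rng.normal(0, 0.1, 3)
        c[4] += rng.normal(0, 0.1, 3)
        frames.append(c)
    traj = make_trajectory(atoms, frames)
    grid = ion_density(traj, Selection([3, 4]), Selection([0, 1, 2]), spacing=0.5)
    assert grid.counts.sum() == 600
    flat = np.argsort(grid.counts.ravel())[::-1]
    top_two = np.stack(np.unravel_index(flat[:2], grid.counts.shape)).T
    pos = grid.origin + (top_two + 0.5) * grid.spacing
    found = {tuple(np.round(p / 2).astype(int)) for p in pos}
    assert np.linalg.norm(pos.min(axis=0) - site_a) < 1.0
    assert np.linalg.norm(pos.max(axis=0) - site_b) < 1.0
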