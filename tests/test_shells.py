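"""Shell analysis: RDF normalisation, classification, fractions, sites."""

import numpy as np
import pytest

from mgshells.core import Role, Selection
from mgshells.shells import (
    RDFResult,
    assign_shells,
    compute_rdf,
    coordination_fractions,
    detect_bridging_waters,
    identify_ion_sites,
    op2_op1_preference,
    suggest_cutoffs,
)
from mgshells.synthetic import (
    IonPlan,
    SyntheticSpec,
    generate_trajectory,
    uniform_ion_trajectory,
)

from conftest import brute_fractions, brute_shell_assignments, make_atom, make_trajectory


# ---------------------------------------------------------------------------
# RDF

def test_rdf_single_fixed_distance_lands_in_one_bin(two_atom_pair):
    """An ion fixed at 2.02 A puts every count in the [2.00, 2.05) bin."""
    traj = two_atom_pair(2.02, n_frames=6, box=np.full(3, 30.0))
    rdf = compute_rdf(traj, Selection([0]), Selection([1]))
    hot = np.nonzero(rdf.counts)[0]
    assert len(hot) == 1
    lo, hi = rdf.bin_edges[hot[0]], rdf.bin_edges[hot[0] + 1]
    assert lo <= 2.02 < hi
    assert (lo, hi) == pytest.approx((2.0, 2.05))
    assert rdf.counts.sum() == 6


def test_rdf_counts_conserved_and_uniform_normalisation():
    """Sum of counts = pairs within r_max; uniform ions give g ~ 1."""
    traj = uniform_ion_trajectory(n_ions=60, n_frames=300, box_edge=40.0, seed=2)
    top = traj.topology
    rdf = compute_rdf(traj, top.select(atom_name="P"), top.select(role=Role.ION), r_max=10.0)
    dists = np.linalg.norm(
        traj.coords()[:, 1:, :] - traj.coords()[:, :1, :], axis=2
    )  # no wrapping needed: center sits mid-box, r_max << box/2
    assert rdf.counts.sum() == int((dists < 10.0).sum())
    band = (rdf.r_mid > 3.0) & (rdf.r_mid < 8.0)
    assert abs(float(np.mean(rdf.g[band])) - 1.0) < 0.05


def test_rdf_errors():
    traj = uniform_ion_trajectory(n_ions=5, n_frames=2)
    with pytest.raises(ValueError, match="empty"):
        compute_rdf(traj, Selection([]), Selection([1]))
    for f in traj.frames:
        f.box = None
    with pytest.raises(ValueError, match="box"):
        compute_rdf(traj, Selection([0]), Selection([1]))


def _rdf_from_g(g, bin_width=0.05):
    g = np.asarray(g, dtype=float)
    edges = np.arange(0.0, bin_width * (len(g) + 0.5), bin_width)[: len(g) + 1]
    return RDFResult("OP", edges, g, g.copy(), n_frames=1)


def test_suggest_cutoffs_flat_falls_back():
    flat = _rdf_from_g(np.ones(200) + 0.01 * np.sin(np.arange(200)))
    suggestion = suggest_cutoffs(flat)
    assert suggestion == (2.5, 5.0, True)


def test_suggest_cutoffs_two_peak_valley():
    """Valley between planted peaks is recovered at the gap's center."""
    r = np.arange(0.025, 10, 0.05)
    g = 60 * np.exp(-((r - 2.0) ** 2) / 0.02) + 20 * np.exp(-((r - 4.3) ** 2) / 0.05)
    suggestion = suggest_cutoffs(_rdf_from_g(g))
    assert not suggestion.fallback
    assert 2.3 <= suggestion.inner_cutoff <= 4.0
    # the minimum plateau of this profile is centred between the two peaks
    assert suggestion.inner_cutoff == pytest.approx(3.15, abs=0.2)


# ---------------------------------------------------------------------------
# shell assignment and fractions

@pytest.mark.parametrize("d, shell", [(2.0, "inner"), (2.49, "inner"), (2.5, "outer"), (4.3, "outer"), (4.99, "outer"), (5.0, None), (6.0, None)])
def test_assign_shells_boundaries(two_atom_pair, d, shell):
    """Strict < 2.5 inner, [2.5, 5.0) outer: an exhaustive partition."""
    traj = two_atom_pair(d, n_frames=1)
    got = assign_shells(traj, Selection([0]), Selection([1]))
    if shell is None:
        assert got == []
    else:
        assert len(got) == 1 and got[0].shell == shell
        assert got[0].distance == pytest.approx(d)


def test_coordination_fraction_hand_count():
    """Ion inner-bound to residue 1's OP2 in 3 of 4 frames -> fraction 0.75."""
    atoms = [make_atom("OP2", 1), make_atom("MG", 2, "MG", "ion")]
    coords = [[[0, 0, 0], [2.0, 0, 0]]] * 3 + [[[0, 0, 0], [8.0, 0, 0]]]
    traj = make_trajectory(atoms, coords)
    a = assign_shells(traj, Selection([0]), Selection([1]))
    profile = coordination_fractions(a, traj.topology, 4)
    assert profile.fraction(1, "inner") == pytest.approx(0.75)
    assert profile.fraction(1, "outer") == 0.0


def test_coordination_fraction_deduplicates_ions_and_atoms():
    """Two ions (and both OPs) inner-bound to one residue count once per frame."""
    atoms = [
        make_atom("OP1", 1),
        make_atom("OP2", 1),
        make_atom("MG", 2, "MG", "ion"),
        make_atom("MG", 3, "MG", "ion"),
    ]
    coords = [[[0, 0, 0], [0.5, 0, 0], [2.0, 0, 0], [-2.0, 0, 0]]]
    traj = make_trajectory(atoms, coords)
    a = assign_shells(traj, Selection([0, 1]), Selection([2, 3]))
    profile = coordination_fractions(a, traj.topology, 1)
    assert profile.fraction(1, "inner") == 1.0


def test_coordination_fraction_multi_trajectory_mean_sd():
    atoms = [make_atom("OP2", 1), make_atom("MG", 2, "MG", "ion")]
    near = make_trajectory(atoms, [[[0, 0, 0], [2.0, 0, 0]]] * 2)
    far = make_trajectory(atoms, [[[0, 0, 0], [9.0, 0, 0]]] * 2)
    lists = [assign_shells(t, Selection([0]), Selection([1])) for t in (near, far)]
    profile = coordination_fractions(lists, near.topology, [2, 2])
    row = profile.per_residue.iloc[0]
    assert row["inner"] == pytest.approx(0.5)
    assert row["inner_sd"] == pytest.approx(np.std([1.0, 0.0], ddof=1))
    assert profile.n_trajectories == 2


def test_fractions_match_brute_force_oracle():
    """Vectorised fractions equal a scalar all-pairs scan on a random system."""
    rng = np.random.default_rng(17)
    atoms = []
    for res in range(1, 6):
        atoms += [make_atom("OP1", res), make_atom("OP2", res)]
    for k in range(3):
        atoms.append(make_atom("MG", 6 + k, "MG", "ion"))
    coords = rng.uniform(0, 15, size=(12, len(atoms), 3))
    traj = make_trajectory(atoms, coords, box=np.full(3, 15.0))
    oxy = traj.topology.select(atom_name=["OP1", "OP2"])
    ions = traj.topology.select(role=Role.ION)
    profile = coordination_fractions(
        assign_shells(traj, oxy, ions), traj.topology, traj.n_frames
    )
    expected = brute_fractions(traj, oxy.indices, ions.indices)
    for res, (inner, outer) in expected.items():
        assert profile.fraction(res, "inner") == pytest.approx(inner)
        assert profile.fraction(res, "outer") == pytest.approx(outer)


# ---------------------------------------------------------------------------
# OP2:OP1 preference

def test_op_preference_planted_ratio():
    """Planted OP2:OP1 occupancies 0.6:0.3 give a ratio near 2."""
    spec = SyntheticSpec(
        n_nucleotides=8,
        n_frames=4000,
        noise_sigma=0.02,
        ion_plans=[
            IonPlan("A", 2, "OP2", occupancy=0.6),
            IonPlan("B", 6, "OP1", occupancy=0.3),
        ],
        seed=13,
    )
    traj, _ = generate_trajectory(spec)
    top = traj.topology
    a = assign_shells(traj, top.select(atom_name=["OP1", "OP2"]), top.select(role=Role.ION))
    pref = op2_op1_preference(a, top)
    assert not pref.op1_zero
    assert pref.global_ratio == pytest.approx(2.0, rel=0.15)
    assert 1.3 <= pref.global_ratio <= 3.0


def test_op_preference_symmetric_and_zero_cases(two_atom_pair):
    atoms = [
        make_atom("OP1", 1),
        make_atom("OP2", 2),
        make_atom("MG", 3, "MG", "ion"),
        make_atom("MG", 4, "MG", "ion"),
    ]
    coords = [[[0, 0, 0], [10, 0, 0], [2.0, 0, 0], [12.0, 0, 0]]] * 5
    traj = make_trajectory(atoms, coords)
    a = assign_shells(traj, Selection([0, 1]), Selection([2, 3]))
    pref = op2_op1_preference(a, traj.topology)
    assert pref.global_ratio == pytest.approx(1.0)
    # OP2-only coordination flags an infinite ratio
    traj2 = two_atom_pair(2.0)
    a2 = assign_shells(traj2, Selection([0]), Selection([1]))
    pref2 = op2_op1_preference(a2, traj2.topology)
    assert pref2.op1_zero and np.isinf(pref2.global_ratio)


# ---------------------------------------------------------------------------
# ion sites

def _site_fixture(n_frames=50, seed=0, noise=0.0):
    spec = SyntheticSpec(
        n_nucleotides=10,
        n_ions=4,  # one extra bulk-only ion
        n_frames=n_frames,
        noise_sigma=noise,
        ion_plans=[
            IonPlan("BI", 3, "OP2", bidentate_partner=4),
            IonPlan("MONO", 7, "OP1"),
            IonPlan("PART", 9, "OP2", occupancy=0.6),
        ],
        seed=seed,
    )
    return generate_trajectory(spec)


def test_identify_sites_bidentate_mono_and_bulk():
    traj, _ = _site_fixture()
    top = traj.topology
    a = assign_shells(traj, top.select(atom_name=["OP1", "OP2"]), top.select(role=Role.ION))
    sites = identify_ion_sites(traj, a)
    # bulk-only ion emits no site
    assert len(sites) == 3
    by_res = {s.dominant_residue: s for s in sites}
    assert by_res[3].bidentate and by_res[3].stable
    assert not by_res[7].bidentate and by_res[7].stable
    assert not by_res[9].stable  # 0.6 occupancy < 0.99 threshold
    # labels ordered by dominant partner residue
    assert [s.label for s in sites] == ["M1", "M2", "M3"]
    assert [s.dominant_residue for s in sites] == [3, 7, 9]


def test_site_labels_invariant_under_frame_reordering():
    traj, _ = _site_fixture(seed=6)
    top = traj.topology
    oxy, ions = top.select(atom_name=["OP1", "OP2"]), top.select(role=Role.ION)
    sites = identify_ion_sites(traj, assign_shells(traj, oxy, ions))
    rng = np.random.default_rng(0)
    order = rng.permutation(traj.n_frames)
    from mgshells.core import Frame, Trajectory

    shuffled = Trajectory(
        top,
        [
            Frame(traj.frames[f].coordinates, traj.frames[f].box, time=float(k))
            for k, f in enumerate(order)
        ],
    )
    sites2 = identify_ion_sites(shuffled, assign_shells(shuffled, oxy, ions))
    assert [(s.label, s.ion, s.dominant_residue) for s in sites] == [
        (s.label, s.ion, s.dominant_residue) for s in sites2
    ]


def test_detect_bridging_waters_counts():
    """Two planted bridges every frame reach both OP1 and OP2; none after removal."""
    spec = SyntheticSpec(
        n_nucleotides=6,
        n_frames=20,
        noise_sigma=0.0,
        ion_plans=[IonPlan("M1", 2, "OP2", bridging_waters=2)],
        seed=1,
    )
    traj, _ = generate_trajectory(spec)
    top = traj.topology
    oxy, ions = top.select(atom_name=["OP1", "OP2"]), top.select(role=Role.ION)
    sites = identify_ion_sites(traj, assign_shells(traj, oxy, ions))
    waters = top.select(role=Role.WATER)
    adj = top.select(residue=3, atom_name=["OP1", "OP2"])
    report = detect_bridging_waters(traj, sites[0], waters, adj)
    assert (report["n_bridging"] == 2).all()
    assert report["reaches_op1"].all() and report["reaches_op2"].all()
    # a far-away phosphate has no bridges
    far = top.select(residue=6, atom_name=["OP1", "OP2"])
    report_far = detect_bridging_waters(traj, sites[0], waters, far)
    assert (report_far["n_bridging"] == 0).all()


def test_detect_single_bridge():
    spec = SyntheticSpec(
        n_nucleotides=6,
        n_frames=10,
        noise_sigma=0.0,
        ion_plans=[IonPlan("M1", 2, "OP2", bridging_waters=1)],
        seed=1,
    )
    traj, _ = generate_trajectory(spec)
    top = traj.topology
    sites = identify_ion_sites(
        traj,
        assign_shells(traj, top.select(atom_name=["OP1", "OP2"]), top.select(role=Role.ION)),
    )
    report = detect_bridging_waters(
        traj, sites[0], top.select(role=Role.WATER), top.select(residue=3, atom_name=["OP1", "OP2"])
    )
    assert (report["n_bridging"] == 1).all()


def test_shell_assignments_match_brute_force():
    rng = np.random.default_rng(3)
    atoms = [make_atom(n, r) for r in (1, 2) for n in ("OP1", "OP2")] + [
        make_atom("MG", 3, "MG", "ion"),
        make_atom("MG", 4, "MG", "ion"),
    ]
    coords = rng.uniform(0, 12, size=(8, len(atoms), 3))
    traj = make_trajectory(atoms, coords, box=np.full(3, 12.0))
    oxy = traj.topology.select(atom_name=["OP1", "OP2"])
    ions = traj.topology.select(role=Role.ION)
    got = {
        (a.frame, a.ion, a.atom, a.shell)
        for a in assign_shells(traj, oxy, ions)
    }
    assert got == brute_shell_assignments(traj, oxy.indices, ions.indices)
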