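# mgshells

Mg²⁺ coordination and conformational analysis of RNA molecular-dynamics
trajectories.

Divalent magnesium is the "dark" metal ion of RNA structural biology: it is
essential for folding, ligand binding and conformational switching, yet hard
to resolve experimentally (it is isoelectronic with Na⁺ and water in X-ray
maps, and nearly silent in NMR). MD simulations can place Mg²⁺ ions
explicitly, but extracting *where* and *how* ions coordinate from microsecond
trajectories requires a stack of careful geometric and energetic analyses.
`mgshells` packages that stack for riboswitch-scale RNA systems:

- **Radial distribution functions** g(r) of Mg²⁺ around RNA oxygen/nitrogen
  atoms (0.05 Å bins, uniform-density normalisation), and data-driven shell
  cutoffs read off the valley between the first-shell (~2.0 Å) and
  second-shell (~4.3 Å) peaks.
- **Inner/outer-shell classification** of every (frame, ion, phosphate-oxygen)
  contact: inner for d < 2.5 Å, outer for 2.5 Å ≤ d < 5 Å, a strict partition.
- **Per-nucleotide coordination fractions** (fraction of frames in which a
  residue's OP1/OP2 coordinates any ion, counted once per frame per residue),
  OP2:OP1 preference ratios, and replicate mean ± SD.
- **Persistent ion sites** (M1, M2, …): per-ion partner phosphates with frame
  fractions, stability flags, bidentate detection (one ion chelating two
  adjacent phosphates), and bridging-water reports (a first-shell water within
  3.5 Å of an adjacent phosphate oxygen).
- **Order parameters and hydrogen bonds**: named per-frame distances (groove
  widths such as d_P6-P14, backbone spans such as d_P38-P40, binding-pocket
  distances d_pk-B37, ligand-carboxyl–ion distances with outer-shell
  fractions), and H-bonds by the standard d(D,A) < 3.5 Å ∧ ∠(D-H-A) > 120°
  criterion.
- **RMSF profiles** after iterative Kabsch alignment to a converged average
  structure, and **ion density grids** in the aligned frame (OpenDX output).
- **Per-nucleotide ligand interaction energies**: for each residue i,
  E_i = Σ_pairs [ k_e q_a q_b / r + ε_ab((r_min/r)¹² − 2(r_min/r)⁶)
  − k_e (1/ε_in − 1/ε_w) q_a q_b / f_GB(r) ],
  with f_GB = √(r² + α_a α_b e^{−r²/4α_aα_b}) — a fixed-Born-radii
  generalized-Born screening of the Coulomb term — plus major-nucleotide
  calling at the conventional −2 kcal/mol line, replicate Pearson
  correlations, and 4-block convergence diagnostics.

Because real microsecond trajectories are not shippable, the package includes
a first-class **synthetic trajectory generator**: a seedable pseudo-RNA helix
with phosphate and base atoms, ions planted at inner/outer-shell distances
with configurable per-frame occupancies, bridging waters, a two-state (U/L)
ligand, and explicit hydrogen-bond plans — all with exported ground-truth
labels, so every analysis can be validated against what was planted.

## Worked example

Run the full pipeline on the default synthetic system (43 nucleotides, 11
planted inner-shell ions, a planted 88.8%-occupancy hydrogen bond and a
77.7%-occupancy carboxyl–ion outer-shell contact):

```sh
mgshells all --seed 4 --n-frames 500 --out demo_out
```

prints (to standard error):

```
synthetic fixture: 43 nt, 11 ions, 500 frames, seed 4
planted inner-shell site count: 11
rdf cutoff suggestion: inner 2.48 A, outer 3.12 A
OP2:OP1 inner-shell preference: 3.00
recovered ion sites: 11 (11 stable)
hbond 14:N1->40:O4: fraction 0.8920
order parameter d_P6-P14: mean 25.94 A, sd 0.07 A
order parameter d_P38-P40: mean 11.41 A, sd 0.07 A
ligand carboxyl outer-shell fraction with M6: 0.7960
ion density grid: (58, 37, 195) voxels, 5500 events
major nucleotides (< -2.0 kcal/mol): none
block convergence of d_P6-P14: max deviation 0.0128 A over 4 blocks
```

Reading this: all 11 planted inner-shell sites are recovered as stable sites
(dominant partner present in ≥ 99% of frames); the suggested inner cutoff
2.48 Å sits in the RDF valley between the planted 2.0 Å and ~2.9 Å
populations; the measured hydrogen-bond fraction 0.892 and carboxyl
outer-shell fraction 0.796 recover the planted occupancies 0.888 and 0.777
to within binomial sampling error at 500 frames; and the 8:3 planted
OP2:OP1 site split appears as a 3.0 contact ratio (the bidentate site
contributes a second OP2 contact). Tables (`rdf.tsv`, `fractions.tsv`,
`sites.tsv`, `hbonds.tsv`, `order_params.tsv`, `energy.tsv`, …) and an
OpenDX density grid land in `demo_out/`; each carries a header comment with
the package version, config hash and seed.

The same pipeline runs on file inputs:

```sh
mgshells all --topology topology.pdb --traj traj.pdb --params params.tsv --out out
```

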