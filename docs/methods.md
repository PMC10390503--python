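# Methods

## Scope and model

`mgshells` analyses Mg²⁺–RNA coordination and the associated conformational
observables in MD trajectories. It does not run dynamics: inputs are a
topology (atom names, residues, roles, nonbonded parameters) and an ordered
set of coordinate frames with orthorhombic periodic boxes. All distance
arithmetic uses the minimum-image convention for orthorhombic cells; general
triclinic cells (e.g. truncated-octahedron boxes) are out of scope, and
trajectories produced in such cells must be re-imaged before analysis.

Atom roles are derived from residue names (metals → ion, water models →
water, SAM/SAH/LIG/UNL → ligand, everything else → RNA). Indexing is
0-based internally; user-facing residue numbers are 1-based serial, matching
conventional RNA nucleotide numbering.

## Shell analysis

**RDF.** g(r) of ions around a center selection uses uniform bins (default
width 0.05 Å, r_max 10 Å) and ideal-gas normalisation
g(r) = ⟨count⟩ / (ρ 4π r² Δr), ρ = n_ions / ⟨box volume⟩, averaged over
frames and centers. Raw counts are retained so Poisson uncertainty bands
can be formed (σ = √expected per bin). Centers may be pooled by atom name
across residues or restricted per residue.

**Cutoffs.** The default shell cutoffs are 2.5 Å (inner) and 5.0 Å (outer),
the canonical positions of the valleys around the ~2.0 Å first-shell and
~4.3 Å second-shell peaks of Mg²⁺–phosphate-oxygen RDFs. `suggest_cutoffs`
reads them off a computed RDF: peaks are detected with an absolute
prominence floor (default 1.0 in g units; the literature states no floor,
so this is a package choice), the inner cutoff is placed at the *center of
the minimum plateau* between the first two peaks (a wide empty gap should
put the cutoff well inside the gap, not at its first touching bin), and the
outer cutoff at the minimum after the second peak. Unresolvable peak
structure returns the defaults with a `fallback` flag.

**Classification.** Inner shell is d < 2.5 Å strictly; outer shell is
2.5 Å ≤ d < 5.0 Å. Half-open intervals make the classes a partition of
[0, 5) — an atom pair is never counted in both shells.

**Coordination fractions.** A residue counts once per frame per shell class
regardless of how many of its oxygens or how many ions participate
(residue-level de-duplication; whether published per-nucleotide fractions
counted OP1/OP2 jointly is generally unstated — joint counting was chosen).
Replicate trajectories are combined as mean ± SD across replicates.

**Ion sites.** Ions are tracked by atom identity. Each ion with any
inner-shell contact becomes a site; partners carry frame fractions; a site
is *stable* when its dominant inner partner is present in ≥ 99% of frames
(threshold configurable; 0.99 rather than 1.0 to tolerate single-frame
jitter) and *bidentate* when inner partners on adjacent residues co-occur
in ≥ 50% of frames (the literature gives no co-occurrence threshold;
majority rule chosen, configurable). Sites are labelled M1, M2, … by the
dominant partner's residue number, which makes labels invariant under frame
reordering. Ion exchange at a site would appear as two sites — a documented
limitation (stable sites in the target systems show no exchange).

**Bridging waters.** A water bridges an ion to an adjacent phosphate when
its oxygen is within the inner cutoff of the ion and within 3.5 Å of that
phosphate's OP1/OP2. The criterion is distance-only so hydrogen-free water
models can be analysed; an angular criterion would require water hydrogens.

## Geometry

Order parameters are per-frame scalars with mean, SD and a histogram
(default bin width 0.1 Å — unstated in the literature, package choice).
Multi-atom sides of a distance are reduced to mass-weighted centers
(geometric weighting by flag); the binding-pocket center is the
mass-weighted center of the pocket bases' heavy atoms. Hydrogen bonds use
d(donor, acceptor) < 3.5 Å and donor–H–acceptor angle > 120°, the angle
measured at the hydrogen (the standard convention). H-bond analysis
requires hydrogens; topologies lacking them fail at the operation, not at
I/O.

Superposition is least-squares rigid-body fitting via the Kabsch SVD
construction with a determinant correction against improper rotations.
RMSF iterates (align all frames to the mean structure on the alignment
set, recompute the mean) until the mean shifts < 10⁻⁶ Å or 50 iterations;
per-residue values are the quadratic mean over the residue's measured
atoms. The alignment set should exclude flexible regions (mask
configurable) — excluded residues are still measured. Ion densities are
binned on a regular grid (default 0.5 Å spacing) after superposing each
frame onto a reference on the same alignment set; counts are conserved and
the grid exports as OpenDX.

## Energetics

Per-nucleotide ligand interaction energies sum, over all (residue atom,
ligand atom) pairs and all frames of the analysis window:

- Coulomb k_e q_i q_j / (ε_in r), k_e = 332.0637 kcal·Å/(mol·e²), ε_in = 1;
- 12-6 Lennard-Jones with r_min,ij = r_min,i/2 + r_min,j/2 and
  ε_ij = √(ε_i ε_j);
- the pairwise generalized-Born cross term
  −k_e (1/ε_in − 1/ε_w) q_i q_j / f_GB, ε_w = 78.5,
  f_GB = √(r² + α_i α_j exp(−r²/4α_iα_j)).

Born radii α are fixed per-atom inputs from the parameter table. This is a
deliberate simplification of full MM/GBSA machinery: no per-frame effective
Born-radii integration and no nonpolar surface-area term. The decomposition
structure (Coulomb + vdW + polar screening, per residue, per frame, summed
exactly into the total) is preserved and fully testable, but absolute
energies depend on the GB variant and radii set and are not comparable
across parameterisations. No nonbonded cutoff is applied by default
(desk-scale systems); a cutoff is available for large inputs. The analysis
window defaults to the second half of the trajectory (the convention of
analysing equilibrated production frames); averaging is within-trajectory
first, then across replicates with the replicate SD. Major nucleotides are
those with mean total below −2.0 kcal/mol, the conventional line separating
pocket-lining residues in interaction-energy profiles. Convergence is
diagnosed by comparing means over 4 equal contiguous blocks.

With the toy parameter set of the synthetic fixture, GB screening cancels
most of the direct Coulomb term (as it should for solvent-exposed polar
contacts), so per-residue totals are modest (|E| ≲ 1.5 kcal/mol) and the
default fixture yields no residues below the −2.0 kcal/mol line; the
machinery (thresholding, sorting, correlations) is exercised by tests with
constructed profiles.

## Synthetic data: what it emulates, and what it does not

The generator builds a helix-like pseudo-RNA (radius 9 Å, rise 2.81 Å,
5.9 Å P–P spacing) whose per-nucleotide roster is exactly the atoms the
analyses consume: P, OP1, OP2, O3′, O5′, C1′ and a 3-atom pseudo-base (one
donor with hydrogen, one acceptor). There is no sugar pucker, no base
stacking, no realistic torsions — only the inter-atom distances and angles
that the analysis mathematics reads are controlled. Consequently, passing
tests demonstrate the *analysis* is correct (classification, counting,
normalisation, alignment, energy summation), not that any biological
conclusion transfers; real trajectories additionally contain correlated
motions, ion exchange, wrapped molecules and solvent structure that the
fixtures do not model.

Planted features, all driven by one seeded generator (identical specs give
bit-identical trajectories):

- **Ions**: per-frame Bernoulli occupancy of an inner (default 2.0 Å) or
  outer (default 4.3 Å) mode at a target OP1/OP2; otherwise bulk, sampled
  uniformly but rejected within 6 Å of the chain so bulk ions never
  contaminate shell statistics. Bidentate plans tilt the two target oxygens
  of adjacent residues toward a shared outward midpoint so a single ion can
  sit at the inner distance from both — deliberately non-realistic geometry
  in service of a clean planted label. Bridging-water plans solve a
  two-sphere constraint so the ion is simultaneously at its mode distance
  from the target and ~4 Å from the adjacent phosphate, then interpose
  water oxygens at 2.1 Å from the ion on the ion→OP axes.
- **Ligand**: a 10-atom proxy (amino N1 with hydrogens, carboxyl O pair
  with carbon, sulfur-center and adenosyl proxies) switching between a
  bound "U" shape (amino H-bond formed at 2.9 Å; carboxyl at 3.5 Å from its
  partner ion, inside the outer-shell window) and an unbound "L" shape
  (5.5 Å / 7.2 Å) via a first-order Markov chain with specified stationary
  U-shape occupancy; switch_rate = 1 makes frames independent. Approach
  directions are chosen from a small deterministic candidate set to
  maximise clearance from the chain; clearance below 2.2 Å raises a
  placement error.
- **Hydrogen bonds**: donor and hydrogen repositioned on the donor–acceptor
  line at the bound (< 3.5 Å) or unbound (> 3.5 Å) distance per a Bernoulli
  draw.
- **Noise**: one isotropic Gaussian jitter pass (default σ = 0.05 Å) over
  all atoms, applied last.

The default study fixture is a 43-nucleotide chain with eleven
occupancy-1.0 inner-shell ions (one bidentate pair, one single-phosphate
site, sites with one and two bridging waters, an 8:3 OP2:OP1 target split),
a ligand whose carboxyl coordinates an ion in 77.7% of frames, and an
RNA–RNA hydrogen bond formed in 88.8% of frames — occupancy magnitudes in
the regime reported for Mg²⁺-saturated riboswitch systems. Its default
length is 2000 frames; parameter-recovery runs use 10 000 frames, the frame
count at which the 3-binomial-SE recovery criterion is evaluated. These
sizes keep the full validation suite in the minutes range on one CPU while
leaving sampling error well below the tested tolerances.

## Numerical choices and statistics

- Binomial recovery checks compare a recovered fraction f̂ to the planted
  occupancy p with |f̂ − p| ≤ 3√(p(1−p)/n). Across many independent checks
  a ~0.3% single-check failure rate is expected by construction, so the
  aggregate criterion is a ≥ 99% pass rate over all checks (20 seeds × 11
  checks), not all-pass.
- The ideal-gas RDF band check likewise allows the statistically expected
  number of 3σ excursions among ~100 bins (at most 2) rather than
  demanding every bin inside the band, which a correct implementation
  would fail in ~1 of 4 realisations.
- The Markov-chain conformer test inflates the binomial SE by
  (1+ρ)/(1−ρ), ρ = 1 − switch_rate, to account for autocorrelation.
- Degenerate inputs: empty selections, missing boxes (for RDF), missing
  hydrogens (for H-bonds), missing Born radii (for GB), overlapping
  RNA/ligand groups, fewer than 3 alignment atoms, and infeasible planted
  geometry all raise immediately with specific messages. An OP1 contact
  count of zero makes the OP2:OP1 ratio an explicitly flagged infinity.
- Pipeline outputs are pure functions of (inputs, config, seed): every
  table carries a version/config-hash/seed header and reruns are
  byte-identical. The output directory is excluded from the config hash.

## Known limitations

- Orthorhombic boxes only; no re-imaging of molecules split across
  boundaries (synthetic fixtures never wrap; external inputs should be
  made whole first).
- Center-of-mass reductions do not re-image group members, so groups split
  across a boundary would give wrong centers.
- Fixed Born radii mean absolute interaction energies are
  parameterisation-dependent; only profile *shapes*, differences and
  correlations should be compared across systems.
- Ion sites are keyed to ion atom identity: exchange events split sites.
- The generator's bulk-ion rejection zone (6 Å) biases bulk statistics very
  slightly away from the chain; RDF calibration therefore uses a dedicated
  ideal-gas fixture with no exclusion zone.
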