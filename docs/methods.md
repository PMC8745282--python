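# Methods

This note documents the models, conventions and numerical choices behind
kirgate, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinate and numbering conventions

All coordinates are in Å.  The membrane normal is +Z and the membrane
plane is XY; every angular descriptor is defined against this fixed
frame (no membrane-plane estimation from lipids is attempted).  Residue
numbers follow the KirBac3.1 construct numbering (1-based) and are never
re-indexed on input.  The four chains are cyclically ordered A→B→C→D;
"chain n−1" means the previous letter with wrap-around (n−1 of A is D).
This is the convention behind the inter-chain distance names
`d46a36d, d46b36a, d46c36b, d46d36c` (residue 46 of chain n against
residue 36 of chain n−1) and `d35a167b, …` (residue 35 of n against 167
of n+1).

PDB input keeps alternate location 'A' or blank and drops the rest
(deterministic single-conformer model); HETATM records are read but
excluded from selections unless explicitly requested, because every
analysis here is protein-only.  Single-frame ensembles are written
without MODEL records for maximal interoperability.  The PDB codec is
implemented directly because the analyses need strict error reporting
(malformed records fail with a line number) and exact control of the
emitted dialect; general-purpose readers are deliberately forgiving on
both counts.

## Structural determinants

**Helix axes.** The axis of a helix is the first principal component of
its Cα coordinates, oriented from the lowest- toward the highest-numbered
residue.  PCA is standard and stable for 9–27-residue helices; the
orientation convention makes elevation angles signed and comparable
across frames.  Default helix definitions: slide 35–43, outer TM 46–71,
inner TM 109–135 (all overridable).

**Upward angle** = arcsin(axis·ẑ) in degrees, signed: 0° is in-plane,
+90° points along the membrane normal.  A *higher* value means the slide
helix lies closer to the membrane.  **Tilt angle** = arccos(|axis·ẑ|),
in [0°, 90°], i.e. the deviation of a TM helix from the membrane normal.

**Distances.** Shortest inter-residue distances minimize over the heavy-
atom cross product (synthetic and crystal structures carry no
hydrogens).  Gate apertures are the shortest distances between opposite
chains (A–C and B–D) at residues 124 and 132; a Cα-only variant is
available (`mode='ca'`) because aperture scatter plots conventionally use
Cα distances, while classification uses shortest distances.

**ASA.** Shrake–Rupley with a Fibonacci-lattice point set (default 960
points per atom), probe radius 1.4 Å, Bondi van der Waals radii with a
documented 1.7 Å fallback for unknown elements.  960 points give
VMD-comparable accuracy (isolated-sphere error < 1 %) at desk cost; the
point count is a parameter where tighter accuracy is needed.

**Correlations.** Pearson coefficients via the sample covariance;
constant columns are excluded with a warning.  Input tables accept both
the `tilt_in_a`/`tilt_out_a` names and the `inclia`/`incloa` (or
`tiltia`/`tiltoa`) aliases that circulate for the same quantities.  The
circle-matrix rendering (diameter and intensity proportional to |r|) is
a plotting convenience, not part of the numeric contract.

## Gating classification

A gate is *open* when its aperture strictly exceeds the diameter of a
non-hydrated K⁺ ion, 3.53 Å; ties classify closed (conservative reading
of "larger than").  Per frame, each gate's aperture is the minimum over
the A–C and B–D pairs, since conduction is limited by the narrowest
point; the `gate_rule='both'` flag makes the both-pairs-open convention
explicit (for positive distances it coincides with the minimum rule).
No van der Waals radius correction is subtracted before the comparison —
distances are compared to the ionic diameter directly; an optional
correction can be layered on by adjusting the threshold.

Backbone superposition uses the Kabsch closed form on matched
(chain, resid, name) atoms, N/CA/C/O by default, with the reflection
branch rejected.  For the deposited-structure check (two-chain
asymmetric units), matching runs over the shared chains as deposited; no
crystallographic symmetry expansion is applied.

## Interaction networks

Residue contacts are distance-based, with thresholds pinned for
reproducibility: hydrogen bond — donor/acceptor heavy atoms (N/O/S)
within 3.5 Å; van der Waals — side-chain heavy atoms within
r_i + r_j + 0.5 Å (Bondi); π–π — aromatic ring centroids within 6.5 Å;
π–cation — cationic-group center (Arg guanidinium / Lys NZ) to ring
centroid within 5.0 Å.  No hydrogen-geometry criterion is applied
because the inputs lack hydrogens.  Sequence-adjacent residues of a
chain are excluded by default.  Each residue pair carries at most one
edge per type (closest qualifying atom pair), stored with a canonical
residue order so that network differences are exact set operations
independent of atom ordering.  On Cα-plus-probe synthetic structures
only van der Waals edges between probe atoms are detectable; the
network tests use probe-bearing fixtures for exactly this reason.

## Excited-normal-mode sampling

The sampler is a deliberate desk-scale analogue: an anisotropic elastic
network (uniform springs, default cutoff 12 Å, spring constant
1 kcal/mol/Å², uniform 110 amu node masses) replaces all-atom normal
modes, and Langevin dynamics on the harmonic potential replaces
molecular dynamics.  Mass-weighted Hessian eigenpairs are sorted
ascending; the near-zero rigid-body modes (six for a generic network)
are detected and excluded from the internal-mode set, and more than six
near-zero modes raise a connectivity error.

*Mode selection* ranks internal modes by squared overlap of the
mass-weighted, normalized open−closed difference vector with each
eigenvector, reporting the cumulative (Bessel-bounded) contribution.
The overlap criterion is this package's pinned choice for "contribution
to gating".

*Isotropic combinations* are greedy rejection samples of unit
coefficient vectors in the selected-mode subspace with a minimum
pairwise angle of 15° (seed-controlled); if the requested count is
geometrically unreachable the partial set is returned with a warning.

*Excitation*: each replica carries one combination direction with a sign
fixed at its first excitation.  At the start of each excitation segment
a velocity increment along the direction is scaled — solving the exact
quadratic including the cross term with the instantaneous velocity — so
the kinetic-energy jump equals (3N/2)·k_B·ΔT to machine precision
(defaults: 130 replicas × 7 excitations of 1.5 ps at ΔT = 8 K).  The
integrator is BAOAB velocity-Verlet Langevin (2 fs step, friction
5 ps⁻¹, 300 K bath) in AKMA units with k_B in kcal/mol/K.

*Clustering* is leader-style on pairwise superposed RMSD (default
threshold 1.0 Å): a frame joins the first cluster whose leader it
matches, else founds one.  The representative minimizes RMSD to the
cluster's coordinate average after superposition onto the leader.
*Relaxation* runs unexcited thermostatted dynamics from each
representative and pools the final tail (default 75 %, mirroring keeping
0.3 of 0.4 ns) of the snapshots, with per-snapshot kinetic temperatures
recorded for equipartition checks.

Test and verification runs use smaller networks and shorter segments
than the defaults (tens of nodes, sub-picosecond excitations); the
defaults document the protocol's canonical shape, and the bookkeeping
(replicas × excitations, exact energy injections) is what the package
guarantees at any size.

## HDX-MS analysis

The pipeline consumes per-peptide centroid masses; everything upstream
(spectra, deconvolution) is out of scope.  Conventions, pinned because
several circulate:

* observable exchangeable amides = peptide length − 1 − internal
  prolines (the N-terminal amide back-exchanges too fast; proline has no
  amide hydrogen);
* relative uptake(t) = 100·(m(t) − m0)/D, with D the fully-deuterated
  control difference when a control exists (back-exchange-corrected,
  "normalized"), else max-exchangeable × labeling deuterium fraction
  (default 0.9, the 10× dilution into deuterated buffer);
* the per-stretch "HDX rate" is the mean relative uptake over the
  sampled time course (0.5–20 min by default).  With fast intrinsic
  kinetics this equals the plateau; with slow kinetics it is a
  time-course average — the definition is configuration-visible.

Per-residue maps weight covering peptides by 1/length (short peptides
localize better); uncovered residues are flagged missing rather than
interpolated.  Mutant−WT differences classify residues as more rigid /
more flexible / unchanged with a ±5 percentage-point tolerance, chosen
to separate reported between-condition differences from replicate-scale
noise without modeling replicate variance explicitly.  Structure
coloring writes per-residue values into B-factors with −1 as the
uncovered sentinel.

## Single-channel analysis

The software filter is a zero-phase Gaussian with −3 dB cutoff f_c
(impulse width σ_t = 0.1325/f_c; 10–90 % step rise ≈ 0.3321/f_c),
standard for single-channel work and cutoff-matched to hardware Bessel
filters.  Idealization generalizes the half-amplitude rule to multiple
levels: nearest-level assignment among baseline + k·unitary, run-length
merging, and dead-time merging (default dead time two filter rise
times) of sub-resolution segments into the neighbor with the closer
level.  Open probability is the fraction of time at any level ≥ 1, with
per-level occupancies reported for sublevel-weighted alternatives.
Amplitude histograms are all-points; level detection fits a Gaussian
mixture (EM, diagonal covariances) with the component count either
supplied or selected by BIC over 1..k_max.  Chord conductance is
g[pS] = 1000·I[pA]/V[mV], assuming reversal at 0 mV as appropriate for
symmetric KCl.

## The synthetic-data generator

`build_channel` realizes a C4 pseudo-symmetric tetramer from ideal
α-helix geometry (rise 1.5 Å, 100°/residue, Cα radius 2.3 Å): slide
helix 35–43 at a requested signed elevation, outer helix 46–71 and inner
helix 109–135 at requested tilts (inner helices at 10 Å from the pore
axis, outer at 16 Å), one pseudo side-chain probe at each gate residue
placed at half the requested aperture from the pore axis at fixed
height, and a cytoplasmic residue 167.  Because each finite ideal helix
is re-oriented so its *principal component* matches the requested axis
exactly, generator angles and descriptor angles agree by construction
(apertures to < 0.05 Å, angles to < 1°), which is what makes strict
round-trip testing possible.  An optional isotropic jitter breaks the
exact symmetry; a jitter that pushes a gate probe across the pore axis
is rejected as infeasible.

Ensembles draw each frame's state independently from a four-state
mixture and both the A–C and B–D apertures of each gate uniformly from
state-consistent intervals — open U(3.8, 8.0) Å, closed U(2.5, 3.3) Å,
keeping ≥ 0.2 Å margin from the 3.53 Å threshold so labels are
unambiguous unless a user deliberately samples near threshold.  The
study mixtures are available as presets (mutant: 7.4 / 49.3 / 32.5 /
10.8 %; wild type: 6.8 / 50.2 / 28.8 / 14.2 %).

HDX fixtures follow single-exponential kinetics toward a controllable
plateau, with the labeling deuterium fraction entering the generated
masses exactly as the analysis removes it, so noise-free fixtures
round-trip to their target; mass noise defaults to 0 Da to keep formula
tests separate from robustness tests.  Current traces are continuous-
time two-state Markov chains (several independent channels for
multi-level traces) sampled at the recording interval, with Gaussian
noise and the Gaussian low-pass applied; the generating dwell sequence
and stationary Po are kept as ground truth.

**What the generator does not emulate:** real side chains and packing,
sequence realism beyond the named residues, membranes and solvent,
correlated inter-chain motions beyond what the user imposes, HDX EX1
behavior or back-exchange kinetics, and channel gating beyond two-state
kinetics per conductance level.  Passing round-trip tests therefore
demonstrates that the *measurement pipeline* is correct and
self-consistent at realistic geometry and noise scales — not that it
would extract these quantities from experimental data of arbitrary
quality.

## Numerical choices and degenerate inputs

Ties at the gating threshold classify closed.  PCA axes of exactly
collinear point sets return the line direction.  A residue's shortest
distance to itself is 0 with a warning.  Superposition requires ≥ 3
matched atoms and always returns a proper rotation.  Eigen-solves use
LAPACK `eigh` on the symmetrized mass-weighted Hessian; rigid-mode
detection uses a 1e−9 relative threshold.  Mixture fits subsample traces
above 200,000 points.  Population reports validate that fractions sum to
100 ± 0.01.  All randomness flows through explicit integer seeds;
identical seeds give identical outputs.

## Limitations

The elastic-network sampler explores harmonic basins only; barrier
crossing enters solely through the kinetic excitations, and absolute
state populations from the sampler are not physically meaningful — the
four-state populations analyzed here are properties of the *input
ensembles*.  Contact detection without hydrogens cannot distinguish
donor from acceptor geometry.  The HDX rate definition (mean over time
points) matches a plateau only for fast kinetics.  Po counts any
above-baseline level as open with full weight; sublevel-weighted
definitions must be assembled from the reported occupancies.
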