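# Methods

This note documents the models and conventions implemented in `enzdyn`, the
numerical choices made where the design was genuinely open, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Data model and conventions

Atom indexing is 0-based internally; all user-facing residue numbers are the
1-based PDB `resSeq` values, and region tables use 1-based inclusive
intervals (multi-interval regions such as the GH-11 fingers,
`4–62, 76–95, 199–216`, are kept as interval lists).  Masses and van der
Waals radii come from a small strict element table (standard atomic weights;
Bondi radii): an element absent from the table is an error, never a guess,
because SASA correctness depends directly on the radii.  Users can extend
the table per call (`element_table=`).

Solvent is recognized by residue name (`HOH/WAT/TIP3/…`, configurable); a
ligand is any HETATM residue that is not solvent.  Hydrogens must be present
in the topology for hydrogen-bond analysis (MD systems are fully
protonated); a structure without them fails with a clear error rather than
silently inferring positions.  Hydrogen–heavy-atom attachment is resolved
from the reference geometry: each hydrogen belongs to the nearest heavy atom
of its own residue within 1.2 Å.

File I/O: PDB and DCD reading is delegated to MDAnalysis, aligned FASTA to
Biopython.  Multi-model PDB writing uses a small fixed-width formatter so
the element column and the `%8.3f` coordinate precision (1 mÅ) are exactly
controlled; round-trips through the writer reproduce coordinates to that
precision.

## Fluctuation profiles

The per-atom fluctuation is the root-mean-square deviation from the
time-average position,

    RMSF_i = sqrt( (1/n) Σ_t ‖r_i(t) − ⟨r_i⟩‖² ),

in Å.  The square root over the time average is essential: it is the only
definition with Å units that is consistent with the temperature-factor
relation `B_i = (8π²/3)·RMSF_i²` (Å²), and both are enforced as an exact
invariant of the profile type.  RMSF of 1 Å corresponds to B = 26.319 Å².

Before profiling, snapshots are least-squares fitted (Kabsch, proper
rotations only) onto the average structure; the fit-to-mean step iterates
until the mean moves by less than 1e−9 Å (a contraction, typically 2–3
rounds), which makes refitting an already-fitted trajectory a no-op to well
below 1e−8 Å.  `rmsf_profile` accepts trajectories fitted elsewhere and only
refits when fitting would still move coordinates beyond a tolerance
(default 1e−3 Å).

"Mass-weighted" is implemented as mass-weighted aggregation of the per-atom
mean-square fluctuations over each residue's N/Cα/C set,
`RMSF_res = sqrt(Σ m_i·msf_i / Σ m_i)`; the superposition itself is
unweighted.  Backbone masses are nearly equal, so the alternatives are
numerically indistinguishable; a flag (`mass_weighted=False`) switches to
the plain mean.  Residues missing a backbone atom are excluded with a
warning.  The "average B-factor" of a profile is the arithmetic mean over
residues; a per-atom mean is available via `mean_bfactor(per_atom=True)`
since either reading is defensible.

Removing the six rigid-body degrees of freedom absorbs a fraction ≈ 2/N of
each atom's variance (N = fitted atoms), i.e. a relative RMSF shortfall of
≈ 1/N.  With the 120-atom synthetic reference used in validation this is
under 1 %, well inside the 3 % recovery tolerance.

RMSD time series use the *starting structure* as reference by convention;
RMSF fitting uses the *average structure*.  The two reference labels are
carried explicitly and never conflated.  Per-region RMSD restricts the
measured atoms only — the superposition stays on the full fit selection.

Cross-enzyme profile comparison consumes a pairwise alignment (aligned
FASTA, exactly two records) and lays both B-factor profiles on alignment
columns; gap columns carry NaN so plotted curves show gaps.  The alignment
itself is an input, not computed here.

## Hydrogen bonds and salt bridges

A hydrogen bond is detected when the donor-heavy-atom to acceptor distance
is strictly below 3.0 Å and the D–H–A angle (vertex at the hydrogen)
strictly exceeds 135°.  Donors are N/O heavy atoms carrying at least one
attached hydrogen; acceptors are all N/O atoms; same-residue donor/acceptor
pairs are excluded; output order is deterministic (frame, donor, acceptor).
For counting, the bond identity is the donor-heavy-atom/acceptor pair —
rotating −NH3+ protons never multi-count.

The *static* count is total events over the trajectory divided by
(snapshots × sequence length): an intensive per-residue-per-snapshot rate.
The *dynamic* count is the number of distinct donor–acceptor residue pairs
observed in at least one snapshot, divided by sequence length.  A
seen-at-least-once count cannot meaningfully be normalized by the snapshot
number as well (it would vanish with longer sampling); the literal
additionally-by-snapshots variant is available behind a flag, and the
normalization used is recorded in the result metadata.  Enzyme–solvent
bonds count both donor directions, de-duplicated per frame.

A salt bridge is formed in a frame when the *minimum* distance between the
side-chain carboxylate oxygens of an Asp/Glu (OD1/OD2, OE1/OE2) and the
side-chain nitrogens of a Lys/Arg (NZ; NE/NH1/NH2) is at most 4.0 Å —
boundary inclusive.  Histidine can be added to the basic set via a flag but
is off by default.  Multiple O–N atom pairs of one residue pair are merged
by the minimum-distance rule.  Occupancies are percentages of sampled
frames; pairs never within the cutoff are omitted.

Ligand-contact tables report, per protein residue × subsite (the −3…+3
xylose-binding positions of a glycoside-hydrolase cleft), the percentage of
frames with at least one protein–ligand hydrogen bond.  Rows below the
reporting threshold (default 10 %) are suppressed but retained in
`all_rows`; a row at exactly the threshold is reported.  An analysis window
(`window=`) restricts the calculation to the first frames of a run.

Default sampling for interaction statistics is 1000 regularly spaced
snapshots (stride-configurable).

## Block-average standard errors

Standard errors of time-series means use the block-average method: the
series is cut into contiguous equal blocks, SE = stdev(block means)/√(blocks),
evaluated on a doubling ladder of block sizes.  The reported value is the
first size at which SE changes by less than 5 % versus the next size (the
plateau); if no plateau is reached the largest size is reported and flagged
(`converged=False`).  For iid data this reproduces sd/√n; for an AR(1)
process with φ = 0.9 it recovers the √((1+φ)/(1−φ)) inflation within the
validation tolerance.

## SASA

Solvent-accessible surface area uses the Shrake–Rupley construction: each
atom is covered with a deterministic golden-spiral lattice of 960 points at
radius r_vdw + probe (probe 1.4 Å); a point is accessible if outside every
neighbour's probe-expanded sphere, and the per-atom area is the exposed
fraction × 4π(r+probe)².  Solvent atoms are excluded from the solute by
default.  The quadrature runs in a canonical body-fixed frame (principal
axes, deterministic sign convention), so the total is exactly invariant
under rigid-body motion of the solute rather than only to quadrature
accuracy; for highly symmetric solutes whose principal axes are degenerate
this canonicalization is arbitrary-but-deterministic.  Quadrature error
versus analytic single- and two-sphere areas is below 1 %.  Trajectory mode
averages over sampled frames and attaches a block-average standard error.

## Collective motions

Cross-correlation uses Cα displacement vectors about their time mean:
`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` ∈ [−1, 1].  Atoms with zero
positional variance are masked (NaN) with a warning.  PCA diagonalizes the
3N×3N coordinate covariance of the selected atoms, with population (1/n)
normalization by default (`ddof=1` available; the difference is far below
sampling noise at realistic frame counts) and unweighted coordinates.
Eigenvalues are clamped at zero; projections, contribution fractions
(eigenvalue/trace) and the exact spectral identities (projection variance =
eigenvalue, reconstruction, trace) are exposed and tested.

The free-energy landscape over the first two projections is the Boltzmann
inversion of their joint histogram, `G = −kT·ln(count/max_count)` with
k = 0.0083145 kJ/(mol·K), on a 50×50 grid over the observed range (the bin
count is configurable; nothing canonical fixes it).  Empty bins are masked
as NaN — a sentinel, never a large finite number — so plots can show a
bounded colour scale honestly.  Local minima use strict 8-neighbour
inequality with lowest-bin-index tie-breaks, each carrying the frame whose
projection lies nearest the bin centre as the basin representative.
`second_basin_gap` reports the gap to the lowest bin at least a third of
the grid away from the global minimum along PC1 — a separation criterion
robust to shallow sampling-noise minima on a peak's flank.

**Superposition and multi-basin ensembles.**  DCC and PCA expect frames in
a common reference frame.  When frames carry genuine global rotation or
translation, superposing onto the average structure removes it, and both
DCC and PCA are then invariant to injected rigid motion (verified to 1e−6).
However, fitting an ensemble that mixes well-separated conformational
basins onto its *mixed* average systematically distorts the basin geometry
(frames of the minor basin are rotated toward the majority mean), which
biases the apparent basin free-energy gap upward by ~10 % in our two-basin
validation.  The pipeline therefore exposes `fit_before_analysis`; for
generator output — which contains no rigid motion by construction — the
fit is disabled.  For real MD data, superposition remains the default and
this mixture-fitting caveat applies to strongly two-state trajectories.
Fitting also leaks a planted m-atom correlation block into the global
rigid-body estimate, shrinking recovered correlations by O(m/N); the
generator contract (recovery within 3/√n) therefore refers to trajectories
analysed in their native frame.

## Synthetic generators

`make_harmonic_trajectory` draws stationary isotropic Gaussian fluctuations
about a reference: per-coordinate standard deviation σ per atom, optional
equi-correlated blocks (pairwise ρ, checked for positive semi-definiteness).
Closed forms: per-atom RMSF = σ√3; cross-correlation = ρ within a block, 0
across independent atoms; empirical convergence is O(1/√frames).  Isotropy
is deliberate — it is what makes the acceptance surface analytic;
anisotropic fluctuation is not modelled.

`make_two_basin_trajectory` assigns each frame to basin 1 with probability
p1 and adds within-basin Gaussian noise; with equal within-basin widths the
expected free-energy gap between basin minima is kT·ln(p1/(1−p1)).  With
p1 = 0.8 at 310 K this is kT·ln 4 = 3.573 kJ/mol.  Validation uses 50 000
frames, where the histogram-peak estimator has a seed-to-seed spread of
~4–5 % (counting statistics of the minor basin's peak bin).

`make_interaction_fixture` builds small systems with real residue and atom
names (ASP OD1, LYS NZ, backbone N–H/O, a xylose-like HETATM ligand) whose
interaction geometry follows an exact per-frame schedule: in "on" frames
the criterion holds by construction (e.g. D–A = 2.8 Å at a 170° angle, or
O–N = 3.5 Å), in "off" frames it fails by a safe margin (3.4 Å / 4.5 Å).
Detector output therefore equals the planted schedule exactly, with no
sampling error.  Real names mean the selection machinery is exercised, not
bypassed.  Occupancy fractions are realized as exact counts
(round(p·frames)) on a seeded random subset of frames.

The synthetic reference protein is a helix-like backbone (5 Å radius,
1.5 Å rise): genuinely three-dimensional so superposition onto it is well
conditioned (a near-collinear extended chain leaves the rotation about its
own axis undetermined and turns fitting into a noise amplifier).

What the generators do **not** emulate: force-field physics, solvent
thermodynamics or realistic water geometry (solvent fixtures are sparse
point sets with water residue names), anisotropic or time-correlated
fluctuations, and coupling between fluctuation amplitude and interaction
schedules.  Passing tests therefore demonstrate the correctness of the
*analysis* — detectors, statistics, spectral identities, normalizations —
not the realism of any particular MD ensemble.

## Pipeline

Stages (`fluct`, `hbonds`, `saltbr`, `sasa`, `dcc`, `pca`, `fel`, `ligand`)
write tab-separated tables plus a manifest with the full configuration (the
defaults are the criteria above: 3 Å / 135° / 4 Å / 1000 snapshots / 10 %),
seeds, package version, stage timings and a SHA-256 hash of every output
file.  Dependencies are enforced (`fel` requires `pca`); a failing stage
keeps completed outputs and is recorded.  Deterministic stages rerun
bit-identically for a fixed configuration; `enzdyn demo` builds all
fixtures, runs every stage, and writes a planted-versus-recovered report
(the demo's deterministic surface is the set of data outputs; per-run
manifests carry wall-clock timings and are excluded from the demo's
identity hash).

Validation problem sizes — 20 000-frame harmonic ensembles (40 residues),
10 000 frames for correlation recovery, 50 000 for the two-basin landscape,
≤ 50-atom/≤ 20-frame randomized systems for detector/oracle equivalence —
were chosen so every closed form is resolved well inside its tolerance
while the whole suite stays desk-scale.

## Known limitations

* No mmCIF input; trajectory formats are multi-model PDB and DCD only.
* No bond-topology inference beyond the name/distance rules needed for
  donor resolution; no π-stacking, hydrophobic or halogen-contact typing;
  no electrostatics.
* Pairwise alignments are consumed, not computed.
* FEL basins are histogram-based; no kernel-density or reweighted
  estimators.
* Eigenvector contribution spectra depend on the input ensemble; no
  reference values exist for them without the original trajectories.
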