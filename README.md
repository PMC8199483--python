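# enzdyn

Analysis of protein molecular-dynamics trajectories, built for comparative
studies of enzyme flexibility and interactions — the kind of question that
arises when contrasting a mesostable and a hyper-thermostable glycoside
hydrolase (e.g. GH-11 xylanases, whose β-jelly-roll fold is described with
thumb / fingers / palm / cord regions): *where* is each enzyme flexible,
*which* hydrogen bonds and salt bridges persist, and *what collective
motions and conformational substates* does each trajectory sample?

Because real microsecond trajectories are large and rarely deposited, the
package ships a first-class synthetic-trajectory generator with analytically
known ground truth, so every stage of the analysis is verifiable at desk
scale without running MD.

## What it computes

Given a topology (PDB), a trajectory (multi-model PDB or DCD) and optional
region / alignment / subsite tables:

* **Fluctuations** — per-frame RMSD (optionally per structural region);
  per-residue RMSF over backbone N/Cα/C atoms after least-squares
  superposition onto the average structure,
  `RMSF_i = sqrt(⟨‖r_i(t) − ⟨r_i⟩‖²⟩_t)`, and the derived temperature factor
  `B_i = (8π²/3)·RMSF_i²`; B-factor profiles of two enzymes matched through
  a pairwise sequence alignment.
* **Hydrogen bonds** — geometric detection (donor–acceptor distance < 3 Å,
  D–H–A angle > 135°), with trajectory-normalized *static*
  (events / snapshots / residues) and *dynamic* (distinct pairs seen at
  least once / residues) counts, and enzyme–solvent bond counts.
* **Salt bridges** — occupancy (% of frames with min acidic-O to basic-N
  distance ≤ 4 Å) per Asp/Glu–Lys/Arg pair, with block-average standard
  errors.
* **Ligand contacts** — per-residue × subsite hydrogen-bond occurrence
  tables for a bound oligosaccharide, with a 10 % reporting threshold.
* **SASA** — Shrake–Rupley solvent-accessible surface area (probe 1.4 Å,
  960 sphere points per atom), per frame or trajectory-averaged.
* **Collective motions** — dynamic cross-correlation of Cα displacement
  vectors, `C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)`; essential-dynamics
  PCA of the coordinate covariance; and free-energy landscapes over the
  first two principal components, `G = −kT·ln(P/P_max)`, with basin minima
  and representative frames.

## Worked example

```python
import numpy as np
from enzdyn import select_atoms, rmsf_profile, dcc_matrix, salt_bridge_occupancy
from enzdyn.synthetic import (HarmonicEnsembleSpec, make_backbone_protein,
                              make_harmonic_trajectory, make_interaction_fixture)

ref = make_backbone_protein(40)
ca = select_atoms(ref, "calpha")
spec = HarmonicEnsembleSpec(ref, sigma_per_atom=0.5, n_frames=20000, seed=1,
                            correlation_blocks=[(ca.atom_ids[:2], 0.8)])
traj = make_harmonic_trajectory(spec)

prof = rmsf_profile(traj, select_atoms(ref, "backbone"))
print(f"mean RMSF  = {prof.rmsf.mean():.3f} A   (sigma*sqrt(3) = {0.5*np.sqrt(3):.3f} A)")
print(f"mean B     = {prof.mean_bfactor():.2f} A^2")

dcc = dcc_matrix(traj, ca)
print(f"C[0,1]     = {dcc.matrix[0, 1]:+.3f}      (planted rho = +0.800)")

_, bridge = make_interaction_fixture(
    "saltbridge", {"n_frames": 100, "pairs": [{"occupancy": 0.8}]}, seed=2)
rec = salt_bridge_occupancy(bridge)[0]
print(f"Asp1-Lys2  = {rec.occupancy:.1f} %      (planted 80.0 %)")
```

prints

```
mean RMSF  = 0.858 A   (sigma*sqrt(3) = 0.866 A)
mean B     = 19.39 A^2
C[0,1]     = +0.800      (planted rho = +0.800)
Asp1-Lys2  = 80.0 %      (planted 80.0 %)
```

The harmonic generator draws isotropic Gaussian fluctuations of standard
deviation σ per coordinate, so the per-residue RMSF converges to σ√3
(0.866 Å here; the small shortfall is the variance absorbed by removing the
six rigid-body degrees of freedom during superposition).  The planted
correlation of 0.8 between the first two Cα atoms reappears in the
cross-correlation matrix, and the scheduled salt bridge is recovered at
exactly its planted 80 % occupancy.

## Command line

```sh
enzdyn run --topology top.pdb --traj traj.dcd --stages fluct,hbonds,saltbr --out results/
enzdyn demo --seed 1 --out demo/        # synthetic end-to-end demo + report
enzdyn regions                          # residue counts of the packaged GH-11 region table
```

Each run writes tab-separated tables plus a `manifest.json` recording the
configuration, seeds and a content hash of every output, so reruns can be
checked for bit-identity.

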