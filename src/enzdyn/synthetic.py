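"""Synthetic trajectories and molecular fixtures with known ground truth.

Every generator here stands in for microsecond-scale MD sampling with an
ensemble whose fluctuation, correlation, free-energy or interaction structure
is known analytically, so each analysis stage can be validated at desk scale:

* :func:`make_harmonic_trajectory` — stationary isotropic Gaussian
  fluctuations about a reference; per-atom RMSF is exactly ``sigma * sqrt(3)``
  and planted inter-atom correlation blocks appear in the cross-correlation
  matrix as their correlation coefficient rho.
* :func:`make_two_basin_trajectory` — conformational exchange between two
  basins with occupancy ``p1``; the free-energy gap between the basin minima
  is ``kT * ln(p1/(1-p1))`` in expectation.
* :func:`make_interaction_fixture` — small protein-like systems (real residue
  and atom names) whose hydrogen-bond / salt-bridge / ligand-contact geometry
  is set frame by frame from an exact occupancy schedule.
* :func:`apply_rigid_motion` — injects random global rotations/translations
  to exercise superposition, preserving all internal distances.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call;
the seed is recorded in the output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model import StructureModel, Trajectory

__all__ = [
    "HarmonicEnsembleSpec",
    "TwoBasinSpec",
    "make_harmonic_trajectory",
    "make_two_basin_trajectory",
    "make_interaction_fixture",
    "make_solvated_fixture",
    "apply_rigid_motion",
    "make_backbone_protein",
]


# ---------------------------------------------------------------------------
# reference-structure builders
# ---------------------------------------------------------------------------

def make_backbone_protein(n_residues: int, resname: str = "ALA",
                          chain: str = "A") -> StructureModel:
    """A helix-like poly-peptide backbone (N, CA, C per residue).

    Residues wind around a 5 Å-radius helix with a 1.5 Å rise, giving the
    reference genuine three-dimensional extent so least-squares
    superposition onto it is well conditioned (a near-collinear chain would
    leave the rotation about its own axis undetermined).
    """
    import math as _math

    names, elements, resids, resnames, coords = [], [], [], [], []
    radius, rise, turn = 5.0, 1.5, _math.radians(100.0)
    for i in range(n_residues):
        a = turn * i
        cx, cy, cz = radius * _math.cos(a), radius * _math.sin(a), rise * i
        for name, el, pos in (
            ("N", "N", (cx, cy, cz)),
            ("CA", "C", (cx + 0.9 * _math.cos(a + 0.8), cy + 0.9 * _math.sin(a + 0.8), cz + 0.6)),
            ("C", "C", (cx + 1.2 * _math.cos(a + 1.6), cy + 1.2 * _math.sin(a + 1.6), cz + 1.1)),
        ):
            names.append(name)
            elements.append(el)
            resids.append(i + 1)
            resnames.append(resname)
            coords.append(pos)
    n = len(names)
    return StructureModel(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_seq=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        chain_ids=np.array([chain] * n, dtype=object),
        coords=np.array(coords),
        record_types=np.array(["ATOM"] * n, dtype=object),
    )


def _assemble(records: list[tuple]) -> StructureModel:
    """records: (record_type, name, element, resname, resid, chain, xyz)."""
    rt, nm, el, rn, ri, ch, xyz = zip(*records)
    return StructureModel(
        atom_names=np.array(nm, dtype=object),
        elements=np.array(el, dtype=object),
        residue_seq=np.array(ri),
        residue_names=np.array(rn, dtype=object),
        chain_ids=np.array(ch, dtype=object),
        coords=np.array(xyz, dtype=float),
        record_types=np.array(rt, dtype=object),
    )


# ---------------------------------------------------------------------------
# harmonic (stationary Gaussian) ensembles
# ---------------------------------------------------------------------------

@dataclass
class HarmonicEnsembleSpec:
    """Stationary Gaussian fluctuations about a reference structure.

    ``sigma_per_atom`` is the isotropic per-coordinate standard deviation in
    Å (scalar or one value per atom); ``correlation_blocks`` lists groups of
    atom indices whose displacement vectors share a pairwise correlation rho.
    """

    reference: StructureModel
    sigma_per_atom: float | np.ndarray
    n_frames: int
    seed: int
    correlation_blocks: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self):
        self.sigma_per_atom = np.broadcast_to(
            np.asarray(self.sigma_per_atom, dtype=float), (self.reference.n_atoms,)
        ).copy()
        if (self.sigma_per_atom < 0).any():
            raise ValueError("sigma_per_atom must be non-negative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        for idx, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation rho={rho} outside [-1, 1]")
            m = len(np.asarray(idx))
            if m >= 2 and rho < -1.0 / (m - 1) - 1e-12:
                raise ValueError(
                    f"rho={rho} with block size {m} gives a non-PSD covariance"
                )


def _correlated_normals(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """(n, m) standard normals with pairwise correlation rho (equicorrelation)."""
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    if (w < -1e-10).any():
        raise ValueError("correlation matrix is not positive semi-definite")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, m)) @ factor.T


def make_harmonic_trajectory(spec: HarmonicEnsembleSpec) -> Trajectory:
    """Draw a trajectory from the harmonic ensemble.

    Analytic expectations attached as metadata: per-atom
    ``expected_rmsf = sigma * sqrt(3)``; cross-correlation between atoms of a
    block equals its rho, and is 0 across independent atoms.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.reference.n_atoms
    disp = rng.standard_normal((spec.n_frames, n_atoms, 3))
    for idx, rho in spec.correlation_blocks:
        idx = np.asarray(idx, dtype=int)
        z = _correlated_normals(rng, spec.n_frames * 3, len(idx), rho)
        disp[:, idx, :] = z.reshape(spec.n_frames, 3, len(idx)).transpose(0, 2, 1)
    disp *= spec.sigma_per_atom[None, :, None]
    coords = spec.reference.coords[None, :, :] + disp
    return Trajectory(
        coords, spec.reference,
        metadata={
            "generator": "harmonic",
            "seed": spec.seed,
            "sigma_per_atom": spec.sigma_per_atom,
            "expected_rmsf": spec.sigma_per_atom * math.sqrt(3.0),
            "correlation_blocks": [
                (np.asarray(i, dtype=int), float(r)) for i, r in spec.correlation_blocks
            ],
        },
    )


# ---------------------------------------------------------------------------
# two-basin conformational exchange
# ---------------------------------------------------------------------------

@dataclass
class TwoBasinSpec:
    """Exchange between two conformational basins with occupancy ``p1``."""

    reference: StructureModel
    basin_centers: tuple[np.ndarray, np.ndarray]
    p1: float
    sigma: float
    n_frames: int
    seed: int

    def __post_init__(self):
        if not 0.0 < self.p1 < 1.0:
            raise ValueError(f"occupancy fraction p1={self.p1} must lie strictly in (0, 1)")
        c1, c2 = (np.asarray(c, dtype=float) for c in self.basin_centers)
        if c1.shape != c2.shape or c1.shape != (self.reference.n_atoms, 3):
            raise ValueError("basin centers must both be (n_atoms, 3)")
        if np.allclose(c1, c2):
            raise ValueError("basin centers must differ")
        self.basin_centers = (c1, c2)
        if self.sigma < 0:
            raise ValueError("within-basin sigma must be non-negative")


def make_two_basin_trajectory(spec: TwoBasinSpec) -> Trajectory:
    """Frames assigned to basin 1 with probability ``p1``, Gaussian within basin.

    The expected free-energy gap between the two basin minima (densities of
    equal within-basin width) is ``kT * ln(p1 / (1 - p1))``.
    """
    rng = np.random.default_rng(spec.seed)
    in_basin1 = rng.random(spec.n_frames) < spec.p1
    centers = np.where(in_basin1[:, None, None],
                       spec.basin_centers[0][None], spec.basin_centers[1][None])
    coords = centers + spec.sigma * rng.standard_normal((spec.n_frames, spec.reference.n_atoms, 3))
    return Trajectory(
        coords, spec.reference,
        metadata={
            "generator": "two_basin",
            "seed": spec.seed,
            "p1": spec.p1,
            "basin_assignment": in_basin1,
            "expected_gap_kT": math.log(spec.p1 / (1.0 - spec.p1)),
        },
    )


# ---------------------------------------------------------------------------
# interaction fixtures (exact occupancy schedules)
# ---------------------------------------------------------------------------

def _resolve_schedule(pair: dict, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    if "on_frames" in pair:
        on = np.zeros(n_frames, dtype=bool)
        on[np.asarray(pair["on_frames"], dtype=int)] = True
        return on
    occ = float(pair["occupancy"])
    if not 0.0 <= occ <= 1.0:
        raise ValueError(f"occupancy {occ} outside [0, 1]")
    k = round(occ * n_frames)
    on = np.zeros(n_frames, dtype=bool)
    on[rng.permutation(n_frames)[:k]] = True
    return on


def _acceptor_position(donor: np.ndarray, hydrogen: np.ndarray,
                       distance: float, angle_deg: float,
                       perp: np.ndarray) -> np.ndarray:
    """Place the acceptor so that |D-A| = distance and the D-H-A angle is met.

    ``perp`` is a unit vector perpendicular to H-D defining the bend plane.
    """
    if not 0.0 < angle_deg <= 180.0:
        raise ValueError(f"infeasible D-H-A angle {angle_deg}°")
    u = hydrogen - donor
    dh = np.linalg.norm(u)
    u = u / dh
    theta = math.radians(angle_deg)
    under = distance ** 2 - (dh * math.sin(theta)) ** 2
    if under < 0:
        raise ValueError(
            f"infeasible geometry: D-A distance {distance} Å unreachable at angle {angle_deg}°"
        )
    s = dh * math.cos(theta) + math.sqrt(under)
    if s <= 0:
        raise ValueError("infeasible geometry: acceptor would coincide with the hydrogen")
    v = -u * math.cos(theta) + perp * math.sin(theta)
    return hydrogen + s * v


def _hbond_fixture(pairs: list[dict], n_frames: int, rng: np.random.Generator,
                   params: dict) -> tuple[StructureModel, Trajectory, dict]:
    """Chain of ALA residues; pair k = (backbone N-H of res 2k+2, O of res 2k+1)."""
    on_d = float(params.get("on_distance", 2.8))
    on_a = float(params.get("on_angle", 170.0))
    off_d = float(params.get("off_distance", 3.4))
    n_res = int(params.get("n_residues", 2 * len(pairs)))
    if n_res < 2 * len(pairs):
        raise ValueError("need two residues per scheduled pair")
    spacing = 25.0
    records = []
    donor_idx, hyd_idx, acc_idx = [], [], []
    iat = 0
    for r in range(n_res):
        base = np.array([0.0, spacing * r, 0.0])
        k = r // 2 if r % 2 == 1 else None
        atoms = [("ATOM", "CA", "C", "ALA", r + 1, "A", base + (6.0, 0.0, 0.0)),
                 ("ATOM", "C", "C", "ALA", r + 1, "A", base + (7.4, 0.5, 0.0))]
        if r % 2 == 0:
            # acceptor residue: carbonyl O placed per-schedule near the partner donor
            atoms.append(("ATOM", "O", "O", "ALA", r + 1, "A", base + (8.0, 1.5, 0.0)))
        else:
            # donor residue: backbone N-H pointing towards the acceptor residue
            atoms.append(("ATOM", "N", "N", "ALA", r + 1, "A", base + (0.0, 0.0, 0.0)))
            atoms.append(("ATOM", "H", "H", "ALA", r + 1, "A", base + (0.0, -1.0, 0.0)))
        for a in atoms:
            records.append(a)
            name = a[1]
            if r % 2 == 0 and name == "O":
                acc_idx.append(iat)
            if r % 2 == 1 and name == "N":
                donor_idx.append(iat)
            if r % 2 == 1 and name == "H":
                hyd_idx.append(iat)
            iat += 1
    model = _assemble(records)
    schedules = [_resolve_schedule(p, n_frames, rng) for p in pairs]
    frames = np.repeat(model.coords[None, :, :], n_frames, axis=0)
    perp = np.array([1.0, 0.0, 0.0])
    for k, (pair, on) in enumerate(zip(pairs, schedules)):
        d_at, h_at, a_at = donor_idx[k], hyd_idx[k], acc_idx[k]
        d_pos, h_pos = model.coords[d_at], model.coords[h_at]
        pos_on = _acceptor_position(d_pos, h_pos,
                                    float(pair.get("on_distance", on_d)),
                                    float(pair.get("on_angle", on_a)), perp)
        pos_off = _acceptor_position(d_pos, h_pos,
                                     float(pair.get("off_distance", off_d)), 180.0, perp)
        frames[:, a_at, :] = np.where(on[:, None], pos_on[None], pos_off[None])
    meta = {
        "pairs": [
            {"donor_atom": donor_idx[k], "hydrogen_atom": hyd_idx[k],
             "acceptor_atom": acc_idx[k],
             "donor_residue": 2 * k + 2, "acceptor_residue": 2 * k + 1,
             "schedule": schedules[k]}
            for k in range(len(pairs))
        ],
    }
    return model, frames, meta


def _saltbridge_fixture(pairs: list[dict], n_frames: int, rng: np.random.Generator,
                        params: dict) -> tuple[StructureModel, Trajectory, dict]:
    """ASP/LYS pairs; the scheduled distance is the minimum OD-NZ separation."""
    on_d = float(params.get("on_distance", 3.5))
    off_d = float(params.get("off_distance", 4.5))
    spacing = 30.0
    records = []
    od1_idx, nz_idx, lys_atoms = [], [], []
    iat = 0
    resid = 0
    for k in range(len(pairs)):
        base = np.array([0.0, spacing * k, 0.0])
        resid += 1
        asp = [("ATOM", "N", "N", "ASP", resid, "A", base + (-2.4, 0.6, 0.0)),
               ("ATOM", "CA", "C", "ASP", resid, "A", base + (-1.4, 0.0, 0.0)),
               ("ATOM", "CB", "C", "ASP", resid, "A", base + (-0.9, 0.0, 1.3)),
               ("ATOM", "CG", "C", "ASP", resid, "A", base + (-1.2, 0.0, 0.0)),
               ("ATOM", "OD1", "O", "ASP", resid, "A", base + (0.0, 0.0, 0.0)),
               ("ATOM", "OD2", "O", "ASP", resid, "A", base + (-1.8, -1.1, 0.0))]
        for a in asp:
            records.append(a)
            if a[1] == "OD1":
                od1_idx.append(iat)
            iat += 1
        resid += 1
        lys_block = []
        for name, el, off in (("N", "N", (8.6, 1.2, 0.0)), ("CA", "C", (7.6, 0.6, 0.0)),
                              ("CB", "C", (6.4, 0.8, 1.0)), ("CD", "C", (5.8, 0.4, 0.0)),
                              ("CE", "C", (4.8, 0.3, 0.0)), ("NZ", "N", (3.5, 0.0, 0.0))):
            rec = ("ATOM", name, el, "LYS", resid, "A", base + np.asarray(off))
            records.append(rec)
            lys_block.append(iat)
            if name == "NZ":
                nz_idx.append(iat)
            iat += 1
        lys_atoms.append(np.array(lys_block))
    model = _assemble(records)
    schedules = [_resolve_schedule(p, n_frames, rng) for p in pairs]
    frames = np.repeat(model.coords[None, :, :], n_frames, axis=0)
    for k, (pair, on) in enumerate(zip(pairs, schedules)):
        d_on = float(pair.get("on_distance", on_d))
        d_off = float(pair.get("off_distance", off_d))
        # translate the whole LYS residue along x so |OD1-NZ| hits the schedule
        cur = model.coords[nz_idx[k], 0] - model.coords[od1_idx[k], 0]
        shift_on, shift_off = d_on - cur, d_off - cur
        shift = np.where(on, shift_on, shift_off)
        frames[:, lys_atoms[k], 0] += shift[:, None]
    meta = {
        "pairs": [
            {"acidic_residue": 2 * k + 1, "basic_residue": 2 * k + 2,
             "schedule": schedules[k]}
            for k in range(len(pairs))
        ],
    }
    return model, frames, meta


def _ligand_fixture(pairs: list[dict], n_frames: int, rng: np.random.Generator,
                    params: dict) -> tuple[StructureModel, Trajectory, dict]:
    """Protein backbone donors vs a xylose-like HETATM ligand (one residue
    per scheduled subsite, each holding one hydroxyl-oxygen acceptor)."""
    on_d = float(params.get("on_distance", 2.8))
    on_a = float(params.get("on_angle", 170.0))
    off_d = float(params.get("off_distance", 3.4))
    spacing = 25.0
    records = []
    donor_idx, hyd_idx, acc_idx = [], [], []
    iat = 0
    subsites = {}
    for k, pair in enumerate(pairs):
        base = np.array([0.0, spacing * k, 0.0])
        prot_resid = k + 1
        for name, el, off in (("N", "N", (0.0, 0.0, 0.0)), ("H", "H", (0.0, -1.0, 0.0)),
                              ("CA", "C", (1.2, 0.8, 0.0)), ("C", "C", (2.6, 0.4, 0.0)),
                              ("O", "O", (3.2, 0.4, 1.1))):
            records.append(("ATOM", name, el, "ASN", prot_resid, "A", base + np.asarray(off)))
            if name == "N":
                donor_idx.append(iat)
            if name == "H":
                hyd_idx.append(iat)
            iat += 1
        lig_resid = 100 + k
        subsites[lig_resid] = str(pair.get("subsite", "-1"))
        for name, el, off in (("C1", "C", (-6.0, -4.0, 0.0)), ("O4", "O", (0.0, -3.0, 0.0))):
            records.append(("HETATM", name, el, "XYS", lig_resid, "X", base + np.asarray(off)))
            if name == "O4":
                acc_idx.append(iat)
            iat += 1
    model = _assemble(records)
    schedules = [_resolve_schedule(p, n_frames, rng) for p in pairs]
    frames = np.repeat(model.coords[None, :, :], n_frames, axis=0)
    perp = np.array([1.0, 0.0, 0.0])
    for k, (pair, on) in enumerate(zip(pairs, schedules)):
        d_pos, h_pos = model.coords[donor_idx[k]], model.coords[hyd_idx[k]]
        pos_on = _acceptor_position(d_pos, h_pos, float(pair.get("on_distance", on_d)),
                                    float(pair.get("on_angle", on_a)), perp)
        pos_off = _acceptor_position(d_pos, h_pos, float(pair.get("off_distance", off_d)),
                                     180.0, perp)
        frames[:, acc_idx[k], :] = np.where(on[:, None], pos_on[None], pos_off[None])
    meta = {
        "subsite_map": subsites,
        "pairs": [
            {"protein_residue": k + 1, "ligand_residue": 100 + k,
             "subsite": subsites[100 + k], "schedule": schedules[k]}
            for k in range(len(pairs))
        ],
    }
    return model, frames, meta


def make_interaction_fixture(kind: str, params: dict, seed: int) -> tuple[StructureModel, Trajectory]:
    """Build a molecular fixture whose interaction geometry follows an exact schedule.

    Parameters
    ----------
    kind
        ``"hbond"``, ``"saltbridge"`` or ``"ligand"``.
    params
        ``{"n_frames": int, "pairs": [{"occupancy": f} | {"on_frames": [...]},
        ...], "on_distance": Å, "on_angle": deg, "off_distance": Å}``.
        Ligand pairs additionally take ``"subsite"`` labels.
    seed
        Seeds schedule randomization (which frames are "on" when an occupancy
        fraction rather than an explicit frame set is given).

    The returned trajectory satisfies the schedule exactly: in "on" frames
    the geometric criterion holds by construction (e.g. D–A = 2.8 Å at a
    D–H–A angle of 170°), in "off" frames it fails by a safe margin.
    Schedules and pair identities are attached to ``trajectory.metadata``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(params["n_frames"])
    pairs = params["pairs"]
    builders = {"hbond": _hbond_fixture, "saltbridge": _saltbridge_fixture,
                "ligand": _ligand_fixture}
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {sorted(builders)}")
    model, frames, meta = builders[kind](pairs, n_frames, rng, params)
    meta.update({"generator": f"fixture:{kind}", "seed": seed})
    traj = Trajectory(frames, model, metadata=meta)
    return model, traj


def make_solvated_fixture(n_waters: int, schedules: list[np.ndarray | dict],
                          n_frames: int, seed: int) -> tuple[StructureModel, Trajectory]:
    """A protein carbonyl acceptor plus waters H-bonding to it on schedule.

    Each water donates through O-H1 to the backbone O of its own protein
    residue; ``schedules[k]`` gives water k's "on" frames (or an occupancy
    dict as in :func:`make_interaction_fixture`).
    """
    rng = np.random.default_rng(seed)
    spacing = 25.0
    records = []
    wat_o, wat_atoms, prot_o = [], [], []
    iat = 0
    for k in range(n_waters):
        base = np.array([0.0, spacing * k, 0.0])
        for name, el, off in (("CA", "C", (-1.3, 0.8, 0.0)), ("C", "C", (-0.8, 0.0, 0.0)),
                              ("O", "O", (0.0, 0.0, 0.0))):
            records.append(("ATOM", name, el, "GLY", k + 1, "A", base + np.asarray(off)))
            if name == "O":
                prot_o.append(iat)
            iat += 1
        block = []
        for name, el, off in (("O", "O", (2.8, 0.0, 0.0)), ("H1", "H", (1.85, 0.0, 0.0)),
                              ("H2", "H", (3.1, 0.9, 0.0))):
            records.append(("HETATM", name, el, "HOH", 100 + k, "W", base + np.asarray(off)))
            block.append(iat)
            iat += 1
        wat_o.append(block[0])
        wat_atoms.append(np.array(block))
    model = _assemble(records)
    sched = [
        s if isinstance(s, np.ndarray) else _resolve_schedule(s, n_frames, rng)
        for s in schedules
    ]
    if len(sched) != n_waters:
        raise ValueError("one schedule per water required")
    frames = np.repeat(model.coords[None, :, :], n_frames, axis=0)
    for k, on in enumerate(sched):
        # off frames push the whole water 10 Å away along +x
        frames[:, wat_atoms[k], 0] += np.where(on, 0.0, 10.0)[:, None]
    meta = {"generator": "fixture:solvent", "seed": seed,
            "schedules": sched, "protein_acceptors": prot_o, "water_donors": wat_o}
    return model, Trajectory(frames, model, metadata=meta)


# ---------------------------------------------------------------------------
# rigid-body motion injection
# ---------------------------------------------------------------------------

def apply_rigid_motion(traj: Trajectory, seed: int,
                       translation_scale: float = 10.0) -> Trajectory:
    """Rotate and translate every frame by a random rigid-body transform.

    Internal geometry is untouched (proper rotations only), so all
    interatomic distances are preserved to floating-point accuracy; use it to
    verify that superposition removes exactly these degrees of freedom.
    """
    rng = np.random.default_rng(seed)
    rots = Rotation.random(traj.n_frames, random_state=rng).as_matrix()
    trans = rng.uniform(-translation_scale, translation_scale, size=(traj.n_frames, 3))
    moved = np.einsum("fij,faj->fai", rots, traj.coords) + trans[:, None, :]
    meta = dict(traj.metadata)
    meta["rigid_motion_seed"] = seed
    return Trajectory(moved, traj.topology, traj.frame_interval, meta)
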