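"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every geometric criterion with naive Python loops and
never call the package's detector internals, so detector/oracle agreement is
a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from enzdyn.model import StructureModel, Trajectory


# ---------------------------------------------------------------------------
# tiny hand-built structures
# ---------------------------------------------------------------------------

def build_model(records, **kwargs) -> StructureModel:
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
        **kwargs,
    )


@pytest.fixture
def tripeptide():
    """Gly-Ala dipeptide plus an Asp: exercises backbone/acidic selections."""
    return build_model([
        ("ATOM", "N", "N", "GLY", 1, "A", (0.0, 0.0, 0.0)),
        ("ATOM", "CA", "C", "GLY", 1, "A", (1.45, 0.0, 0.0)),
        ("ATOM", "C", "C", "GLY", 1, "A", (2.0, 1.4, 0.0)),
        ("ATOM", "N", "N", "ALA", 2, "A", (3.3, 1.5, 0.0)),
        ("ATOM", "CA", "C", "ALA", 2, "A", (4.2, 2.6, 0.0)),
        ("ATOM", "C", "C", "ALA", 2, "A", (5.6, 2.2, 0.0)),
        ("ATOM", "CB", "C", "ALA", 2, "A", (4.0, 3.5, 1.2)),
        ("ATOM", "N", "N", "ASP", 3, "A", (6.5, 3.2, 0.0)),
        ("ATOM", "CA", "C", "ASP", 3, "A", (7.9, 2.9, 0.0)),
        ("ATOM", "C", "C", "ASP", 3, "A", (8.7, 4.2, 0.0)),
        ("ATOM", "CB", "C", "ASP", 3, "A", (8.3, 2.1, 1.2)),
        ("ATOM", "CG", "C", "ASP", 3, "A", (9.7, 1.6, 1.1)),
        ("ATOM", "OD1", "O", "ASP", 3, "A", (10.6, 2.3, 0.6)),
        ("ATOM", "OD2", "O", "ASP", 3, "A", (9.9, 0.5, 1.6)),
    ])


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_attach_h(model: StructureModel, cutoff: float = 1.2) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for h in range(model.n_atoms):
        if model.elements[h] != "H":
            continue
        best, best_d = None, cutoff
        for j in range(model.n_atoms):
            if j == h or model.elements[j] == "H":
                continue
            if (model.chain_ids[j], model.residue_seq[j]) != (model.chain_ids[h], model.residue_seq[h]):
                continue
            d = math.dist(model.coords[h], model.coords[j])
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            out.setdefault(best, []).append(h)
    return out


def oracle_hbonds(traj: Trajectory, donor_ids, acceptor_ids,
                  dist_cut: float = 3.0, ang_cut: float = 135.0):
    """All (frame, D, H, A) satisfying D-A < dist_cut and D-H-A angle > ang_cut."""
    top = traj.topology
    attached = oracle_attach_h(top)
    found = set()
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for d in donor_ids:
            for a in acceptor_ids:
                if d == a:
                    continue
                if (top.chain_ids[d], top.residue_seq[d]) == (top.chain_ids[a], top.residue_seq[a]):
                    continue
                if math.dist(xyz[d], xyz[a]) >= dist_cut:
                    continue
                for h in attached.get(int(d), ()):
                    v1 = xyz[d] - xyz[h]
                    v2 = xyz[a] - xyz[h]
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if ang > ang_cut:
                        found.add((f, int(d), int(h), int(a)))
    return found


def oracle_salt_bridges(traj: Trajectory, cutoff: float = 4.0):
    """Occupancy fraction per acidic/basic residue pair, min-distance semantics."""
    top = traj.topology
    acid, base = {}, {}
    for i in range(top.n_atoms):
        key = (top.chain_ids[i], int(top.residue_seq[i]))
        rn, an = top.residue_names[i], top.atom_names[i]
        if (rn, an) in {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}:
            acid.setdefault(key, []).append(i)
        if (rn, an) in {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}:
            base.setdefault(key, []).append(i)
    occ = {}
    for ak, a_ids in acid.items():
        for bk, b_ids in base.items():
            n_on = 0
            for f in range(traj.n_frames):
                dmin = min(math.dist(traj.coords[f][i], traj.coords[f][j])
                           for i in a_ids for j in b_ids)
                n_on += dmin <= cutoff
            if n_on:
                occ[(ak, bk)] = n_on / traj.n_frames
    return occ


def oracle_dcc(traj: Trajectory, ids) -> np.ndarray:
    """Double-loop normalized displacement covariance."""
    n = len(ids)
    disp = traj.coords[:, ids, :] - traj.coords[:, ids, :].mean(axis=0)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = np.mean([np.dot(disp[f, i], disp[f, j]) for f in range(traj.n_frames)])
            vi = np.mean([np.dot(disp[f, i], disp[f, i]) for f in range(traj.n_frames)])
            vj = np.mean([np.dot(disp[f, j], disp[f, j]) for f in range(traj.n_frames)])
            C[i, j] = num / math.sqrt(vi * vj)
    return C


def two_sphere_sasa(r1: float, r2: float, d: float) -> float:
    """Closed-form accessible area of two intersecting spheres.

    Each sphere loses a cap of height h_i = r_i - (d² + r_i² - r_j²)/(2d);
    exposed area = 4πr² − 2πr·h per sphere.
    """
    if d >= r1 + r2:
        return 4 * math.pi * (r1 ** 2 + r2 ** 2)
    h1 = r1 - (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d)
    h2 = r2 - (d ** 2 + r2 ** 2 - r1 ** 2) / (2 * d)
    return (4 * math.pi * r1 ** 2 - 2 * math.pi * r1 * h1
            + 4 * math.pi * r2 ** 2 - 2 * math.pi * r2 * h2)


# ---------------------------------------------------------------------------
# randomized interaction fixtures for detector/oracle equivalence
# ---------------------------------------------------------------------------

def random_hbond_system(rng: np.random.Generator):
    """<= 50 atoms, <= 20 frames: residues with N-H donors and O acceptors at
    random positions in a 12 Å box (dense enough for chance contacts)."""
    n_res = int(rng.integers(3, 9))
    records = []
    for r in range(n_res):
        center = rng.uniform(0, 12, 3)
        npos = center
        hdir = rng.normal(size=3)
        hdir /= np.linalg.norm(hdir)
        records.append(("ATOM", "N", "N", "ALA", r + 1, "A", tuple(npos)))
        records.append(("ATOM", "H", "H", "ALA", r + 1, "A", tuple(npos + hdir)))
        records.append(("ATOM", "CA", "C", "ALA", r + 1, "A", tuple(center + rng.uniform(2, 4, 3))))
        records.append(("ATOM", "O", "O", "ALA", r + 1, "A", tuple(center + rng.uniform(-4, 4, 3))))
    model = build_model(records)
    n_frames = int(rng.integers(2, 21))
    coords = model.coords[None] + rng.uniform(-1.5, 1.5, (n_frames, model.n_atoms, 3))
    return model, Trajectory(coords, model)


def random_saltbridge_system(rng: np.random.Generator):
    n_pairs = int(rng.integers(1, 4))
    records = []
    resid = 0
    for _ in range(n_pairs):
        base = rng.uniform(0, 10, 3)
        resid += 1
        for name in ("OD1", "OD2"):
            records.append(("ATOM", name, "O", "ASP", resid, "A",
                            tuple(base + rng.uniform(-1, 1, 3))))
        records.append(("ATOM", "CB", "C", "ASP", resid, "A", tuple(base + (0, 0, 2))))
        resid += 1
        base2 = base + rng.uniform(-6, 6, 3)
        basic = ("NZ",) if rng.random() < 0.5 else ("NE", "NH1", "NH2")
        resname = "LYS" if basic == ("NZ",) else "ARG"
        for name in basic:
            records.append(("ATOM", name, "N", resname, resid, "A",
                            tuple(base2 + rng.uniform(-1, 1, 3))))
    model = build_model(records)
    n_frames = int(rng.integers(2, 21))
    coords = model.coords[None] + rng.uniform(-1.0, 1.0, (n_frames, model.n_atoms, 3))
    return model, Trajectory(coords, model)
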