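"""Hydrogen bonds, salt bridges, ligand contacts, SASA, block-average errors.

Geometric criteria (all configurable, defaults as used throughout):

* hydrogen bond — donor-heavy-atom to acceptor distance strictly < 3.0 Å
  and D–H–A angle (vertex at the hydrogen) strictly > 135°;
* salt bridge — minimum distance between side-chain carboxylate oxygens of
  Asp/Glu and side-chain nitrogens of Lys/Arg at most 4.0 Å (inclusive).

Statistics follow trajectory-normalized conventions: the *static* HB count
is total events / (snapshots × sequence length); the *dynamic* HB count is
the number of distinct donor–acceptor residue pairs seen in at least one
snapshot, divided by the sequence length.  Standard errors of time series
come from the block-average method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model import AtomSelection, StructureModel, Trajectory, select_atoms

__all__ = [
    "HBondEvent", "detect_hbonds", "HBStats", "hb_stats", "solvent_hb_count",
    "SaltBridgeRecord", "salt_bridge_occupancy",
    "OccurrenceTable", "ligand_hb_occurrence",
    "SASAResult", "sasa", "sasa_trajectory",
    "BlockSE", "block_average_se",
]


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondEvent:
    """One hydrogen bond observed in one frame."""

    frame: int
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    distance_DA: float
    angle_at_H: float


def _angle_at(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle (degrees) at ``vertex`` between directions to ``a`` and ``b``."""
    va = a - vertex
    vb = b - vertex
    cosang = (va * vb).sum(axis=-1) / (
        np.linalg.norm(va, axis=-1) * np.linalg.norm(vb, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(traj: Trajectory, donors: AtomSelection, acceptors: AtomSelection,
                  stride: int = 1, distance_cutoff: float = 3.0,
                  angle_cutoff: float = 135.0) -> list[HBondEvent]:
    """Detect hydrogen bonds in every sampled frame.

    A (D, H, A) triple is emitted when the donor-heavy-atom/acceptor distance
    is strictly below ``distance_cutoff`` and the D–H–A angle (vertex at H)
    strictly exceeds ``angle_cutoff``.  Same-residue donor/acceptor pairs are
    excluded.  Events come out deterministically ordered by
    (frame, donor id, acceptor id).

    Donor atoms must carry at least one hydrogen (resolved from the
    topology's reference geometry); donors without one are an error.
    """
    top = traj.topology
    attached = top.attached_hydrogens()
    bare = [i for i in donors.atom_ids if int(i) not in attached]
    if bare:
        names = ", ".join(
            f"{top.chain_ids[i]}/{top.residue_names[i]}{top.residue_seq[i]}/{top.atom_names[i]}"
            for i in bare
        )
        raise ValueError(f"donor atoms without an attached hydrogen: {names}")
    d_ids = donors.atom_ids
    a_ids = acceptors.atom_ids
    d_res = [(top.chain_ids[i], int(top.residue_seq[i])) for i in d_ids]
    a_res = [(top.chain_ids[i], int(top.residue_seq[i])) for i in a_ids]
    same_res = np.array([[dr == ar for ar in a_res] for dr in d_res])
    same_atom = d_ids[:, None] == a_ids[None, :]
    events: list[HBondEvent] = []
    for fi in range(0, traj.n_frames, stride):
        frame = traj.coords[fi]
        dist = cdist(frame[d_ids], frame[a_ids])
        cand = (dist < distance_cutoff) & ~same_res & ~same_atom
        for di, ai in zip(*np.nonzero(cand)):
            d_at, a_at = int(d_ids[di]), int(a_ids[ai])
            for h_at in attached[d_at]:
                ang = float(_angle_at(frame[h_at], frame[d_at], frame[a_at]))
                if ang > angle_cutoff:
                    events.append(HBondEvent(fi, d_at, h_at, a_at,
                                             float(dist[di, ai]), ang))
    events.sort(key=lambda e: (e.frame, e.donor_atom, e.acceptor_atom, e.hydrogen_atom))
    return events


@dataclass
class HBStats:
    """Trajectory-normalized hydrogen-bond statistics."""

    static_count: float            # events per snapshot per residue
    dynamic_count: float           # distinct residue pairs per residue
    n_snapshots: int
    sequence_length: int
    standard_error: float          # block-average SE of the static count
    metadata: dict = field(default_factory=dict)


def _pair_sets(events: list[HBondEvent], top: StructureModel):
    """Per-frame sets of (donor atom, acceptor atom) pairs (hydrogens merged),
    plus the overall set of donor/acceptor *residue* pairs."""
    per_frame: dict[int, set] = {}
    residue_pairs: set = set()
    for e in events:
        per_frame.setdefault(e.frame, set()).add((e.donor_atom, e.acceptor_atom))
        residue_pairs.add((
            (top.chain_ids[e.donor_atom], int(top.residue_seq[e.donor_atom])),
            (top.chain_ids[e.acceptor_atom], int(top.residue_seq[e.acceptor_atom])),
        ))
    return per_frame, residue_pairs


def hb_stats(events: list[HBondEvent], n_snapshots: int, sequence_length: int,
             topology: StructureModel, frames: np.ndarray | None = None,
             literal_dynamic_normalization: bool = False) -> HBStats:
    """Static and dynamic hydrogen-bond counts from detected events.

    static = (total HB events over all snapshots) / (snapshots × residues);
    an event is one donor-heavy-atom/acceptor pair per frame — multiple
    hydrogens of one donor never multi-count.
    dynamic = (distinct donor–acceptor residue pairs seen in >= 1 snapshot)
    / residues.  A count of at-least-once pairs cannot scale with snapshot
    number; the literal additionally-by-snapshots normalization is available
    via ``literal_dynamic_normalization`` and recorded in metadata.
    """
    if n_snapshots < 1 or sequence_length < 1:
        raise ValueError("n_snapshots and sequence_length must be >= 1")
    per_frame, residue_pairs = _pair_sets(events, topology)
    if frames is None:
        frames = np.arange(n_snapshots)
    counts = np.array([len(per_frame.get(int(f), ())) for f in frames], dtype=float)
    total = counts.sum()
    static = total / (n_snapshots * sequence_length)
    dynamic = len(residue_pairs) / sequence_length
    if literal_dynamic_normalization:
        dynamic /= n_snapshots
    se = (block_average_se(counts / sequence_length).value
          if len(counts) >= 4 else float("nan"))
    return HBStats(
        float(static), float(dynamic), int(n_snapshots), int(sequence_length), se,
        metadata={
            "static_normalization": "events / (n_snapshots * sequence_length)",
            "dynamic_normalization": (
                "distinct residue pairs / (sequence_length * n_snapshots)"
                if literal_dynamic_normalization
                else "distinct residue pairs / sequence_length"
            ),
            "pair_identity": "donor heavy atom / acceptor atom (hydrogen merged)",
        },
    )


def solvent_hb_count(traj: Trajectory, protein_selection: AtomSelection,
                     solvent_selection: AtomSelection, stride: int = 1,
                     **criteria) -> float:
    """Mean number of protein–solvent hydrogen bonds per sampled snapshot.

    Both directions count: protein donor → water acceptor and water donor →
    protein acceptor; pairs are de-duplicated per frame on the
    (donor atom, acceptor atom) identity.
    """
    if len(solvent_selection) == 0:
        raise ValueError("solvent selection is empty")
    top = traj.topology
    donors = select_atoms(top, "donors")
    acceptors = select_atoms(top, "acceptors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_don = donors.intersect(protein_selection)
        p_acc = acceptors.intersect(protein_selection)
        s_don = donors.intersect(solvent_selection)
        s_acc = acceptors.intersect(solvent_selection)
    events: list[HBondEvent] = []
    if len(p_don) and len(s_acc):
        events += detect_hbonds(traj, p_don, s_acc, stride, **criteria)
    if len(s_don) and len(p_acc):
        events += detect_hbonds(traj, s_don, p_acc, stride, **criteria)
    per_frame, _ = _pair_sets(events, top)
    n_sampled = len(range(0, traj.n_frames, stride))
    return float(sum(len(s) for s in per_frame.values()) / n_sampled)


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

@dataclass
class SaltBridgeRecord:
    """Occupancy of one acidic/basic residue pair over the trajectory."""

    acidic_residue: tuple[str, int, str]    # (chain, resseq, resname)
    basic_residue: tuple[str, int, str]
    occupancy: float                        # % of sampled frames
    standard_error: float                   # % (block-average method)


def salt_bridge_occupancy(traj: Trajectory, stride: int = 1,
                          cutoff: float = 4.0,
                          include_his: bool = False) -> list[SaltBridgeRecord]:
    """Occupancy (% of frames) of every salt bridge observed at least once.

    A pair of residues is bridged in a frame when the *minimum* distance over
    its acidic-oxygen/basic-nitrogen atom pairs does not exceed ``cutoff``
    (boundary inclusive).  Pairs never within the cutoff are omitted.
    """
    top = traj.topology
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acid = select_atoms(top, "acidic-O")
        base = select_atoms(top, "basic-N", include_his_basic=include_his)
    if len(acid) == 0 or len(base) == 0:
        raise ValueError("no acidic oxygens or basic nitrogens in topology")

    def reskey(i):
        return (top.chain_ids[i], int(top.residue_seq[i]), str(top.residue_names[i]))

    acid_res: dict[tuple, list[int]] = {}
    for i in acid.atom_ids:
        acid_res.setdefault(reskey(i), []).append(int(i))
    base_res: dict[tuple, list[int]] = {}
    for i in base.atom_ids:
        base_res.setdefault(reskey(i), []).append(int(i))

    frames = range(0, traj.n_frames, stride)
    n_sampled = len(frames)
    on: dict[tuple, np.ndarray] = {}
    for t, fi in enumerate(frames):
        frame = traj.coords[fi]
        for ak, a_ids in acid_res.items():
            for bk, b_ids in base_res.items():
                d = cdist(frame[a_ids], frame[b_ids]).min()
                if d <= cutoff:
                    on.setdefault((ak, bk), np.zeros(n_sampled, bool))[t] = True
    records = []
    for (ak, bk), series in sorted(on.items()):
        occ = 100.0 * series.mean()
        se = (100.0 * block_average_se(series.astype(float)).value
              if n_sampled >= 4 else float("nan"))
        records.append(SaltBridgeRecord(ak, bk, float(occ), float(se)))
    return records


# ---------------------------------------------------------------------------
# ligand contacts
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceTable:
    """Per-residue × subsite hydrogen-bond occurrence percentages."""

    rows: list[tuple[tuple[str, int, str], str, float]]   # (residue, subsite, %)
    threshold: float
    all_rows: list[tuple[tuple[str, int, str], str, float]] = None


def ligand_hb_occurrence(traj: Trajectory, ligand_selection: AtomSelection,
                         subsite_map: dict[int, str], window: int | None = None,
                         stride: int = 1, threshold: float = 10.0,
                         suppress_below_threshold: bool = True,
                         **criteria) -> OccurrenceTable:
    """Occurrence (%) of protein-residue ↔ ligand hydrogen bonds per subsite.

    ``subsite_map`` assigns each ligand residue number to a subsite label
    (−3…+3 convention).  ``window`` restricts the analysis to the first
    ``window`` frames (e.g. an early segment of a long run).  Rows below
    ``threshold`` % are suppressed unless asked for.
    """
    if len(ligand_selection) == 0:
        raise ValueError("no ligand present")
    top = traj.topology
    for i in ligand_selection.atom_ids:
        r = int(top.residue_seq[i])
        if r not in subsite_map:
            raise KeyError(f"ligand residue {r} missing from subsite map")
    work = traj if window is None else Trajectory(
        traj.coords[:window], top, traj.frame_interval, dict(traj.metadata))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        protein = select_atoms(top, "protein")
        donors = select_atoms(top, "donors")
        acceptors = select_atoms(top, "acceptors")
        p_don, p_acc = donors.intersect(protein), acceptors.intersect(protein)
        l_don, l_acc = donors.intersect(ligand_selection), acceptors.intersect(ligand_selection)
    events: list = []
    if len(p_don) and len(l_acc):
        events += detect_hbonds(work, p_don, l_acc, stride, **criteria)
    if len(l_don) and len(p_acc):
        events += detect_hbonds(work, l_don, p_acc, stride, **criteria)
    n_sampled = len(range(0, work.n_frames, stride))
    lig_ids = set(int(i) for i in ligand_selection.atom_ids)
    seen: dict[tuple, set[int]] = {}
    for e in events:
        prot_at, lig_at = ((e.acceptor_atom, e.donor_atom)
                           if e.donor_atom in lig_ids else (e.donor_atom, e.acceptor_atom))
        residue = (top.chain_ids[prot_at], int(top.residue_seq[prot_at]),
                   str(top.residue_names[prot_at]))
        subsite = subsite_map[int(top.residue_seq[lig_at])]
        seen.setdefault((residue, subsite), set()).add(e.frame)
    all_rows = sorted(
        ((res, sub, 100.0 * len(fr) / n_sampled) for (res, sub), fr in seen.items()),
        key=lambda r: (r[0][0], r[0][1], r[1]),
    )
    rows = ([r for r in all_rows if r[2] >= threshold]
            if suppress_below_threshold else list(all_rows))
    return OccurrenceTable(rows, threshold, all_rows)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

@dataclass
class SASAResult:
    """Solvent-accessible surface area, per atom and total (Å²)."""

    per_atom_area: np.ndarray
    total_area: float
    probe_radius: float
    n_sphere_points: int
    standard_error: float | None = None


def _canonical_frame(xyz: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into their principal-axes frame.

    Axes are ordered by decreasing positional variance; each axis sign is
    fixed by making the third moment along it non-negative, and handedness
    is restored by flipping the last axis if needed.
    """
    center = xyz.mean(axis=0)
    X = xyz - center
    if len(X) < 2:
        return X
    cov = X.T @ X
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]
    Y = X @ v
    for k in range(3):
        m3 = (Y[:, k] ** 3).sum()
        if m3 < 0 or (m3 == 0 and Y[:, k].min() + Y[:, k].max() < 0):
            Y[:, k] *= -1
            v[:, k] *= -1
    if np.linalg.det(v) < 0:
        Y[:, 2] *= -1
    return Y


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(model: StructureModel, coords: np.ndarray | None = None,
         probe: float = 1.4, n_points: int = 960,
         selection: AtomSelection | None = None) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area of one conformation.

    Each atom is covered with ``n_points`` quasi-uniform sphere points at
    radius ``r_vdw + probe``; the exposed fraction times the sphere area
    ``4 pi (r + probe)^2`` gives the per-atom contribution.  Solvent atoms
    are excluded from the solute set by default.

    The quadrature runs in a canonical body-fixed frame (principal axes of
    the solute, deterministic sign convention), so the result is exactly
    invariant under rigid-body motion of the whole solute rather than only
    to quadrature accuracy.
    """
    if coords is None:
        coords = model.coords
    if selection is None:
        ids = np.nonzero(~model.is_solvent())[0]
    else:
        ids = selection.atom_ids
    xyz = np.asarray(coords, dtype=float)[ids]
    xyz = _canonical_frame(xyz)
    radii = model.vdw_radii[ids] + probe
    sphere = _fibonacci_sphere(n_points)
    n = len(ids)
    areas = np.zeros(n)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        neigh = np.nonzero((d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i))[0]
        pts = xyz[i] + radii[i] * sphere
        if len(neigh):
            buried = np.zeros(n_points, bool)
            for j in neigh:
                buried |= ((pts - xyz[j]) ** 2).sum(-1) < radii[j] ** 2
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    per_atom = np.zeros(model.n_atoms)
    per_atom[ids] = areas
    return SASAResult(per_atom, float(areas.sum()), probe, n_points)


def sasa_trajectory(traj: Trajectory, stride: int = 1, probe: float = 1.4,
                    n_points: int = 960,
                    selection: AtomSelection | None = None) -> SASAResult:
    """Time-mean SASA over sampled frames, with block-average standard error."""
    frames = range(0, traj.n_frames, stride)
    totals, per_atom = [], None
    for fi in frames:
        r = sasa(traj.topology, traj.coords[fi], probe, n_points, selection)
        totals.append(r.total_area)
        per_atom = r.per_atom_area if per_atom is None else per_atom + r.per_atom_area
    totals = np.array(totals)
    se = block_average_se(totals).value if len(totals) >= 4 else float("nan")
    return SASAResult(per_atom / len(totals), float(totals.mean()),
                      probe, n_points, standard_error=float(se))


# ---------------------------------------------------------------------------
# block-average standard error
# ---------------------------------------------------------------------------

@dataclass
class BlockSE:
    """Block-average standard error at the plateau block size."""

    value: float
    block_size: int
    converged: bool


def block_average_se(series: np.ndarray, min_blocks: int = 4,
                     plateau_rtol: float = 0.05) -> BlockSE:
    """Standard error of the mean of a (possibly autocorrelated) series.

    The series is cut into contiguous equal blocks; for each block size on a
    geometric ladder (doubling), SE = stdev(block means) / sqrt(n_blocks).
    The reported value is the first of the ladder where SE changes by less
    than ``plateau_rtol`` relative to the next size (the plateau); if no
    plateau is reached the largest size is reported with ``converged=False``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < min_blocks:
        raise ValueError(f"series of length {n} too short for {min_blocks} blocks")
    sizes = []
    b = 1
    while n // b >= min_blocks:
        sizes.append(b)
        b *= 2
    ses = []
    for b in sizes:
        nb = n // b
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        ses.append(means.std(ddof=1) / np.sqrt(nb))
    for k in range(len(sizes) - 1):
        denom = ses[k + 1] if ses[k + 1] > 0 else 1.0
        if abs(ses[k] - ses[k + 1]) < plateau_rtol * denom or ses[k + 1] == ses[k] == 0.0:
            return BlockSE(float(ses[k]), sizes[k], True)
    return BlockSE(float(ses[-1]), sizes[-1], False)
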