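"""Superposition, RMSD series, RMSF / B-factor profiles, profile matching.

The per-residue flexibility profile follows the standard MD convention:
snapshots are least-squares fitted (proper rotations only) onto the
time-average structure, the root-mean-square fluctuation of each backbone
atom about its mean position is computed, per-residue values aggregate the
N/CA/C atoms mass-weightedly, and the crystallographic-style temperature
factor is ``B = (8 pi^2 / 3) * RMSF^2`` (Å²).

Note on the RMSF definition: the quantity is the *root* mean square
fluctuation, ``sqrt(mean_t ||r_i(t) - <r_i>||^2)`` — the square root over the
time average is essential for Å units and for the B-factor relation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AtomSelection, RegionMap, StructureModel, Trajectory

__all__ = [
    "BFACTOR_COEFF",
    "kabsch",
    "superpose",
    "average_structure",
    "RMSDSeries",
    "rmsd_series",
    "FluctuationProfile",
    "rmsf_profile",
    "bfactor_profile",
    "MatchedProfile",
    "match_profiles",
]

#: B-factor conversion coefficient (8/3) * pi^2
BFACTOR_COEFF = (8.0 / 3.0) * np.pi ** 2


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation/translation of ``mobile`` onto ``target``.

    Batched: ``mobile`` may be (F, N, 3) or (N, 3).  Returns
    ``(rotations, mobile_centroids, target_centroid)`` such that
    ``(x - mobile_centroid) @ R.T + target_centroid`` is the fitted frame.
    Reflections are never returned: the rotation determinant is +1.
    """
    single = mobile.ndim == 2
    M = mobile[None] if single else mobile
    cm = M.mean(axis=1, keepdims=True)
    ct = target.mean(axis=0)
    A = np.einsum("fni,nj->fij", M - cm, target - ct)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    U[:, :, -1] *= d[:, None]
    # R maps mobile -> target:  R = V @ diag(1,1,d) @ U^T
    R = np.einsum("fji,fkj->fik", Vt, U)
    if single:
        return R[0], cm[0, 0], ct
    return R, cm[:, 0, :], ct


def superpose(traj: Trajectory, reference: np.ndarray,
              fit_selection: AtomSelection) -> Trajectory:
    """RMS-fit every frame onto reference coordinates.

    The optimal rigid transform is computed on ``fit_selection`` and applied
    to *all* atoms; this removes global translation and rotation while
    leaving internal motion untouched.
    """
    ids = fit_selection.atom_ids
    if len(ids) < 3:
        raise ValueError(
            f"fit selection {fit_selection.label!r} has {len(ids)} atoms; need >= 3"
        )
    ref = np.asarray(reference, dtype=float)
    ref_sel = ref[ids]
    if np.linalg.matrix_rank(ref_sel - ref_sel.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("fit selection geometry is degenerate (collinear atoms)")
    R, cm, ct = kabsch(traj.coords[:, ids, :], ref_sel)
    fitted = np.einsum("fij,faj->fai", R, traj.coords - cm[:, None, :]) + ct
    return Trajectory(fitted, traj.topology, traj.frame_interval, dict(traj.metadata))


def average_structure(traj: Trajectory, fit_selection: AtomSelection,
                      tol: float = 1e-9, max_iter: int = 10) -> tuple[Trajectory, np.ndarray]:
    """Fit the trajectory onto its own average structure.

    Fit-to-mean iterations are repeated while the mean still moves by more
    than ``tol`` Å (a contraction; typically 2-3 rounds).  The tight default
    makes refitting the returned trajectory a no-op to well below 1e-8 Å.
    Returns ``(fitted trajectory, average coordinates)``.
    """
    fitted = traj
    mean = traj.coords.mean(axis=0)
    for _ in range(max_iter):
        fitted = superpose(fitted, mean, fit_selection)
        new_mean = fitted.coords.mean(axis=0)
        moved = np.abs(new_mean - mean).max()
        mean = new_mean
        if moved <= tol:
            break
    return fitted, mean


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) of a selection against a reference."""

    values: np.ndarray
    selection_label: str
    reference_label: str
    region_name: str | None = None


def _rmsd(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.sqrt(((coords - ref[None]) ** 2).sum(axis=-1).mean(axis=-1))


def rmsd_series(traj: Trajectory, reference: np.ndarray, selection: AtomSelection,
                regions: RegionMap | None = None, enzyme_label: str | None = None,
                fit: bool = True, fit_selection: AtomSelection | None = None,
                reference_label: str = "starting structure") -> RMSDSeries | dict[str, RMSDSeries]:
    """RMSD of each frame to a reference after (optional) superposition.

    With a :class:`RegionMap`, one series per region is returned; regions
    restrict the *measured* atoms only — the fit stays on ``fit_selection``
    (default: the measurement selection).
    """
    if len(selection) == 0:
        raise ValueError(f"selection {selection.label!r} is empty")
    ref = np.asarray(reference, dtype=float)
    work = superpose(traj, ref, fit_selection or selection) if fit else traj
    if regions is None:
        return RMSDSeries(_rmsd(work.coords[:, selection.atom_ids], ref[selection.atom_ids]),
                          selection.label, reference_label)
    top = traj.topology
    out: dict[str, RMSDSeries] = {}
    for name in regions.region_names(enzyme_label):
        resnums = set(regions.residue_numbers(enzyme_label, name).tolist())
        ids = np.array([i for i in selection.atom_ids if int(top.residue_seq[i]) in resnums])
        if len(ids) == 0:
            raise ValueError(f"region {name!r} selects no atoms from {selection.label!r}")
        out[name] = RMSDSeries(_rmsd(work.coords[:, ids], ref[ids]),
                               selection.label, reference_label, region_name=name)
    return out


# ---------------------------------------------------------------------------
# RMSF / B-factor profiles
# ---------------------------------------------------------------------------

@dataclass
class FluctuationProfile:
    """Per-residue RMSF (Å) and derived B-factor (Å²) over an atom selection."""

    residue_keys: list[tuple[str, int]]     # (chain, resseq)
    residue_names: list[str]
    rmsf: np.ndarray
    bfactor: np.ndarray = None
    atom_selection_label: str = "backbone"
    mass_weighted: bool = True
    per_atom_msf: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.bfactor is None:
            self.bfactor = BFACTOR_COEFF * self.rmsf ** 2

    def __len__(self) -> int:
        return len(self.rmsf)

    def mean_bfactor(self, per_atom: bool = False) -> float:
        """Average B-factor: arithmetic mean over residues (or atoms)."""
        if per_atom:
            msf = np.array(list(self.per_atom_msf.values()))
            return float(BFACTOR_COEFF * msf.mean())
        return float(self.bfactor.mean())


def rmsf_profile(traj: Trajectory, selection: AtomSelection,
                 mass_weighted: bool = True, refit_tol: float = 1e-3,
                 backbone_names: tuple[str, ...] = ("N", "CA", "C")) -> FluctuationProfile:
    """Per-residue RMSF and B-factor about the time-average structure.

    The trajectory is expected to be superposed already; the average is
    recomputed and, if fitting to it would still move coordinates by more
    than ``refit_tol`` Å, the trajectory is refitted once.

    Per-atom fluctuation is ``sqrt(mean_t ||r_i(t) - <r_i>||^2)``; the
    per-residue value aggregates each residue's backbone atoms as
    ``sqrt(sum_i m_i * msf_i / sum_i m_i)`` (mass-weighted; plain mean with
    ``mass_weighted=False``).  Residues missing any backbone atom are
    excluded with a warning.
    """
    if len(selection) == 0:
        raise ValueError(f"selection {selection.label!r} is empty")
    work = traj
    mean = work.coords.mean(axis=0)
    check = superpose(work, mean, selection)
    if np.abs(check.coords - work.coords).max() > refit_tol:
        work, mean = average_structure(work, selection)
    top = traj.topology
    ids = selection.atom_ids
    msf = ((work.coords[:, ids] - mean[None, ids]) ** 2).sum(axis=-1).mean(axis=0)
    per_atom = {int(i): float(v) for i, v in zip(ids, msf)}

    by_res: dict[tuple[str, int], list[int]] = {}
    for i in ids:
        by_res.setdefault((top.chain_ids[i], int(top.residue_seq[i])), []).append(int(i))
    keys, names, values = [], [], []
    required = set(backbone_names) if selection.label == "backbone" else None
    for key, atom_ids in by_res.items():
        if required is not None:
            have = {str(top.atom_names[i]) for i in atom_ids}
            if not required <= have:
                warnings.warn(
                    f"residue {key} misses backbone atoms {sorted(required - have)}; "
                    "excluded from profile", stacklevel=2,
                )
                continue
        m = top.masses[atom_ids]
        v = np.array([per_atom[i] for i in atom_ids])
        w = m if mass_weighted else np.ones_like(m)
        keys.append(key)
        names.append(str(top.residue_names[atom_ids[0]]))
        values.append(np.sqrt((w * v).sum() / w.sum()))
    return FluctuationProfile(keys, names, np.array(values),
                              atom_selection_label=selection.label,
                              mass_weighted=mass_weighted, per_atom_msf=per_atom)


def bfactor_profile(profile: FluctuationProfile) -> FluctuationProfile:
    """Recompute the B-factor column, ``B_i = RMSF_i^2 * (8/3) * pi^2``."""
    profile.bfactor = BFACTOR_COEFF * profile.rmsf ** 2
    return profile


# ---------------------------------------------------------------------------
# alignment-based profile matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedProfile:
    """Two B-factor profiles laid out on alignment columns (NaN = gap)."""

    columns: np.ndarray          # column indices, 0-based
    res_a: np.ndarray            # ungapped residue index or -1
    res_b: np.ndarray
    b_a: np.ndarray              # B-factor or NaN at gaps
    b_b: np.ndarray

    def __len__(self) -> int:
        return len(self.columns)


def match_profiles(profile_a: FluctuationProfile, profile_b: FluctuationProfile,
                   aln) -> MatchedProfile:
    """Match two per-residue profiles through a pairwise sequence alignment.

    Profile entry ``k`` corresponds to ungapped residue ``k`` of its
    sequence; gap columns carry NaN so plots naturally show curve gaps.
    """
    na, nb = len(aln.ungapped_a), len(aln.ungapped_b)
    if len(profile_a) != na or len(profile_b) != nb:
        raise ValueError(
            f"profile lengths ({len(profile_a)}, {len(profile_b)}) do not match "
            f"ungapped alignment lengths ({na}, {nb})"
        )
    n = len(aln.column_map)
    res_a = np.full(n, -1, dtype=int)
    res_b = np.full(n, -1, dtype=int)
    b_a = np.full(n, np.nan)
    b_b = np.full(n, np.nan)
    for k, (ia, ib) in enumerate(aln.column_map):
        if ia is not None:
            res_a[k] = ia
            b_a[k] = profile_a.bfactor[ia]
        if ib is not None:
            res_b[k] = ib
            b_b[k] = profile_b.bfactor[ib]
    return MatchedProfile(np.arange(n), res_a, res_b, b_a, b_b)
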