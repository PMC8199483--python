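"""Correlated motions: cross-correlation matrices, essential-dynamics PCA,
and free-energy landscapes over principal-component projections.

The dynamic cross-correlation between two Cα atoms i and j is the
normalized covariance of their displacement vectors,

    C_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²> <Δr_j²>),   Δr = r − <r>,

with C = 1 for fully correlated and −1 for fully anticorrelated motion.
PCA diagonalizes the 3N × 3N coordinate covariance matrix of the selected
atoms; the eigenvalues (Å²) are the variances along the collective modes and
their fractions of the trace form the contribution spectrum.  The
free-energy landscape over the first two projections is the Boltzmann
inversion of the joint histogram, G = −kT ln(P / P_max).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AtomSelection, Trajectory

__all__ = [
    "BOLTZMANN_KJ_PER_MOL_K",
    "DCCMatrix", "dcc_matrix",
    "PCAResult", "pca_decompose",
    "FELGrid", "fel_from_projections",
]

#: Boltzmann constant in kJ/(mol K) (i.e. the molar gas constant R)
BOLTZMANN_KJ_PER_MOL_K = 0.0083145


# ---------------------------------------------------------------------------
# dynamic cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class DCCMatrix:
    """Residue × residue cross-correlation matrix (NaN rows = zero variance)."""

    matrix: np.ndarray
    residue_labels: list[tuple[str, int]]
    masked: np.ndarray = None       # bool, True where variance was zero

    def __post_init__(self):
        if self.masked is None:
            self.masked = np.zeros(len(self.residue_labels), bool)


def dcc_matrix(traj: Trajectory, selection: AtomSelection) -> DCCMatrix:
    """Cross-correlation of displacement vectors of the selected atoms.

    The trajectory is expected to be superposed onto its average structure
    already (the displacements are taken about the time mean).  Atoms with
    zero positional variance are masked (NaN row/column) with a warning.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for cross-correlations")
    ids = selection.atom_ids
    top = traj.topology
    disp = traj.coords[:, ids, :] - traj.coords[:, ids, :].mean(axis=0, keepdims=True)
    cov = np.einsum("fik,fjk->ij", disp, disp) / traj.n_frames
    var = np.diag(cov).copy()
    zero = var < 1e-12
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance atoms masked in DCC", stacklevel=2)
        var[zero] = np.nan
    C = cov / np.sqrt(var[:, None] * var[None, :])
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    labels = [(top.chain_ids[i], int(top.residue_seq[i])) for i in ids]
    return DCCMatrix(C, labels, masked=zero)


# ---------------------------------------------------------------------------
# essential-dynamics PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigensystem of the coordinate covariance matrix plus projections."""

    eigenvalues: np.ndarray           # Å², descending
    eigenvectors: np.ndarray          # (3N, n_components), orthonormal columns
    projections: np.ndarray           # (n_frames, n_components), Å
    contribution_fractions: np.ndarray
    mean_coords: np.ndarray           # (N, 3) of the selected atoms
    atom_ids: np.ndarray = None

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def pca_decompose(traj: Trajectory, selection: AtomSelection,
                  n_components: int | None = None, ddof: int = 0) -> PCAResult:
    """Diagonalize the coordinate covariance of the selected atoms.

    Frames are taken as already aligned to their average coordinates.  The
    covariance uses population (1/n) normalization by default (``ddof=1``
    for the sample convention).  Eigenvalues are clamped at zero; the
    contribution fractions are eigenvalue / trace.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    ids = selection.atom_ids
    three_n = 3 * len(ids)
    if n_components is None:
        n_components = three_n
    elif n_components > three_n:
        warnings.warn(
            f"n_components={n_components} exceeds 3N={three_n}; clamped", stacklevel=2)
        n_components = three_n
    mean = traj.coords[:, ids, :].mean(axis=0)
    X = (traj.coords[:, ids, :] - mean[None]).reshape(traj.n_frames, three_n)
    cov = X.T @ X / (traj.n_frames - ddof)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    trace = w.sum()
    fractions = w / trace if trace > 0 else np.zeros_like(w)
    return PCAResult(
        eigenvalues=w[:n_components],
        eigenvectors=v[:, :n_components],
        projections=X @ v[:, :n_components],
        contribution_fractions=fractions[:n_components],
        mean_coords=mean,
        atom_ids=ids,
    )


# ---------------------------------------------------------------------------
# free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FELGrid:
    """Free-energy surface over two principal-component projections.

    ``G`` is in kJ/mol, zero at the most probable bin, NaN where the bin is
    unpopulated (infinite free energy; exported as a sentinel, never as a
    large finite number).
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray
    G: np.ndarray
    temperature: float
    minima: list[tuple[tuple[int, int], float, int]] = field(default_factory=list)
    # each minimum: ((bin_i, bin_j), G value, representative frame index)


def fel_from_projections(pc1: np.ndarray, pc2: np.ndarray, temperature_K: float,
                         n_bins: int = 50) -> FELGrid:
    """Boltzmann inversion of the joint PC1/PC2 histogram.

    ``G = -kT ln(count / max_count)`` with ``k = 0.0083145`` kJ/(mol·K), so
    the most probable bin sits at G = 0 and every populated bin has G >= 0.
    Local minima are detected on the populated grid with strict 8-neighbor
    inequality (ties broken by lowest bin index); each minimum carries the
    index of the frame whose projection lies nearest its bin center.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if not (np.isfinite(pc1).all() and np.isfinite(pc2).all()):
        raise ValueError("projections must be finite")
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    counts, ex, ey = np.histogram2d(pc1, pc2, bins=n_bins)
    kT = BOLTZMANN_KJ_PER_MOL_K * temperature_K
    with np.errstate(divide="ignore"):
        G = -kT * np.log(counts / counts.max())
    G[counts == 0] = np.nan

    minima = []
    ni, nj = G.shape
    for i in range(ni):
        for j in range(nj):
            g = G[i, j]
            if not np.isfinite(g):
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < ni and 0 <= b < nj and np.isfinite(G[a, b]):
                        if G[a, b] <= g:
                            is_min = False
                            break
                if not is_min:
                    break
            if is_min:
                cx = 0.5 * (ex[i] + ex[i + 1])
                cy = 0.5 * (ey[j] + ey[j + 1])
                rep = int(np.argmin((pc1 - cx) ** 2 + (pc2 - cy) ** 2))
                minima.append(((i, j), float(g), rep))
    minima.sort(key=lambda m: (m[1], m[0]))
    return FELGrid(ex, ey, counts, G, float(temperature_K), minima)


def second_basin_gap(grid: FELGrid, min_separation_bins: int | None = None) -> float:
    """Free-energy gap between the global basin and the nearest distinct basin.

    The second basin's minimum is the lowest-G populated bin whose PC1 bin
    index is at least ``min_separation_bins`` (default: a third of the grid)
    away from the global minimum — a separation criterion that is robust to
    shallow sampling-noise minima on the flanks of a peak.
    """
    ni = grid.G.shape[0]
    if min_separation_bins is None:
        min_separation_bins = ni // 3
    flat = np.nan_to_num(grid.G, nan=np.inf)
    i0 = np.unravel_index(np.argmin(flat), flat.shape)[0]
    far = flat[np.abs(np.arange(ni) - i0) >= min_separation_bins, :]
    if not np.isfinite(far).any():
        raise ValueError("no populated bins beyond the separation distance")
    return float(far.min() - flat.min())
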