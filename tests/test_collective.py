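"""Cross-correlation matrices, PCA identities, free-energy landscapes."""

import numpy as np
import pytest

from enzdyn.collective import (
    BOLTZMANN_KJ_PER_MOL_K as KB,
    dcc_matrix,
    fel_from_projections,
    pca_decompose,
    second_basin_gap,
)
from enzdyn.model import Trajectory, select_atoms
from enzdyn.synthetic import (
    HarmonicEnsembleSpec,
    TwoBasinSpec,
    apply_rigid_motion,
    make_backbone_protein,
    make_harmonic_trajectory,
    make_two_basin_trajectory,
)
from enzdyn.fluctuations import average_structure

from conftest import oracle_dcc


@pytest.fixture(scope="module")
def ref():
    return make_backbone_protein(12)


@pytest.fixture(scope="module")
def calpha(ref):
    return select_atoms(ref, "calpha")


class TestDCC:
    def test_identical_displacements_fully_correlated(self, ref, calpha):
        rng = np.random.default_rng(0)
        disp = rng.normal(0, 0.5, (50, 1, 3))
        coords = np.repeat(ref.coords[None], 50, axis=0)
        ids = calpha.atom_ids[:2]
        coords[:, ids, :] += disp            # same displacement for both atoms
        coords[:, calpha.atom_ids[2:], :] += rng.normal(0, 0.5, (50, len(calpha) - 2, 3))
        d = dcc_matrix(Trajectory(coords, ref), calpha)
        assert d.matrix[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_opposite_displacements_anticorrelated(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(
            ref, 0.5, 200, seed=1, correlation_blocks=[(calpha.atom_ids[:2], -1.0)]))
        d = dcc_matrix(traj, calpha)
        assert d.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_atoms_near_zero(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 10000, seed=2))
        d = dcc_matrix(traj, calpha)
        off = d.matrix[~np.eye(len(calpha), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_matches_bruteforce_oracle(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(
            ref, 0.4, 50, seed=3, correlation_blocks=[(calpha.atom_ids[:3], 0.6)]))
        d = dcc_matrix(traj, calpha)
        brute = oracle_dcc(traj, calpha.atom_ids)
        assert np.abs(d.matrix - brute).max() < 1e-10

    def test_symmetric_unit_diagonal_bounded(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 500, seed=4))
        d = dcc_matrix(traj, calpha)
        assert np.abs(d.matrix - d.matrix.T).max() < 1e-10
        assert np.allclose(np.diag(d.matrix), 1.0)
        assert np.nanmax(np.abs(d.matrix)) <= 1.0 + 1e-12

    def test_zero_variance_atom_masked(self, ref, calpha):
        coords = np.repeat(ref.coords[None], 20, axis=0)
        rng = np.random.default_rng(5)
        moving = calpha.atom_ids[1:]
        coords[:, moving, :] += rng.normal(0, 0.3, (20, len(moving), 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            d = dcc_matrix(Trajectory(coords, ref), calpha)
        assert np.isnan(d.matrix[0]).all()
        assert d.masked[0]

    def test_invariant_under_rigid_motion_after_fit(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(
            ref, 0.4, 300, seed=6, correlation_blocks=[(calpha.atom_ids[:2], 0.8)]))
        moved = apply_rigid_motion(traj, seed=7)
        f1, _ = average_structure(traj, calpha)
        f2, _ = average_structure(moved, calpha)
        d1 = dcc_matrix(f1, calpha)
        d2 = dcc_matrix(f2, calpha)
        assert np.abs(d1.matrix - d2.matrix).max() < 1e-6


class TestPCA:
    def test_constant_trajectory_zero_spectrum(self, ref, calpha):
        traj = Trajectory(np.repeat(ref.coords[None], 5, axis=0), ref)
        p = pca_decompose(traj, calpha)
        assert np.abs(p.eigenvalues).max() < 1e-12

    def test_planted_collective_axis_recovered(self, ref, calpha):
        rng = np.random.default_rng(8)
        n = 20000
        axis = rng.normal(size=3 * len(calpha))
        axis /= np.linalg.norm(axis)
        amp = rng.normal(0, 2.0, n)                       # variance 4 along axis
        noise = rng.normal(0, 0.5, (n, 3 * len(calpha)))  # 0.25 elsewhere
        X = amp[:, None] * axis[None] + noise
        coords = np.repeat(ref.coords[None], n, axis=0)
        coords[:, calpha.atom_ids, :] += X.reshape(n, len(calpha), 3)
        p = pca_decompose(Trajectory(coords, ref), calpha)
        assert p.eigenvalues[0] == pytest.approx(4.0 + 0.25, rel=0.05)
        angle = np.degrees(np.arccos(min(1.0, abs(p.eigenvectors[:, 0] @ axis))))
        assert angle < 5.0

    def test_projection_variance_equals_eigenvalue(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 400, seed=9))
        p = pca_decompose(traj, calpha)
        assert np.abs(p.projections.var(axis=0) - p.eigenvalues).max() < 1e-6

    def test_reconstruction_and_trace_identity(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 300, seed=10))
        p = pca_decompose(traj, calpha)
        X = (traj.coords[:, calpha.atom_ids, :] - p.mean_coords[None]).reshape(300, -1)
        assert np.abs(p.projections @ p.eigenvectors.T - X).max() < 1e-6
        total_var = X.var(axis=0).sum()
        assert p.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)
        assert p.contribution_fractions.sum() == pytest.approx(1.0, rel=1e-10)

    def test_orthonormal_eigenvectors(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 100, seed=11))
        p = pca_decompose(traj, calpha)
        gram = p.eigenvectors.T @ p.eigenvectors
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_excess_components_clamped_with_warning(self, ref, calpha):
        traj = make_harmonic_trajectory(HarmonicEnsembleSpec(ref, 0.5, 50, seed=12))
        with pytest.warns(UserWarning, match="clamped"):
            p = pca_decompose(traj, calpha, n_components=10_000)
        assert p.n_components == 3 * len(calpha)


class TestFEL:
    def test_uniform_occupancy_gives_zero_everywhere(self):
        # one sample at every bin center: every populated bin has P = P_max
        centers = (np.arange(10) + 0.5) / 10.0
        pc1 = np.repeat(centers, 10)
        pc2 = np.tile(centers, 10)
        g = fel_from_projections(pc1, pc2, 310.0, n_bins=10)
        assert np.isfinite(g.G).all()
        assert np.nanmax(np.abs(g.G)) == 0.0

    def test_half_count_bin_closed_form(self):
        pc1 = np.concatenate([np.zeros(1000), np.ones(500)])
        g = fel_from_projections(pc1, np.zeros(1500), 310.0, n_bins=2)
        kT = KB * 310.0
        assert np.nanmax(g.G) == pytest.approx(kT * np.log(2), rel=1e-10)
        assert np.nanmin(g.G) == 0.0

    def test_empty_bins_masked_not_finite(self):
        pc1 = np.concatenate([np.zeros(10), np.full(10, 10.0)])
        g = fel_from_projections(pc1, np.zeros(20), 300.0, n_bins=5)
        assert np.isnan(g.G[g.counts == 0]).all()
        assert np.isfinite(g.G[g.counts > 0]).all()
        assert (g.counts == 0).any() and (g.counts > 0).any()

    def test_sign_relabeling_mirrors_grid(self):
        rng = np.random.default_rng(13)
        pc1, pc2 = rng.normal(size=(2, 5000))
        g1 = fel_from_projections(pc1, pc2, 310.0, n_bins=20)
        g2 = fel_from_projections(-pc1, pc2, 310.0, n_bins=20)
        assert np.allclose(g1.G, g2.G[::-1, :], equal_nan=True)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            fel_from_projections(np.zeros(5), np.zeros(5), -1.0)

    def test_two_basin_gap_closed_form(self):
        ref = make_backbone_protein(10)
        shift = np.zeros_like(ref.coords)
        shift[:, 0] = 6.0 * np.where(np.arange(len(shift)) % 2 == 0, 1.0, -1.0)
        traj = make_two_basin_trajectory(TwoBasinSpec(
            ref, (ref.coords, ref.coords + shift), 0.8, 1.0, 50000, seed=14))
        ca = select_atoms(ref, "calpha")
        p = pca_decompose(traj, ca, 2)  # frames already share the generator frame
        g = fel_from_projections(p.projections[:, 0], p.projections[:, 1], 310.0)
        expected = KB * 310.0 * np.log(0.8 / 0.2)
        assert second_basin_gap(g) == pytest.approx(expected, rel=0.10)
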