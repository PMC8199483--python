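"""Hydrogen bonds, salt bridges, ligand contacts, SASA, block averaging."""

import numpy as np
import pytest

from enzdyn.interactions import (
    block_average_se,
    detect_hbonds,
    hb_stats,
    ligand_hb_occurrence,
    salt_bridge_occupancy,
    sasa,
    sasa_trajectory,
    solvent_hb_count,
)
from enzdyn.model import AtomSelection, Trajectory, select_atoms
from enzdyn.synthetic import (
    apply_rigid_motion,
    make_interaction_fixture,
    make_solvated_fixture,
)

from conftest import (
    build_model,
    oracle_dcc,  # noqa: F401  (used in test_collective)
    oracle_hbonds,
    oracle_salt_bridges,
    random_hbond_system,
    random_saltbridge_system,
    two_sphere_sasa,
)


def _dha_fixture(distance, angle_deg):
    """Donor N at origin, H on +x, acceptor placed at given D-A distance/angle."""
    theta = np.radians(angle_deg)
    s = np.cos(theta) + np.sqrt(max(distance ** 2 - np.sin(theta) ** 2, 0.0))
    h = np.array([1.0, 0.0, 0.0])
    v = np.array([-np.cos(theta), np.sin(theta), 0.0])
    a = h + s * v
    return build_model([
        ("ATOM", "N", "N", "ALA", 1, "A", (0.0, 0.0, 0.0)),
        ("ATOM", "H", "H", "ALA", 1, "A", tuple(h)),
        ("ATOM", "O", "O", "GLY", 2, "A", tuple(a)),
    ])


class TestHBondCriteria:
    @pytest.mark.parametrize("distance,angle,expected", [
        (2.8, 170.0, True),    # both criteria met
        (3.2, 180.0, False),   # distance fails
        (2.8, 120.0, False),   # angle fails
        (2.999, 135.5, True),  # just inside both
    ])
    def test_geometric_criteria(self, distance, angle, expected):
        model = _dha_fixture(distance, angle)
        traj = Trajectory(model.coords[None], model)
        donors = AtomSelection("d", np.array([0]))
        acceptors = AtomSelection("a", np.array([2]))
        events = detect_hbonds(traj, donors, acceptors)
        assert bool(events) is expected
        if expected:
            e = events[0]
            assert e.distance_DA == pytest.approx(distance, abs=1e-9)
            assert e.angle_at_H == pytest.approx(angle, abs=1e-6)

    def test_donor_without_hydrogen_is_error(self):
        model = build_model([
            ("ATOM", "N", "N", "ALA", 1, "A", (0, 0, 0)),
            ("ATOM", "O", "O", "GLY", 2, "A", (2.8, 0, 0)),
        ])
        traj = Trajectory(model.coords[None], model)
        with pytest.raises(ValueError, match="without an attached hydrogen"):
            detect_hbonds(traj, AtomSelection("d", np.array([0])),
                          AtomSelection("a", np.array([1])))

    def test_matches_bruteforce_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            model, traj = random_hbond_system(rng)
            donors = select_atoms(model, "donors")
            acceptors = select_atoms(model, "acceptors")
            events = detect_hbonds(traj, donors, acceptors)
            got = {(e.frame, e.donor_atom, e.hydrogen_atom, e.acceptor_atom)
                   for e in events}
            want = oracle_hbonds(traj, donors.atom_ids, acceptors.atom_ids)
            assert got == want


@pytest.fixture(scope="module")
def enumerable():
    model, traj = make_interaction_fixture(
        "hbond", {"n_frames": 10, "n_residues": 5,
                  "pairs": [{"occupancy": 1.0}, {"occupancy": 0.4}]}, seed=11)
    events = detect_hbonds(traj, select_atoms(model, "donors"),
                           select_atoms(model, "acceptors"))
    return model, events


class TestHBStats:
    def test_static_count(self, enumerable):
        model, events = enumerable
        stats = hb_stats(events, 10, 5, model)
        assert stats.static_count == pytest.approx(0.28, abs=1e-12)

    def test_dynamic_count(self, enumerable):
        model, events = enumerable
        stats = hb_stats(events, 10, 5, model)
        assert stats.dynamic_count == pytest.approx(0.4, abs=1e-12)

    def test_no_events_gives_zero(self, enumerable):
        model, _ = enumerable
        stats = hb_stats([], 10, 5, model)
        assert stats.static_count == 0.0 and stats.dynamic_count == 0.0

    def test_always_on_pair_static_is_inverse_length(self):
        model, traj = make_interaction_fixture(
            "hbond", {"n_frames": 8, "pairs": [{"occupancy": 1.0}]}, seed=12)
        events = detect_hbonds(traj, select_atoms(model, "donors"),
                               select_atoms(model, "acceptors"))
        n_res = len(model.residue_keys())
        stats = hb_stats(events, 8, n_res, model)
        assert stats.static_count == pytest.approx(1.0 / n_res, abs=1e-12)


class TestSolventHB:
    def test_three_always_bound_waters(self):
        model, traj = make_solvated_fixture(
            3, [{"occupancy": 1.0}] * 3, 20, seed=13)
        c = solvent_hb_count(traj, select_atoms(model, "protein"),
                             select_atoms(model, "solvent"))
        assert c == pytest.approx(3.0, abs=1e-12)

    def test_half_time_waters(self):
        model, traj = make_solvated_fixture(
            2, [{"occupancy": 0.5}, {"occupancy": 0.5}], 20, seed=14)
        c = solvent_hb_count(traj, select_atoms(model, "protein"),
                             select_atoms(model, "solvent"))
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_empty_solvent_is_error(self):
        model, traj = make_interaction_fixture(
            "hbond", {"n_frames": 4, "pairs": [{"occupancy": 1.0}]}, seed=15)
        with pytest.raises(ValueError, match="solvent"):
            solvent_hb_count(traj, select_atoms(model, "protein"),
                             AtomSelection("solvent", np.array([])))


class TestSaltBridges:
    def test_planted_occupancy(self):
        _, traj = make_interaction_fixture(
            "saltbridge", {"n_frames": 10, "pairs": [{"occupancy": 0.8}]}, seed=16)
        recs = salt_bridge_occupancy(traj)
        assert len(recs) == 1
        assert recs[0].occupancy == pytest.approx(80.0, abs=1e-12)

    def test_never_formed_pair_omitted(self):
        _, traj = make_interaction_fixture(
            "saltbridge",
            {"n_frames": 5, "pairs": [{"occupancy": 1.0, "on_distance": 4.5,
                                       "off_distance": 5.0}]}, seed=17)
        assert salt_bridge_occupancy(traj) == []

    def test_boundary_distance_counts_as_formed(self):
        # inclusive rule: a bridge at exactly the cutoff is formed
        _, traj = make_interaction_fixture(
            "saltbridge", {"n_frames": 4, "pairs": [{"occupancy": 1.0,
                                                     "on_distance": 4.0}]}, seed=18)
        recs = salt_bridge_occupancy(traj)
        assert recs[0].occupancy == 100.0

    def test_matches_bruteforce_on_random_systems(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            _, traj = random_saltbridge_system(rng)
            got = {(r.acidic_residue[:2], r.basic_residue[:2]): r.occupancy / 100
                   for r in salt_bridge_occupancy(traj)}
            want = oracle_salt_bridges(traj)
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12)


@pytest.fixture(scope="module")
def fixture():
    return make_interaction_fixture(
        "ligand", {"n_frames": 100, "pairs": [
            {"occupancy": 0.65, "subsite": "-1"},
            {"occupancy": 0.08, "subsite": "+2"},
        ]}, seed=19)


class TestLigandOccurrence:
    def test_planted_occurrence_recovered(self, fixture):
        model, traj = fixture
        table = ligand_hb_occurrence(traj, select_atoms(model, "ligand"),
                                     traj.metadata["subsite_map"])
        assert table.rows[0][2] == pytest.approx(65.0, abs=1e-12)
        assert table.rows[0][1] == "-1"

    def test_subthreshold_row_suppressed_but_available(self, fixture):
        model, traj = fixture
        table = ligand_hb_occurrence(traj, select_atoms(model, "ligand"),
                                     traj.metadata["subsite_map"])
        assert len(table.rows) == 1
        assert any(pct == pytest.approx(8.0) for *_, pct in table.all_rows)
        full = ligand_hb_occurrence(traj, select_atoms(model, "ligand"),
                                    traj.metadata["subsite_map"],
                                    suppress_below_threshold=False)
        assert len(full.rows) == 2

    def test_exact_threshold_row_reported(self, fixture):
        model, traj = fixture
        table = ligand_hb_occurrence(traj, select_atoms(model, "ligand"),
                                     traj.metadata["subsite_map"], threshold=8.0)
        assert len(table.rows) == 2

    def test_missing_subsite_is_error(self, fixture):
        model, traj = fixture
        with pytest.raises(KeyError, match="subsite"):
            ligand_hb_occurrence(traj, select_atoms(model, "ligand"), {100: "-1"})

    def test_no_ligand_is_error(self, fixture):
        model, traj = fixture
        with pytest.raises(ValueError, match="ligand"):
            ligand_hb_occurrence(traj, AtomSelection("ligand", np.array([])), {})


class TestSASA:
    def _atom(self, element="C", pos=(0, 0, 0), name="C1"):
        return ("HETATM", name, element, "UNK", 1, "A", pos)

    def test_isolated_atom_analytic_sphere(self):
        model = build_model([self._atom()])
        r = sasa(model)
        assert r.total_area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        model = build_model([self._atom(pos=(0, 0, 0)),
                             ("HETATM", "C2", "C", "UNK", 2, "A", (100.0, 0, 0))])
        r = sasa(model)
        assert r.total_area == pytest.approx(2 * 4 * np.pi * 3.1 ** 2, rel=0.01)
        assert r.total_area == pytest.approx(r.per_atom_area.sum(), rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_overlap_closed_form(self, d):
        model = build_model([self._atom(pos=(0, 0, 0)),
                             ("HETATM", "C2", "C", "UNK", 2, "A", (d, 0.0, 0.0))])
        r = sasa(model)
        exact = two_sphere_sasa(3.1, 3.1, d)
        assert r.total_area == pytest.approx(exact, rel=0.01)

    def test_rigid_motion_invariance(self):
        model, traj = make_interaction_fixture(
            "saltbridge", {"n_frames": 6, "pairs": [{"occupancy": 0.5}]}, seed=20)
        moved = apply_rigid_motion(traj, seed=21)
        for f in range(traj.n_frames):
            a = sasa(model, traj.coords[f]).total_area
            b = sasa(model, moved.coords[f]).total_area
            assert abs(a - b) / a < 1e-3

    def test_trajectory_mean_and_se(self):
        model, traj = make_interaction_fixture(
            "saltbridge", {"n_frames": 8, "pairs": [{"occupancy": 0.5}]}, seed=22)
        r = sasa_trajectory(traj)
        per_frame = [sasa(model, traj.coords[f]).total_area for f in range(8)]
        assert r.total_area == pytest.approx(np.mean(per_frame), rel=1e-12)
        assert r.standard_error >= 0


class TestBlockAverageSE:
    def test_iid_matches_naive_se(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 10000)
        b = block_average_se(x)
        assert b.value == pytest.approx(2.0 / np.sqrt(10000), rel=0.2)
        assert b.converged

    def test_constant_series_zero(self):
        b = block_average_se(np.full(64, 3.14))
        assert b.value == 0.0

    def test_ar1_inflation_recovered(self):
        # AR(1): true SE of the mean is (sd/sqrt(n)) * sqrt((1+phi)/(1-phi))
        phi, n = 0.9, 20000
        rng = np.random.default_rng(2)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        sd = x.std(ddof=1)
        expected = sd / np.sqrt(n) * np.sqrt((1 + phi) / (1 - phi))
        b = block_average_se(x)
        assert b.value == pytest.approx(expected, rel=0.3)

    def test_too_short_series_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            block_average_se(np.array([1.0, 2.0]))
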