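"""Data model, periodic geometry, and structure/trajectory I/O."""

import numpy as np
import pytest

from crowdbind import (BoxGeometry, MolecularSystem, Role, Trajectory,
                       load_structure, load_trajectory, min_image_distance,
                       read_system, write_system, write_trajectory)
from crowdbind.io import PDBParseError, RoleRuleError
from crowdbind.system import SystemError_, TrajectoryError


class TestMinImage:
    def test_zero_for_identical_points(self):
        box = BoxGeometry((10.0, 10.0, 10.0))
        assert min_image_distance([1, 2, 3], [1, 2, 3], box) == 0.0

    def test_wrap_across_boundary(self):
        box = BoxGeometry((10.0, 10.0, 10.0))
        assert min_image_distance([0, 0, 0], [9, 0, 0], box) == pytest.approx(1.0)

    def test_non_periodic_is_euclidean(self):
        box = BoxGeometry((10.0, 10.0, 10.0), periodic=False)
        assert min_image_distance([0, 0, 0], [9, 0, 0], box) == pytest.approx(9.0)

    def test_matches_27_image_brute_force(self):
        rng = np.random.default_rng(0)
        L = np.array([10.0, 14.0, 8.0])
        box = BoxGeometry(tuple(L))
        shifts = np.array([[i, j, k] for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)]) * L
        for _ in range(200):
            a = rng.uniform(0, L)
            b = rng.uniform(0, L)
            brute = min(np.linalg.norm(b + s - a) for s in shifts)
            assert min_image_distance(a, b, box) == pytest.approx(brute, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        box = BoxGeometry((7.0, 9.0, 11.0))
        a, b = rng.uniform(0, 7, 3), rng.uniform(0, 7, 3)
        assert min_image_distance(a, b, box) == pytest.approx(
            min_image_distance(b, a, box))


def _simple_system(roles, elements=None):
    n = len(roles)
    elements = elements or ["C"] * n
    return MolecularSystem(
        element=np.array(elements, dtype=object),
        heavy_atom=np.array([e != "H" for e in elements]),
        res_name=np.array(["RES"] * n, dtype=object),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n, dtype=object),
        molecule_id=np.arange(n),
        role=np.array(roles, dtype=object),
    )


class TestMolecularSystem:
    def test_exactly_one_target_enforced(self):
        with pytest.raises(SystemError_):
            _simple_system([Role.TARGET, Role.TARGET])
        with pytest.raises(SystemError_):
            _simple_system([Role.CROWDER, Role.LIGAND])

    def test_heavy_flag_must_track_hydrogen(self):
        with pytest.raises(SystemError_):
            MolecularSystem(
                element=np.array(["C", "H"], dtype=object),
                heavy_atom=np.array([True, True]),  # H marked heavy
                res_name=np.array(["R", "R"], dtype=object),
                res_id=np.array([1, 1]),
                chain_id=np.array(["A", "A"], dtype=object),
                molecule_id=np.array([0, 0]),
                role=np.array([Role.TARGET, Role.TARGET], dtype=object),
            )

    def test_counts_per_role(self):
        s = _simple_system([Role.TARGET, Role.LIGAND, Role.LIGAND])
        counts = s.counts_per_role()
        assert counts[Role.TARGET] == 1
        assert counts[Role.LIGAND] == 2


class TestLoadStructure:
    def test_single_chain_target(self, toy_pdb_one_chain):
        system, coords = load_structure(toy_pdb_one_chain,
                                        chain_roles={"A": "TARGET"})
        assert system.n_atoms == 3
        assert coords.shape == (3, 3)
        assert system.counts_per_role()[Role.TARGET] == 1
        assert len(system.molecules(Role.TARGET)) == 1

    def test_two_chain_partition_matches_hand_count(self, toy_pdb_two_chain):
        system, coords = load_structure(
            toy_pdb_two_chain, chain_roles={"A": "TARGET", "B": "LIGAND"})
        # hand count of the fixture: 5 atoms in chain A, 2 in chain B
        assert system.n_atoms == 7
        assert int(system.role_mask(Role.TARGET).sum()) == 5
        assert int(system.role_mask(Role.LIGAND).sum()) == 2
        assert len(system.molecules()) == 2

    def test_hydrogens_flagged_light(self, toy_pdb_two_chain):
        system, _ = load_structure(
            toy_pdb_two_chain, chain_roles={"A": "TARGET", "B": "LIGAND"})
        is_h = np.array([e == "H" for e in system.element])
        assert np.array_equal(~np.asarray(system.heavy_atom), is_h)
        assert is_h.sum() == 1

    def test_unassigned_chain_is_an_error(self, toy_pdb_two_chain):
        with pytest.raises(RoleRuleError):
            load_structure(toy_pdb_two_chain, chain_roles={"A": "TARGET"})

    def test_residue_rule_overrides_chain_rule(self, toy_pdb_two_chain):
        system, _ = load_structure(toy_pdb_two_chain,
                                   chain_roles={"A": "TARGET", "B": "TARGET"},
                                   residue_roles={"LIG": "LIGAND"})
        assert int(system.role_mask(Role.LIGAND).sum()) == 2

    def test_malformed_atom_line(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM      1  N   ALA A   1      xx.xxx   6.134"
                       "  -6.504  1.00  0.00           N\nEND\n")
        with pytest.raises(PDBParseError):
            load_structure(bad, chain_roles={"A": "TARGET"})


def _tiny_trajectory(n_frames=2, n_atoms=3, dt=0.5, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 20, size=(n_frames, n_atoms, 3))
    return Trajectory(coords, np.full((n_frames, 3), 20.0), dt)


class TestTrajectoryIO:
    def test_round_trip_to_six_decimals(self, tmp_path):
        traj = _tiny_trajectory(n_frames=4, n_atoms=5)
        path = tmp_path / "t.traj"
        write_trajectory(path, traj)
        back = load_trajectory(path)
        assert back.n_frames == 4
        assert back.dt_ps == traj.dt_ps
        np.testing.assert_allclose(back.coords, traj.coords, atol=5e-7)
        np.testing.assert_allclose(back.box_lengths, traj.box_lengths)

    def test_frame_count_read(self, tmp_path):
        path = tmp_path / "t.traj"
        write_trajectory(path, _tiny_trajectory(n_frames=2, n_atoms=3))
        assert load_trajectory(path).n_frames == 2

    def test_atom_count_mismatch_vs_system(self, tmp_path, free_box):
        _, _, system, _ = free_box
        path = tmp_path / "t.traj"
        write_trajectory(path, _tiny_trajectory(n_atoms=3))
        with pytest.raises(TrajectoryError, match="atoms"):
            load_trajectory(path, system)

    def test_extra_coordinate_line_detected(self, tmp_path):
        path = tmp_path / "t.traj"
        write_trajectory(path, _tiny_trajectory(n_frames=1, n_atoms=4))
        text = path.read_text().replace("natoms 4", "natoms 3")
        path.write_text(text)
        with pytest.raises(TrajectoryError):
            load_trajectory(path)

    def test_non_monotonic_times_rejected(self, tmp_path):
        path = tmp_path / "t.traj"
        write_trajectory(path, _tiny_trajectory(n_frames=3, n_atoms=2))
        text = path.read_text().replace("frame 2 time_ps 1.000000",
                                        "frame 2 time_ps 0.200000")
        path.write_text(text)
        with pytest.raises(TrajectoryError, match="increasing"):
            load_trajectory(path)

    def test_system_json_round_trip(self, tmp_path, free_box):
        _, _, system, _ = free_box
        path = tmp_path / "sys.json"
        write_system(path, system)
        back = read_system(path)
        assert back.n_atoms == system.n_atoms
        assert all(a is b for a, b in zip(back.role, system.role))
        np.testing.assert_allclose(back.radius_offset, system.radius_offset)


class TestTrajectoryInvariants:
    def test_positive_box_required(self):
        with pytest.raises(TrajectoryError):
            Trajectory(np.zeros((1, 2, 3)), np.array([[10.0, -1.0, 10.0]]), 1.0)

    def test_positive_spacing_required(self):
        with pytest.raises(TrajectoryError):
            Trajectory(np.zeros((1, 2, 3)), np.full((1, 3), 10.0), 0.0)
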