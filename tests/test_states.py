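"""Two-state sidechain analysis, pseudo-torsions, RMSF, and contact counts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crowdbind import (MolecularSystem, Role, Trajectory, ca_contact_count,
                       classify_two_state, dihedral, generate_sidechain_series,
                       population_shift_table, pseudo_torsion, rmsf)
from crowdbind.states import StateSeries
from crowdbind.synthetic import STATE_IN, STATE_OUT


def _traj(frames, box=100.0, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames, np.full((frames.shape[0], 3), box), dt)


class TestClassifyTwoState:
    def test_constant_series_all_in(self):
        series, pops = classify_two_state(np.full(50, 5.0),
                                          method="threshold", threshold=6.5)
        assert pops.in_pct == 100.0
        assert np.all(series.states == STATE_IN)

    def test_mixture_recovers_bimodal_modes(self):
        """EM mixture on 5.0/8.5 Å bimodal data (SD 0.5) recovers both
        component means within 3 standard errors."""
        d, s = generate_sidechain_series(5.0, 8.5, 0.5, 50, 50, 10000,
                                         seed=21)
        _, pops = classify_two_state(d, method="mixture")
        n_in = (s == STATE_IN).sum()
        n_out = len(s) - n_in
        assert abs(pops.mean_in - 5.0) < 3 * 0.5 / np.sqrt(n_in)
        assert abs(pops.mean_out - 8.5) < 3 * 0.5 / np.sqrt(n_out)

    def test_mixture_labels_agree_with_truth(self):
        """Modes 7 SD apart: maximum-posterior labels match the generating
        states in at least 99% of frames (Bayes error is ~0.02%)."""
        d, s = generate_sidechain_series(5.0, 8.5, 0.5, 30, 30, 8000,
                                         seed=17)
        series, _ = classify_two_state(d, method="mixture")
        agree = (series.states == s).mean()
        assert agree >= 0.99

    def test_mixture_means_bracket_threshold(self):
        d, _ = generate_sidechain_series(5.0, 8.5, 0.5, 30, 30, 5000,
                                         seed=2)
        _, pops = classify_two_state(d, method="mixture")
        assert pops.mean_in < 6.5 < pops.mean_out

    def test_degenerate_mixture_falls_back(self):
        rng = np.random.default_rng(0)
        d = 5.0 + 1e-8 * rng.normal(size=500)   # effectively constant
        with pytest.warns(UserWarning, match="degenerate"):
            series, pops = classify_two_state(d, method="mixture")
        assert series.rule.startswith("threshold")
        assert pops.in_pct == 100.0

    def test_mixture_needs_enough_frames(self):
        with pytest.raises(ValueError):
            classify_two_state(np.ones(50), method="mixture")


class TestPopulationShift:
    def _series(self, out_pct, n=1000):
        states = np.zeros(n, dtype=np.int8)
        states[:int(n * out_pct / 100)] = STATE_OUT
        return StateSeries(np.zeros(n), states, "given")

    def test_hand_read_table(self):
        series = {f"s{c}": self._series(p)
                  for c, p in zip((0, 2, 4, 8), (10, 30, 55, 80))}
        counts = {f"s{c}": c for c in (0, 2, 4, 8)}
        rows, trend = population_shift_table(series, counts)
        assert [r[1] for r in rows] == [0, 2, 4, 8]
        assert trend["out_pct_non_decreasing"]
        assert trend["majority_switch_at_crowders"] == 4
        for _, _, pops in rows:
            assert pops.in_pct + pops.out_pct == pytest.approx(100.0)

    def test_flat_trend_detected(self):
        series = {f"s{c}": self._series(40) for c in (0, 2)}
        _, trend = population_shift_table(series, {"s0": 0, "s2": 2})
        assert trend["flat"]

    def test_contact_scaled_gate_shifts_out_upward(self):
        """Gate series from the crowded-box generator: the extended-state
        fraction must grow with the crowder count."""
        from crowdbind import SynthConfig, simulate_crowded_box
        from crowdbind.synthetic import sidechain_series_from_gate

        out_pct = []
        for n in (0, 4, 8):
            cfg = SynthConfig(seed=31, box_length=120.0, n_crowders=n,
                              target_radius=15.0, crowder_radius=18.0,
                              n_ligands=2, n_steps=12000, eps=0.0,
                              eps_pocket=0.0, k_open=0.02, k_close=0.06)
            _, _, truth = simulate_crowded_box(cfg)
            out_pct.append(100.0 * truth.gate_open.mean())
        assert out_pct[0] < out_pct[1] < out_pct[2], out_pct

    def test_needs_two_systems(self):
        with pytest.raises(ValueError):
            population_shift_table({"a": self._series(10)}, {"a": 0})


def _praxeolitic_dihedral(p0, p1, p2, p3):
    """Independent dihedral oracle using the projection formulation."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return np.degrees(np.arctan2(y, x))


class TestPseudoTorsion:
    CIS = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
           np.array([2.0, 0, 0]), np.array([1.0, 1, 0]) + [2, 0, 0]]

    def test_planar_cis_zero(self):
        assert dihedral(*self.CIS) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_180(self):
        p3 = np.array([3.0, -1.0, 0.0])
        assert abs(dihedral(self.CIS[0], self.CIS[1], self.CIS[2], p3)) \
            == pytest.approx(180.0)

    def test_matches_independent_formulation(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3.0
            got = dihedral(*pts)
            expect = _praxeolitic_dihedral(*pts)
            if np.isnan(got):
                continue
            assert got == pytest.approx(expect, abs=1e-6) or \
                abs(abs(got) - 180.0) < 1e-6

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(4, 3)) * 2.0
        ref = dihedral(*pts)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            moved = rot.apply(pts) + [3.0, -1.0, 2.0]
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)

    def test_collinear_gives_nan_frame(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                         [3.0, 0, 0]])
        traj = _traj(line[None, :, :])
        out = pseudo_torsion(traj, [[0], [1], [2], [3]])
        assert np.isnan(out[0])

    def test_group_centroids_used(self):
        pts = np.array([[1.0, 1, 0], [0.0, 0, 0], [2.0, 0, 0],
                        [3.0, 1, 0], [3.0, 1, 0]])
        traj = _traj(pts[None, :, :])
        out = pseudo_torsion(traj, [[0], [1], [2], [3, 4]])
        assert out[0] == pytest.approx(
            dihedral(pts[0], pts[1], pts[2], pts[3]), abs=1e-10)


class TestRMSF:
    def test_static_structure_zero(self):
        frames = np.tile(np.random.default_rng(0).normal(size=(1, 5, 3)),
                         (4, 1, 1))
        np.testing.assert_allclose(rmsf(_traj(frames)), 0.0, atol=1e-12)

    def test_oscillating_atom_closed_form(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = [1.0, -1.0, 1.0, -1.0]
        out = rmsf(_traj(frames))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)

    def test_matches_two_pass_variance(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(20, 6, 3))
        out = rmsf(_traj(frames))
        mean = frames.mean(axis=0)
        expect = np.sqrt(((frames - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(out, expect)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            rmsf(_traj(np.zeros((1, 2, 3))))


class TestCaContacts:
    def _sys(self, roles, names, mols):
        n = len(roles)
        return MolecularSystem(
            element=np.array(["C"] * n, dtype=object),
            heavy_atom=np.ones(n, dtype=bool),
            res_name=np.array(["R"] * n, dtype=object),
            res_id=np.arange(1, n + 1),
            chain_id=np.array(["A"] * n, dtype=object),
            molecule_id=np.array(mols),
            role=np.array(roles, dtype=object),
            atom_name=np.array(names, dtype=object),
        )

    def test_far_apart_zero(self):
        sys_ = self._sys([Role.TARGET, Role.CROWDER], ["CA", "CA"], [0, 1])
        frames = np.tile(np.array([[[0.0, 0, 0], [30.0, 0, 0]]]), (3, 1, 1))
        out = ca_contact_count(_traj(frames), sys_, cutoff=8.0)
        assert out["mean_contacts"] == 0.0

    def test_persistent_pair_counts_one(self):
        sys_ = self._sys([Role.TARGET, Role.CROWDER], ["CA", "CA"], [0, 1])
        frames = np.tile(np.array([[[0.0, 0, 0], [7.0, 0, 0]]]), (5, 1, 1))
        out = ca_contact_count(_traj(frames), sys_, cutoff=8.0)
        assert out["mean_contacts"] == pytest.approx(1.0)

    def test_matches_brute_force_and_state_split(self):
        rng = np.random.default_rng(20)
        roles = [Role.TARGET] * 3 + [Role.CROWDER] * 4
        names = ["CA", "CB", "CA", "CA", "CA", "CB", "CA"]
        sys_ = self._sys(roles, names, [0, 0, 0, 1, 1, 2, 2])
        frames = rng.uniform(0, 25, size=(12, 7, 3))
        traj = _traj(frames, box=25.0)
        out = ca_contact_count(traj, sys_, cutoff=8.0)

        from crowdbind.system import BoxGeometry, min_image_distance
        box = BoxGeometry((25.0,) * 3)
        t_idx = [0, 2]
        c_idx = [3, 4, 6]
        per_frame = []
        for f in range(12):
            n = sum(min_image_distance(frames[f, i], frames[f, j], box) <= 8
                    for i in t_idx for j in c_idx)
            per_frame.append(n)
        assert out["mean_contacts"] == pytest.approx(np.mean(per_frame))

        states = StateSeries(np.zeros(12),
                             np.array([0, 1] * 6, dtype=np.int8), "alt")
        split = ca_contact_count(traj, sys_, cutoff=8.0, states=states)
        assert split["mean_contacts_in"] == pytest.approx(
            np.mean(per_frame[0::2]))
        assert split["mean_contacts_out"] == pytest.approx(
            np.mean(per_frame[1::2]))

    def test_missing_marker_atoms_error(self):
        sys_ = self._sys([Role.TARGET, Role.CROWDER], ["CB", "CA"], [0, 1])
        with pytest.raises(ValueError, match="CA"):
            ca_contact_count(_traj(np.zeros((1, 2, 3))), sys_)
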