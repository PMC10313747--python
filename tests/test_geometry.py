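"""Superposition, RMSD/RMSF and gate-distance metrics."""

import numpy as np
import pytest

from siefel import (
    ConformationThresholds,
    SelectionSpec,
    Trajectory,
    centroid_distance_series,
    classify_conformation,
    kabsch_superpose,
    rmsd_series,
    rmsf_per_residue,
)
from siefel.geometry import GeometryError
from toyutil import make_atom, random_rotation, topology_from_atoms


class TestKabsch:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        shifted = pts + np.array([5.0, -3.0, 2.0])
        res = kabsch_superpose(shifted, pts)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.apply(shifted), pts, atol=1e-12)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_known_rotation_recovered(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        R = random_rotation(rng)
        t = rng.normal(size=3)
        res = kabsch_superpose(pts @ R.T + t, pts)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.rotation, R.T, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-12)
        assert res.rmsd > 0.1  # a mirror image cannot be superposed exactly

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


def _two_frame_toy():
    """4 non-collinear anchors (res 1-4) + 2 probe atoms (res 5-6)."""
    anchors = [make_atom(1, (0, 0, 0)), make_atom(2, (3.8, 0, 0)),
               make_atom(3, (0, 3.8, 0)), make_atom(4, (0, 0, 3.8))]
    probes = [make_atom(5, (10, 0, 0), res_seq=5),
              make_atom(6, (0, 10, 0), res_seq=6)]
    top = topology_from_atoms(anchors + probes)
    base = top.coords()
    moved = base.copy()
    moved[4] += [1.0, 0.0, 0.0]
    moved[5] += [0.0, 2.0, 0.0]
    frames = np.stack([base, moved])
    return top, Trajectory(topology=top, frames=frames,
                           times=np.array([0.0, 10.0]))


class TestRMSDSeries:
    def test_constant_trajectory_is_zero(self, toy, gate_traj):
        static = Trajectory(topology=toy.topology,
                            frames=np.repeat(toy.topology.coords()[None], 3, 0),
                            times=np.arange(3.0))
        fit = SelectionSpec("1-60", atom_names=("CA",))
        df = rmsd_series(static, toy.topology.coords(), fit, fit)
        np.testing.assert_allclose(df["rmsd_A"], 0.0, atol=1e-12)

    def test_inflated_reference_strictly_positive(self, toy):
        base = toy.topology.coords()
        centroid = base.mean(axis=0)
        inflated = centroid + (base - centroid) * 1.01
        static = Trajectory(topology=toy.topology,
                            frames=base[None], times=np.array([0.0]))
        fit = SelectionSpec("1-60", atom_names=("CA",))
        df = rmsd_series(static, inflated, fit, fit)
        assert np.all(df["rmsd_A"] > 0)

    def test_matches_hand_calculation(self):
        """Anchored fit: RMSD is exactly sqrt(mean squared displacement)."""
        top, traj = _two_frame_toy()
        df = rmsd_series(traj, traj.frames[0],
                         fit_sel=SelectionSpec("1-4"),
                         measure_sel=SelectionSpec("5-6"))
        assert df["rmsd_A"][0] == pytest.approx(0.0, abs=1e-12)
        assert df["rmsd_A"][1] == pytest.approx(np.sqrt((1.0 + 4.0) / 2), abs=1e-9)

    def test_invariant_to_rigid_motion_of_frame(self):
        top, traj = _two_frame_toy()
        rng = np.random.default_rng(9)
        R = random_rotation(rng)
        moved = Trajectory(topology=top, frames=traj.frames @ R.T + 7.0,
                           times=traj.times)
        sel = SelectionSpec("1-6")
        a = rmsd_series(traj, traj.frames[0], sel, sel)["rmsd_A"]
        b = rmsd_series(moved, traj.frames[0], sel, sel)["rmsd_A"]
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestRMSF:
    def test_static_trajectory_zero(self, toy):
        static = Trajectory(topology=toy.topology,
                            frames=np.repeat(toy.topology.coords()[None], 4, 0),
                            times=np.arange(4.0))
        sel = SelectionSpec("1-60", atom_names=("CA",))
        df = rmsf_per_residue(static, sel, sel)
        np.testing.assert_allclose(df["rmsf_A"], 0.0, atol=1e-12)

    def test_isotropic_jitter_matches_sqrt3_sigma(self):
        """Per-coordinate sigma=0.5 gives RMSF ~ sqrt(3)*0.5 within 3%."""
        sigma, n_frames = 0.5, 5000
        anchors = [make_atom(1, (0, 0, 0)), make_atom(2, (3.8, 0, 0)),
                   make_atom(3, (0, 3.8, 0)), make_atom(4, (0, 0, 3.8))]
        probes = [make_atom(10 + k, (20.0 + 8 * k, 15.0, 0), res_seq=10 + k)
                  for k in range(3)]
        top = topology_from_atoms(anchors + probes)
        base = top.coords()
        rng = np.random.default_rng(42)
        frames = np.repeat(base[None], n_frames, axis=0)
        frames[:, 4:, :] += rng.normal(0, sigma, size=(n_frames, 3, 3))
        traj = Trajectory(topology=top, frames=frames,
                          times=np.arange(n_frames, dtype=float))
        df = rmsf_per_residue(traj, SelectionSpec("10-12"), SelectionSpec("1-4"))
        expected = np.sqrt(3.0) * sigma
        np.testing.assert_allclose(df["rmsf_A"], expected, rtol=0.03)

    def test_only_mobile_residue_fluctuates(self):
        anchors = [make_atom(1, (0, 0, 0)), make_atom(2, (3.8, 0, 0)),
                   make_atom(3, (0, 3.8, 0)), make_atom(4, (0, 0, 3.8))]
        mobile = [make_atom(9, (25.0, 14.0, 3.0), res_seq=9)]
        top = topology_from_atoms(anchors + mobile)
        frames = np.repeat(top.coords()[None], 50, axis=0)
        rng = np.random.default_rng(3)
        frames[:, 4, :] += rng.normal(0, 0.4, size=(50, 3))
        traj = Trajectory(topology=top, frames=frames,
                          times=np.arange(50.0))
        df = rmsf_per_residue(traj, SelectionSpec("1-9"), SelectionSpec("1-4"))
        by_res = df.set_index("residue_seq")["rmsf_A"]
        assert by_res[9] > 0.2
        assert (by_res.drop(9) < 1e-9).all()

    def test_single_frame_rejected(self, toy):
        static = Trajectory(topology=toy.topology,
                            frames=toy.topology.coords()[None],
                            times=np.array([0.0]))
        sel = SelectionSpec("1-60", atom_names=("CA",))
        with pytest.raises(GeometryError):
            rmsf_per_residue(static, sel, sel)


class TestCentroidDistance:
    def test_two_single_atoms(self):
        top = topology_from_atoms([make_atom(1, (0, 0, 0), res_seq=1),
                                   make_atom(2, (0, 0, 19.0), res_seq=2),
                                   make_atom(3, (5, 5, 5), res_seq=3)])
        traj = Trajectory(topology=top, frames=top.coords()[None],
                          times=np.array([0.0]))
        df = centroid_distance_series(traj, SelectionSpec("1"), SelectionSpec("2"))
        assert df["distance_A"][0] == pytest.approx(19.0)

    def test_symmetric_under_swap(self, gate_traj):
        a = SelectionSpec("16-26", atom_names=("CA",))
        b = SelectionSpec("41-51", atom_names=("CA",))
        d1 = centroid_distance_series(gate_traj, a, b)["distance_A"]
        d2 = centroid_distance_series(gate_traj, b, a)["distance_A"]
        np.testing.assert_array_equal(d1, d2)

    def test_gate_series_mean_between_basins(self, gate_traj):
        a = SelectionSpec("16-26", atom_names=("CA",))
        b = SelectionSpec("41-51", atom_names=("CA",))
        d = centroid_distance_series(gate_traj, a, b)["distance_A"]
        assert 19.0 < d.mean() < 22.0

    def test_invariant_when_both_selections_transformed(self, gate_traj):
        rng = np.random.default_rng(13)
        R = random_rotation(rng)
        moved = Trajectory(topology=gate_traj.topology,
                           frames=gate_traj.frames @ R.T + np.array([3, -8, 1.0]),
                           times=gate_traj.times)
        a = SelectionSpec("16-26", atom_names=("CA",))
        b = SelectionSpec("41-51", atom_names=("CA",))
        d1 = centroid_distance_series(gate_traj, a, b)["distance_A"]
        d2 = centroid_distance_series(moved, a, b)["distance_A"]
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestClassifyConformation:
    @pytest.mark.parametrize("distance,label", [
        (22.00, "open"),
        (19.00, "close"),
        (20.50, "open"),   # boundary tie goes to open
        (20.49, "close"),
    ])
    def test_labels(self, distance, label):
        assert classify_conformation(distance) == label

    def test_array_input(self):
        labels = classify_conformation(np.array([18.0, 23.0, 20.5]))
        assert list(labels) == ["close", "open", "open"]

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(GeometryError):
            classify_conformation(0.0)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ConformationThresholds(d_open=19.0, d_close=22.0, boundary=20.5)
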