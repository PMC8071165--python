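"""Superposition, RMSD/RMSF/distance series, clustering and helix rotations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cxcaxis as cx
from cxcaxis.errors import DegenerateGeometryError, ValidationError
from cxcaxis.io import Trajectory
from cxcaxis.metrics import (_superpose_frames, kabsch_superpose,
                             neighbor_cluster, pairwise_rmsd_matrix)

TRIANGLE = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def _sub_traj(topology, frames):
    return Trajectory(topology=topology, frames=np.asarray(frames, float),
                      times=np.arange(len(frames), dtype=float))


class TestKabsch:
    def test_identity(self):
        tf = kabsch_superpose(TRIANGLE, TRIANGLE)
        assert tf.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert tf.rmsd_after == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation(self):
        tf = kabsch_superpose(TRIANGLE + [5.0, 0.0, 0.0], TRIANGLE)
        assert tf.rmsd_after == pytest.approx(0.0, abs=1e-9)
        assert tf.angle_deg == pytest.approx(0.0, abs=1e-7)

    def test_90_degree_rotation_about_z(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        mobile = rot.apply(TRIANGLE)
        tf = kabsch_superpose(mobile, TRIANGLE)
        assert tf.rmsd_after == pytest.approx(0.0, abs=1e-9)
        assert tf.angle_deg == pytest.approx(90.0, abs=1e-7)
        assert abs(abs(tf.axis[2]) - 1.0) < 1e-7
        # brute-force scan over z-rotations confirms 90 deg is the minimum
        errs = {a: np.abs(Rotation.from_euler("z", a, degrees=True).apply(mobile)
                          - TRIANGLE).max()
                for a in range(0, 360, 10)}
        assert min(errs, key=errs.get) == 270  # inverse rotation: -90 mod 360

    def test_rotation_matrix_is_proper(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        tf = kabsch_superpose(a, b)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-8)
        trace_angle = np.degrees(
            np.arccos(np.clip((np.trace(tf.rotation) - 1) / 2, -1, 1)))
        assert tf.angle_deg == pytest.approx(trace_angle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_angle_symmetric_between_directions(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        fwd = kabsch_superpose(a, b).angle_deg
        rev = kabsch_superpose(b, a).angle_deg
        assert fwd == pytest.approx(rev, abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(TRIANGLE[:2], TRIANGLE[:2])

    def test_collinear_points(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_planted_180_degree_flip(self):
        rot = Rotation.from_euler("x", 180, degrees=True)
        tf = kabsch_superpose(rot.apply(TRIANGLE), TRIANGLE)
        assert tf.angle_deg == pytest.approx(180.0, abs=1e-6)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self, bundle):
        angles = {"TM1": np.array([0.0, 10.0, 20.0])}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=1)
        sel = cx.select_atoms(bundle, "TM1", "CA")
        series = cx.rmsd_series(traj, sel, sel, reference_frame=0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_removed_by_fit(self, bundle):
        sel = cx.select_atoms(bundle, "TM1", "CA")
        frames = [bundle.coords + np.array([i * 3.0, -i, 2.0 * i])
                  for i in range(4)]
        traj = _sub_traj(bundle, frames)
        series = cx.rmsd_series(traj, sel, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_hand_computed_displacement(self):
        """One of two analysis atoms displaced by (3,4,0) with a fixed fit
        frame gives RMSD 5/sqrt(2)."""
        from conftest import build_structure

        base = build_structure([
            ("A", i + 1, "GLY", {"CA": xyz}) for i, xyz in enumerate([
                (0, 0, 0), (10, 0, 0), (0, 10, 0), (10, 10, 0),  # fit anchor
                (20, 0, 0), (21, 5, 0),                          # analysis pair
            ])
        ])
        moved = base.coords.copy()
        moved[4] += np.array([3.0, 4.0, 0.0])
        traj = _sub_traj(base, [base.coords, moved])
        series = cx.rmsd_series(traj, [4, 5], [0, 1, 2, 3])
        assert series.values[1] == pytest.approx(5.0 / np.sqrt(2), abs=1e-9)

    def test_invariance_under_common_rigid_transform(self, bundle):
        angles = {"TM3": np.array([0.0, 12.0, 24.0])}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=5)
        sel = cx.select_atoms(bundle, "TM3", "CA")
        rot = Rotation.from_euler("xyz", [30, -50, 110], degrees=True)
        moved = np.array([rot.apply(f) + [7.0, -3.0, 11.0] for f in traj.frames])
        a = cx.rmsd_series(traj, sel, sel).values
        b = cx.rmsd_series(_sub_traj(bundle, moved), sel, sel).values
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestRmsf:
    def test_static_trajectory_is_zero(self, bundle):
        traj = _sub_traj(bundle, [bundle.coords] * 3)
        sel = cx.select_atoms(bundle, "TM2", "CA")
        series = cx.rmsf_profile(traj, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)
        assert series.x_kind == "residue"

    def test_alternating_atom_has_unit_rmsf(self):
        from conftest import build_structure

        base = build_structure([
            ("A", i + 1, "GLY", {"CA": xyz}) for i, xyz in enumerate([
                (0, 0, 0), (10, 0, 0), (0, 10, 0), (10, 10, 0), (5, 5, 8),
            ])
        ])
        plus = base.coords.copy()
        plus[4, 0] += 1.0
        minus = base.coords.copy()
        minus[4, 0] -= 1.0
        traj = _sub_traj(base, [plus, minus, plus, minus])
        series = cx.rmsf_profile(traj, [0, 1, 2, 3, 4],
                                 fit_selection=[0, 1, 2, 3])
        assert series.values[4] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(series.values[:4], 0.0, atol=1e-9)

    def test_matches_two_pass_oracle(self, bundle):
        angles = {"TM4": np.linspace(0, 20, 6)}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, jitter=0.3, seed=9)
        sel = cx.select_atoms(bundle, "TM4", "CA")
        series = cx.rmsf_profile(traj, sel)
        # oracle: identical superposition chain, independent variance pass
        aligned = _superpose_frames(traj, sel)
        avg = aligned[:, sel, :].mean(axis=0)
        coords = np.array([kabsch_superpose(f[sel], avg).apply(f[sel])
                           for f in traj.frames])
        mean = coords.mean(axis=0)
        per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(series.values, per_atom, atol=1e-10)

    def test_single_frame_rejected(self, bundle):
        traj = _sub_traj(bundle, [bundle.coords])
        with pytest.raises(ValidationError):
            cx.rmsf_profile(traj, cx.select_atoms(bundle, "TM1", "CA"))


class TestComDistance:
    def test_two_atoms_seven_angstrom(self):
        from conftest import build_structure

        s = build_structure([("A", 1, "GLY", {"CA": (0, 0, 0)}),
                             ("B", 2, "GLY", {"CA": (7, 0, 0)})])
        traj = _sub_traj(s, [s.coords])
        series = cx.com_distance(traj, [0], [1])
        assert series.values[0] == pytest.approx(7.0, abs=1e-12)

    def test_identical_centers(self):
        from conftest import build_structure

        s = build_structure([("A", 1, "GLY", {"CA": (1, 0, 0)}),
                             ("A", 2, "GLY", {"CA": (-1, 0, 0)}),
                             ("B", 3, "GLY", {"CA": (0, 1, 0)}),
                             ("B", 4, "GLY", {"CA": (0, -1, 0)})])
        traj = _sub_traj(s, [s.coords])
        assert cx.com_distance(traj, [0, 1], [2, 3]).values[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_overlapping_groups_rejected(self, bundle):
        traj = _sub_traj(bundle, [bundle.coords])
        with pytest.raises(ValidationError):
            cx.com_distance(traj, [0, 1], [1, 2])

    def test_recovers_programmed_schedule(self, bundle):
        d = 35.0 * np.exp(-0.5 * np.arange(10)) + 24.0
        traj, truth = cx.make_approach_trajectory(bundle, d, seed=11)
        rec = np.flatnonzero(traj.topology.chain_ids == "R")
        blob = np.flatnonzero(traj.topology.chain_ids == "Q")
        series = cx.com_distance(traj, rec, blob)
        np.testing.assert_allclose(series.values, d, atol=1e-6)


class TestGromosClustering:
    def test_identical_frames_single_cluster(self, bundle):
        traj = _sub_traj(bundle, [bundle.coords] * 5)
        sel = cx.select_atoms(bundle, "TM1", "CA")
        res = cx.gromos_cluster(traj, sel, cutoff=1.0)
        assert res.sizes == [5]
        assert res.centers[0] == 0

    def test_zero_cutoff_gives_singletons(self, bundle, segment_map):
        # jittered frames are pairwise distinct even after superposition
        angles = {"TM1": np.zeros(4)}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, jitter=0.1,
                                              seed=2, segment_map=segment_map)
        sel = cx.select_atoms(bundle, "TM1", "CA")
        res = cx.gromos_cluster(traj, sel, cutoff=0.0)
        assert res.sizes == [1, 1, 1, 1]

    def test_planted_three_plus_two_outliers(self, bundle):
        """3 frames within 1 Å, 2 outliers far from everything, cutoff 2 Å.

        Outliers are non-rigid deformations (radial scalings) of the
        selection — rigid motions would be removed by the pairwise fit.
        """
        sel = cx.select_atoms(bundle, "TM1", "CA")
        rng = np.random.default_rng(0)
        tight = [bundle.coords + rng.normal(0, 0.2 / np.sqrt(3),
                                            bundle.coords.shape)
                 for _ in range(3)]

        def scaled(factor):
            coords = bundle.coords.copy()
            center = coords[sel].mean(axis=0)
            coords[sel] = center + factor * (coords[sel] - center)
            return coords

        out1 = scaled(1.6)
        out2 = scaled(0.4)
        traj = _sub_traj(bundle, tight + [out1, out2])
        mat = pairwise_rmsd_matrix(traj.frames[:, sel, :])
        assert mat[:3, :3].max() < 1.0 and mat[3, :3].min() > 5.0 \
            and mat[4, :3].min() > 5.0
        res = cx.gromos_cluster(traj, sel, cutoff=2.0)
        assert res.sizes == [3, 1, 1]

    def test_equals_brute_force_reference(self, bundle, segment_map):
        angles = {"TM1": np.linspace(0, 40, 30)}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, jitter=0.4,
                                              seed=7, segment_map=segment_map)
        sel = cx.select_atoms(bundle, "TM1", "CA")
        mat = pairwise_rmsd_matrix(traj.frames[:, sel, :])
        for cutoff in (0.2, 0.5, 1.0):
            res = cx.gromos_cluster(traj, sel, cutoff)
            ref = _brute_daura(mat, cutoff)
            assert res.sizes == [len(m) for _, m in ref]
            for cid, (center, members) in enumerate(ref):
                assert res.centers[cid] == center
                assert sorted(f for f, c in res.assignments.items()
                              if c == cid) == members

    def test_cutoff_monotonicity_of_neighbor_graph(self):
        rng = np.random.default_rng(1)
        mat = np.abs(rng.normal(size=(12, 12)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        c1, _ = neighbor_cluster(mat, 0.4)
        c2, _ = neighbor_cluster(mat, 1.2)
        assert len(c2) <= len(c1)


def _brute_daura(mat, cutoff):
    """Independent exhaustive reference, sorted by decreasing size."""
    n = len(mat)
    remaining = list(range(n))
    out = []
    while remaining:
        best, best_members = None, None
        for i in remaining:
            members = sorted(j for j in remaining if mat[i, j] <= cutoff)
            if best_members is None or len(members) > len(best_members):
                best, best_members = i, members
        out.append((best, best_members))
        remaining = [j for j in remaining if j not in best_members]
    return sorted(out, key=lambda t: -len(t[1]))


class TestRepresentativeFrame:
    def test_single_frame(self, bundle):
        traj = _sub_traj(bundle, [bundle.coords])
        sel = cx.select_atoms(bundle, "TM1", "CA")
        assert cx.representative_frame(traj, sel) == 0

    def test_middle_frame_equals_average_of_ends(self, bundle):
        sel = cx.select_atoms(bundle, "TM1", "CA")
        delta = np.zeros_like(bundle.coords)
        delta[sel[0]] = [1.5, 0, 0]
        traj = _sub_traj(bundle, [bundle.coords - delta, bundle.coords,
                                  bundle.coords + delta])
        assert cx.representative_frame(traj, sel) == 1

    def test_equals_brute_force_argmin(self, bundle, segment_map):
        angles = {"TM5": np.linspace(0, 30, 20)}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, jitter=0.3,
                                              seed=13, segment_map=segment_map)
        sel = cx.select_atoms(bundle, "TM5", "CA")
        rep = cx.representative_frame(traj, sel)
        aligned = _superpose_frames(traj, sel)[:, sel, :]
        avg = aligned.mean(axis=0)
        brute = int(np.argmin([
            kabsch_superpose(traj.frames[i][sel], avg).rmsd_after
            for i in range(traj.n_frames)
        ]))
        assert rep == brute


class TestHelixRotation:
    def test_reference_frame_is_zero(self, bundle, segment_map):
        angles = {"TM1": np.array([0.0, 25.0])}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=1,
                                              segment_map=segment_map)
        series, _ = cx.helix_rotation_series(traj, "TM1",
                                             segment_map=segment_map)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_planted_angles_recovered(self, bundle, segment_map):
        angles = {f"TM{i + 1}": np.array([0.0, 5.0 * (i + 1)])
                  for i in range(7)}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=1,
                                              segment_map=segment_map)
        for i in range(7):
            series, tfs = cx.helix_rotation_series(traj, f"TM{i + 1}",
                                                   segment_map=segment_map)
            assert series.values[1] == pytest.approx(5.0 * (i + 1), abs=1e-6)
            assert tfs[1].angle_deg == series.values[1]

    def test_planted_180_degree_flip(self, bundle, segment_map):
        angles = {"TM6": np.array([0.0, 180.0])}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=1,
                                              segment_map=segment_map)
        series, _ = cx.helix_rotation_series(traj, "TM6",
                                             segment_map=segment_map)
        assert series.values[1] == pytest.approx(180.0, abs=1e-6)

    def test_relative_to_previous_gives_increments(self, bundle, segment_map):
        angles = {"TM2": np.array([0.0, 10.0, 20.0, 30.0])}
        traj, _ = cx.make_rotation_trajectory(bundle, angles, seed=1,
                                              segment_map=segment_map)
        series, _ = cx.helix_rotation_series(
            traj, "TM2", segment_map=segment_map, relative_to="previous")
        np.testing.assert_allclose(series.values[1:], 10.0, atol=1e-6)

    def test_global_tumbling_removed_by_fit(self, bundle, segment_map):
        angles = {"TM1": np.zeros(4)}
        traj, truth = cx.make_rotation_trajectory(
            bundle, angles, jitter=0.05, tumble=True, seed=21,
            segment_map=segment_map)
        ca = np.flatnonzero(bundle.atom_names == "CA")
        series = cx.rmsd_series(traj, ca, ca)
        # residual after fitting is at the jitter level, not the tumble level
        assert series.values[1:].max() < 0.2
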