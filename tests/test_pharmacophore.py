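"""Activity conversion, pose clustering, feature rules, PAM and the
consensus interaction model."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

import cxcaxis as cx
from cxcaxis.errors import TopologyError, ValidationError
from cxcaxis.io import Pose
from cxcaxis.pharmacophore import (feature_distance_matrix, most_frequent_pose)
from conftest import build_structure


def mol_from_smiles(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return Chem.RemoveHs(mol)


class TestPic50:
    def test_most_potent_ligand_value(self):
        # IC50 = 0.04 µM -> pIC50 7.398 at three decimals
        assert round(cx.pic50_from_ic50(0.04), 3) == 7.398

    def test_micromolar_reference(self):
        assert cx.pic50_from_ic50(1.0) == pytest.approx(6.0, abs=1e-12)

    def test_weakest_ligand_value(self):
        assert cx.pic50_from_ic50(50.0) == pytest.approx(4.30103, abs=1e-5)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValidationError):
            cx.pic50_from_ic50(bad)


class TestClusterPoses:
    def _poses(self, coord_list, scores=None):
        return [Pose("L1", c, None if scores is None else scores[i], i)
                for i, c in enumerate(coord_list)]

    def test_identical_poses_single_cluster(self):
        base = np.zeros((4, 3))
        clusters = cx.cluster_poses(self._poses([base] * 50))
        assert len(clusters) == 1
        assert clusters[0].population == 50

    def test_planted_two_sites(self):
        rng = np.random.default_rng(1)
        base = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        coords = [base + rng.normal(0, 0.5 / np.sqrt(3), (1, 3))
                  for _ in range(7)]
        coords += [base + [6.0, 0, 0] + rng.normal(0, 0.5 / np.sqrt(3), (1, 3))
                   for _ in range(3)]
        clusters = cx.cluster_poses(self._poses(coords), rmsd_cutoff=2.0)
        assert [c.population for c in clusters] == [7, 3]
        assert clusters[0].representative < 7  # winner comes from site A

    def test_zero_cutoff_singletons(self):
        base = np.zeros((3, 3))
        coords = [base + [i, 0, 0] for i in range(5)]
        clusters = cx.cluster_poses(self._poses(coords), rmsd_cutoff=0.0)
        assert [c.population for c in clusters] == [1] * 5

    def test_representative_tie_breaks_on_docking_score(self):
        base = np.zeros((3, 3))
        poses = self._poses([base, base, base], scores=[-7.0, -9.5, -8.0])
        clusters = cx.cluster_poses(poses)
        assert clusters[0].representative == 1  # best (lowest) score wins

    def test_most_frequent_pose_helper(self):
        base = np.zeros((3, 3))
        poses = self._poses([base] * 4 + [base + 10.0] * 2)
        assert most_frequent_pose(poses).run_index in (0, 1, 2, 3)

    def test_topology_mismatch_rejected(self):
        with pytest.raises(TopologyError):
            cx.cluster_poses(self._poses([np.zeros((3, 3)), np.zeros((4, 3))]))


class TestFeatureRules:
    def test_benzene_is_one_ring_one_hydrophobe(self):
        feats = cx.extract_features(mol_from_smiles("c1ccccc1"), "benzene", 5.0)
        assert sorted(f.feature_type for f in feats) == ["Arm", "Hph"]
        arm = next(f for f in feats if f.feature_type == "Arm")
        hph = next(f for f in feats if f.feature_type == "Hph")
        np.testing.assert_allclose(arm.centroid, hph.centroid, atol=1e-8)

    def test_ethanol_oxygen_is_donor_and_acceptor(self):
        mol = mol_from_smiles("CCO")
        feats = cx.extract_features(mol, "ethanol", 5.0)
        types = sorted(f.feature_type for f in feats)
        assert types == ["HAc", "HDn"]
        o_xyz = mol.GetConformer().GetPositions()[2]
        for f in feats:
            np.testing.assert_allclose(f.centroid, o_xyz, atol=1e-8)

    def test_acetate_anion_at_carboxylate_midpoint(self):
        mol = mol_from_smiles("CC([O-])=O")
        feats = cx.extract_features(mol, "acetate", 5.0)
        nin = [f for f in feats if f.feature_type == "NIn"]
        assert len(nin) == 1
        pos = mol.GetConformer().GetPositions()
        o_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"]
        np.testing.assert_allclose(nin[0].centroid, pos[o_idx].mean(axis=0),
                                   atol=1e-8)

    def test_methylammonium_is_positive_only(self):
        feats = cx.extract_features(mol_from_smiles("C[NH3+]"), "ma", 5.0)
        assert [f.feature_type for f in feats] == ["PIn"]

    def test_amine_nitrogen_is_pure_donor(self):
        feats = cx.extract_features(mol_from_smiles("CN"), "methylamine", 5.0)
        assert [f.feature_type for f in feats] == ["HDn"]

    def test_radius_floor_is_one_angstrom(self):
        feats = cx.extract_features(mol_from_smiles("CCO"), "e", 5.0)
        assert all(f.radius >= 1.0 for f in feats)

    def test_rigid_transform_covariance(self):
        mol = mol_from_smiles("CC(=O)c1ccccc1O")
        before = cx.extract_features(mol, "x", 5.0)
        rot = Rotation.from_euler("xyz", [15, 85, -40], degrees=True)
        shift = np.array([3.0, -7.0, 12.0])
        conf = mol.GetConformer()
        moved = rot.apply(conf.GetPositions()) + shift
        from rdkit.Geometry import Point3D
        for i, xyz in enumerate(moved):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        after = cx.extract_features(mol, "x", 5.0)
        assert [f.feature_type for f in before] == \
            [f.feature_type for f in after]
        for fb, fa in zip(before, after):
            np.testing.assert_allclose(rot.apply(fb.centroid) + shift,
                                       fa.centroid, atol=1e-8)
            assert fb.radius == pytest.approx(fa.radius, abs=1e-8)


class TestPAM:
    def test_k_equals_n_zero_cost(self):
        pts = np.array([[0.0], [1.0], [5.0], [9.0]])
        d = np.abs(pts - pts.T)
        medoids, labels, cost = cx.pam_cluster(d, 4)
        assert cost == 0.0
        assert sorted(medoids) == [0, 1, 2, 3]

    def test_one_dimensional_median(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        d = np.abs(pts - pts.T)
        medoids, labels, cost = cx.pam_cluster(d, 1)
        assert medoids == [1]
        assert cost == pytest.approx(10.0)

    def test_duplicated_points(self):
        pts = np.array([[2.0], [2.0], [2.0], [7.0]])
        d = np.abs(pts - pts.T)
        medoids, _, cost = cx.pam_cluster(d, 1)
        assert cost == pytest.approx(5.0)
        assert medoids == [0]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            cx.pam_cluster(np.zeros((3, 3)), 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        k = int(rng.integers(1, 4))
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        _, _, cost = cx.pam_cluster(d, k)
        best = min(float(d[:, list(c)].min(axis=1).sum())
                   for c in itertools.combinations(range(n), k))
        assert cost == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_build_swap_branch_is_swap_optimal(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 40, 4  # C(40,4) is beyond the exact-enumeration limit
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        medoids, _, cost = cx.pam_cluster(d, k)
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = h
                assert float(d[:, cand].min(axis=1).sum()) >= cost - 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        m1, a1, c1 = cx.pam_cluster(d, 3)
        m2, a2, c2 = cx.pam_cluster(d, 3)
        assert m1 == m2 and c1 == c2
        np.testing.assert_array_equal(a1, a2)


class TestConsensusModel:
    def test_single_donor_hotspot_recovered(self):
        ligs, _, truth = cx.make_ligand_series(
            n=50, hotspots=[("HDn", (0.0, 7.0, 0.0))], coefficients=[1.0],
            presence_prob=1.0, decoy_rate=0.0, jitter=0.5, seed=6)
        feats = [f for l in ligs for f in cx.extract_features(l)]
        model = cx.build_general_model(feats, n_ligands=50)
        hdn = [c for c in model.selected if c.feature_type == "HDn"]
        assert len(hdn) == 1
        assert np.linalg.norm(hdn[0].medoid - [0.0, 7.0, 0.0]) <= 1.0

    @pytest.mark.parametrize("seed", [1, 4, 8])
    def test_three_hotspots_with_decoys(self, seed):
        ligs, _, truth = cx.make_ligand_series(
            n=50, presence_prob=0.7, decoy_rate=0.1, jitter=0.5, seed=seed)
        feats = [f for l in ligs for f in cx.extract_features(l)]
        model = cx.build_general_model(feats, n_ligands=50)
        assert sorted(c.feature_type for c in model.selected) == \
            ["HAc", "HDn", "Hph"]
        anchors = {h["type"]: np.array(h["anchor"])
                   for h in truth.data["hotspots"]}
        for c in model.selected:
            assert np.linalg.norm(c.medoid - anchors[c.feature_type]) <= 1.0

    def test_selected_ordered_by_summed_activity(self):
        ligs, _, _ = cx.make_ligand_series(n=50, presence_prob=0.7, seed=2)
        feats = [f for l in ligs for f in cx.extract_features(l)]
        model = cx.build_general_model(feats, n_ligands=50)
        scores = [c.sum_pic50 for c in model.selected]
        assert scores == sorted(scores, reverse=True)

    def test_single_ligand_rejected(self):
        ligs, _, _ = cx.make_ligand_series(n=10, seed=3)
        feats = cx.extract_features(ligs[0])
        with pytest.raises(ValidationError):
            cx.build_general_model(feats)

    def test_no_features_rejected(self):
        with pytest.raises(ValidationError):
            cx.build_general_model([])

    def test_distance_includes_radius_term(self):
        f1 = cx.PharmacophoreFeature("Hph", (0, 0, 0), 1.0)
        f2 = cx.PharmacophoreFeature("Hph", (3, 0, 0), 2.0)
        d = feature_distance_matrix([f1, f2], lam=0.5)
        assert d[0, 1] == pytest.approx(3.0 + 0.5 * 1.0)


class TestAnnotateResidues:
    def _model_at(self, xyz):
        cluster = cx.pharmacophore.ConsensusCluster(
            "HAc", np.asarray(xyz, float), 1, 1, 5.0, 1.0, True)
        return cx.ConsensusModel([cluster], n_ligands=2, coverage_min=0.3)

    def test_single_nearby_residue(self):
        rec = build_structure([
            ("R", 91, "GLY", {"CA": (3.0, 0, 0)}),
            ("R", 200, "GLY", {"CA": (12.0, 0, 0)}),
        ])
        residues, shared = cx.annotate_residues(self._model_at((0, 0, 0)), rec)
        assert residues[0] == [(91, "GLY")]
        assert shared == set()

    def test_zero_radius_empty(self):
        rec = build_structure([("R", 91, "GLY", {"CA": (3.0, 0, 0)})])
        residues, _ = cx.annotate_residues(self._model_at((0, 0, 0)), rec,
                                           radius=0.0)
        assert residues[0] == []

    def test_boundary_at_five_angstrom(self):
        rec = build_structure([
            ("R", 10, "GLY", {"CA": (4.9, 0, 0)}),
            ("R", 11, "GLY", {"CA": (5.1, 0, 0)}),
        ])
        residues, _ = cx.annotate_residues(self._model_at((0, 0, 0)), rec)
        assert residues[0] == [(10, "GLY")]

    def test_shared_residues_flagged(self):
        rec = build_structure([("R", 27, "LEU", {"CA": (0, 0, 0)})])
        c1 = cx.pharmacophore.ConsensusCluster(
            "HAc", np.array([1.0, 0, 0]), 1, 1, 5.0, 1.0, True)
        c2 = cx.pharmacophore.ConsensusCluster(
            "Hph", np.array([-1.0, 0, 0]), 1, 1, 4.0, 1.0, True)
        model = cx.ConsensusModel([c1, c2], n_ligands=2, coverage_min=0.3)
        residues, shared = cx.annotate_residues(model, rec)
        assert shared == {27}
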