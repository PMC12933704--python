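"""Symmetry-corrected RMSD, lDDT-PLI, validity checks, and aggregation."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.distance import cdist

from dmdock.errors import InputError
from dmdock.evalkit import (
    EvalScores,
    evaluate_manifest,
    ligand_automorphisms,
    lddt_pli,
    summarize,
    symmetry_corrected_rmsd,
    validity_checks,
)
from dmdock.geometry import rotation_about_axis
from .conftest import mol_from_smiles


def _nx_automorphisms(mol):
    """Independent oracle: brute-force VF2 automorphisms via networkx."""
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetSymbol())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   bt=str(b.GetBondType()))
    gm = GraphMatcher(g, g, node_match=categorical_node_match("el", None),
                      edge_match=lambda a, b: a["bt"] == b["bt"])
    return {tuple(m[i] for i in range(mol.GetNumAtoms()))
            for m in gm.isomorphisms_iter()}


class TestSymmetryCorrectedRmsd:
    def test_identical_poses_zero(self, rigid_complex):
        cx = rigid_complex
        assert symmetry_corrected_rmsd(cx.true_pose, cx.true_pose,
                                       cx.example.mol) == 0.0

    def test_uniform_translation_exact(self, rigid_complex):
        cx = rigid_complex
        shifted = cx.true_pose + np.array([1.0, 0.0, 0.0])
        assert symmetry_corrected_rmsd(
            shifted, cx.true_pose, cx.example.mol) == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_benzene_ring_rotation_forgiven(self):
        mol = mol_from_smiles("c1ccccc1")
        from dmdock.featurize import embed_conformer
        mol = embed_conformer(mol, seed=1)
        pose = np.asarray(mol.GetConformer().GetPositions())
        center = pose.mean(axis=0)
        normal = np.cross(pose[1] - pose[0], pose[2] - pose[0])
        rot = rotation_about_axis(normal, np.pi / 3)
        rotated = (pose - center) @ rot.T + center
        plain = np.sqrt(np.mean(np.sum((rotated - pose) ** 2, axis=1)))
        corrected = symmetry_corrected_rmsd(rotated, pose, mol)
        assert plain > 1.0
        assert corrected < 1e-3

    @pytest.mark.parametrize("smi", [
        "c1ccccc1", "CC(C)C", "c1ccc(-c2ccccc2)cc1", "OC(=O)CC(=O)O",
        "CC(=O)Nc1ccc(O)cc1", "c1ccc2[nH]ccc2c1", "CCOC(=O)c1ccc(N)cc1",
        "Cc1ccccc1C", "NCCc1ccc(O)c(O)c1", "FC(F)c1ccccc1",
    ])
    def test_matches_brute_force_oracle(self, smi):
        mol = mol_from_smiles(smi)
        from dmdock.featurize import embed_conformer
        mol = embed_conformer(mol, seed=3)
        ref = np.asarray(mol.GetConformer().GetPositions())
        rng = np.random.default_rng(hash(smi) % 2**31)
        pred = ref + rng.normal(0, 0.8, ref.shape)
        oracle_perms = _nx_automorphisms(mol)
        assert len(oracle_perms) <= 12
        oracle = min(np.sqrt(np.mean(np.sum(
            (pred[list(perm)] - ref) ** 2, axis=1))) for perm in oracle_perms)
        ours = symmetry_corrected_rmsd(pred, ref, mol)
        assert ours == pytest.approx(oracle, abs=1e-9)
        impl_perms = {tuple(p) for p in ligand_automorphisms(mol)}
        assert impl_perms == oracle_perms

    def test_never_exceeds_plain_rmsd(self, flexible_complex):
        cx = flexible_complex
        rng = np.random.default_rng(0)
        pred = cx.true_pose + rng.normal(0, 1.0, cx.true_pose.shape)
        plain = np.sqrt(np.mean(np.sum((pred - cx.true_pose) ** 2, axis=1)))
        assert symmetry_corrected_rmsd(pred, cx.true_pose,
                                       cx.example.mol) <= plain + 1e-12

    def test_atom_mismatch_raises(self, rigid_complex):
        with pytest.raises(InputError):
            symmetry_corrected_rmsd(np.zeros((3, 3)),
                                    rigid_complex.true_pose,
                                    rigid_complex.example.mol)


class TestLddtPli:
    def test_self_comparison_is_one(self, contact_complex):
        cx = contact_complex
        score = lddt_pli(cx.true_pose, cx.true_pose, cx.pocket)
        assert score == 1.0

    def test_all_contacts_destroyed_zero(self, contact_complex):
        cx = contact_complex
        pred = cx.true_pose + np.array([50.0, 0.0, 0.0])
        assert lddt_pli(pred, cx.true_pose, cx.pocket) == 0.0

    def test_half_shifted_contact_table(self):
        """Hand-enumerated: anchors on the x-axis, two ligand atoms; one
        prediction exact, one shifted 1.5 Angstrom along x."""
        from dmdock.mol_io import Pocket, ProteinStructure
        anchors = np.array([[4.0, 0, 0], [5.0, 1, 0], [4.5, -1, 2],
                            [5.5, 0.5, -1]])
        pocket = Pocket(atoms=ProteinStructure(
            element=np.array(["C"] * 4), atom_name=np.array(["CA"] * 4),
            res_name=np.array(["ALA"] * 4), res_id=np.arange(4),
            chain_id=np.array(["A"] * 4), coords=anchors,
            is_hetero=np.zeros(4, bool)))
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pred = ref.copy()
        pred[1] += np.array([-1.5, 0.0, 0.0])
        d_ref = cdist(anchors, ref)
        mask = d_ref < 6.0
        delta = np.abs(cdist(anchors, pred) - d_ref)[mask]
        expected = np.mean([(delta < t).mean() for t in (0.5, 1, 2, 4)])
        assert lddt_pli(pred, ref, pocket) == pytest.approx(expected,
                                                            abs=1e-12)
        # atom 0 contacts exact (4 thresholds pass); atom 1 contacts off by
        # ~1.5 A pass only the 2 and 4 A thresholds
        assert 0.5 < expected < 1.0

    def test_empty_contact_set_nan(self, rigid_complex):
        # the default shell starts at 6 A: no contacts inside the radius
        score = lddt_pli(rigid_complex.true_pose, rigid_complex.true_pose,
                         rigid_complex.pocket, inclusion_radius=2.0)
        assert np.isnan(score)

    def test_joint_rigid_motion_invariant(self, contact_complex):
        from dmdock.geometry import random_rotation
        from dmdock.mol_io import Pocket
        cx = contact_complex
        rng = np.random.default_rng(3)
        pred = cx.true_pose + rng.normal(0, 0.5, cx.true_pose.shape)
        s0 = lddt_pli(pred, cx.true_pose, cx.pocket)
        rot = random_rotation(rng)
        t = np.array([5.0, -2.0, 9.0])
        moved = Pocket(atoms=cx.example.protein.with_coords(
            cx.pocket.coords @ rot.T + t))
        s1 = lddt_pli(pred @ rot.T + t, cx.true_pose @ rot.T + t, moved)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_monotone_under_noise(self, contact_complex):
        cx = contact_complex
        means = []
        for sigma in (0.1, 0.5, 1.5):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                pred = cx.true_pose + rng.normal(0, sigma,
                                                 cx.true_pose.shape)
                vals.append(lddt_pli(pred, cx.true_pose, cx.pocket))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestValidityChecks:
    def test_true_pose_passes(self, contact_complex):
        cx = contact_complex
        res = validity_checks(cx.true_pose, cx.example.mol, cx.pocket)
        assert res["pb_valid_subset"] is True

    def test_pocket_clash_fails(self, contact_complex):
        cx = contact_complex
        pred = cx.true_pose.copy()
        pred[0] = cx.pocket.coords[0] + np.array([1.0, 0.0, 0.0])
        res = validity_checks(pred, cx.example.mol, cx.pocket)
        assert res["pocket_clash"] is False
        assert res["pb_valid_subset"] is False

    def test_stretched_bond_fails(self, contact_complex):
        cx = contact_complex
        mol = cx.example.mol
        b = mol.GetBondWithIdx(0)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        pred = cx.true_pose.copy()
        pred[j] = pred[i] + 2.0 * (pred[j] - pred[i])  # double the length
        res = validity_checks(pred, mol, cx.pocket)
        assert res["bond_lengths"] is False


class TestSummarize:
    def test_median_and_fraction(self):
        scores = [EvalScores(srmsd=1.0, lddt_pli=0.9),
                  EvalScores(srmsd=3.0, lddt_pli=0.2)]
        s = summarize(scores)
        assert s.median_srmsd == 2.0
        assert s.frac_srmsd_lt2 == 0.5
        assert s.median_lddt_pli == pytest.approx(0.55)
        assert s.frac_lddt_gt_0_5 == 0.5

    def test_strict_thresholds(self):
        s = summarize([EvalScores(srmsd=1.9, lddt_pli=0.51)])
        assert s.frac_srmsd_lt2 == 1.0 and s.frac_lddt_gt_0_5 == 1.0
        s2 = summarize([EvalScores(srmsd=2.0, lddt_pli=0.5)])
        assert s2.frac_srmsd_lt2 == 0.0 and s2.frac_lddt_gt_0_5 == 0.0

    def test_matches_sort_oracle_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 6, 101)
        scores = [EvalScores(srmsd=v, lddt_pli=v / 6.0) for v in vals]
        s = summarize(scores)
        assert s.median_srmsd == sorted(vals)[50]
        rng.shuffle(scores)
        s2 = summarize(scores)
        assert (s2.median_srmsd, s2.frac_srmsd_lt2, s2.median_lddt_pli,
                s2.frac_lddt_gt_0_5) == (s.median_srmsd, s.frac_srmsd_lt2,
                                         s.median_lddt_pli, s.frac_lddt_gt_0_5)

    def test_failures_reported_separately(self):
        s = summarize([EvalScores(srmsd=1.0, lddt_pli=0.8)], n_failed=3)
        assert s.n_failed == 3 and s.n_scored == 1

    def test_empty_raises(self):
        with pytest.raises(InputError):
            summarize([])


class TestEvaluateManifest:
    def test_pred_equals_ref(self, tmp_path, contact_complex):
        import pandas as pd
        from dmdock.mol_io import write_protein
        from dmdock.posegen import Pose, write_poses

        cx = contact_complex
        ref_sdf = tmp_path / "ref.sdf"
        write_poses([Pose(coords=cx.true_pose)], cx.example.mol, ref_sdf)
        pdb = tmp_path / "pocket.pdb"
        write_protein(cx.example.protein, pdb)
        manifest = tmp_path / "manifest.csv"
        pd.DataFrame([
            {"pred_sdf": ref_sdf, "ref_sdf": ref_sdf, "pocket_pdb": pdb},
            {"pred_sdf": tmp_path / "missing.sdf", "ref_sdf": ref_sdf,
             "pocket_pdb": pdb},
        ]).to_csv(manifest, index=False)
        per_case, summary = evaluate_manifest(manifest, out_dir=tmp_path)
        assert summary.n_failed == 1 and summary.n_scored == 1
        assert summary.median_srmsd == pytest.approx(0.0, abs=1e-6)
        assert summary.median_lddt_pli == pytest.approx(1.0)
        assert (tmp_path / "per_case.csv").exists()
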