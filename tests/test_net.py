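"""Autodiff correctness and the symmetry contract of the network:
rigid-motion invariance of the predicted distance matrix, pocket-encoder
scalar invariance / vector equivariance, exact permutation equivariance."""

import numpy as np
import pytest
from rdkit import Chem

from dmdock.featurize import build_ligand_graph, build_pocket_graph
from dmdock.geometry import random_rotation
from dmdock.mol_io import Pocket
from dmdock.net import (
    DockingModel,
    InteractionBlock,
    ModelConfig,
    TINY,
    load_checkpoint,
    save_checkpoint,
)
from dmdock.nn import Tensor, concat, einsum, matmul, smooth_l1
from .conftest import mol_from_smiles, random_protein


@pytest.fixture(scope="module")
def tiny_model():
    return DockingModel(ModelConfig(**TINY), seed=0)


@pytest.fixture(scope="module")
def lig_graph():
    return build_ligand_graph(mol_from_smiles("CC(=O)Nc1ccc(O)cc1"),
                              conformer_seed=4)


@pytest.fixture(scope="module")
def pocket_graph():
    return build_pocket_graph(Pocket(atoms=random_protein(45, seed=9)))


class TestAutodiff:
    def _check(self, fn, *shapes, seed=0):
        """Numerical gradient check of a scalar-valued tensor function."""
        rng = np.random.default_rng(seed)
        xs = [Tensor(rng.normal(size=s), requires_grad=True) for s in shapes]
        out = fn(*xs)
        out.backward()
        for x in xs:
            idx = tuple(rng.integers(d) for d in x.shape)
            eps = 1e-6
            orig = x.data[idx]
            x.data[idx] = orig + eps
            up = float(fn(*xs).data)
            x.data[idx] = orig - eps
            dn = float(fn(*xs).data)
            x.data[idx] = orig
            num = (up - dn) / (2 * eps)
            assert x.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_arithmetic_grads(self):
        self._check(lambda a, b: ((a * b + a - b) ** 2).sum(), (3, 4), (3, 4))

    def test_broadcast_grads(self):
        self._check(lambda a, b: (a + b * 2.0).mean(), (5, 1, 4), (3, 4))

    def test_matmul_grads(self):
        self._check(lambda a, b: matmul(a, b).sum(), (4, 5), (5, 3))

    def test_batched_matmul_grads(self):
        self._check(lambda a, b: matmul(a, b).sum(), (2, 4, 5), (2, 5, 3))

    def test_einsum_grads(self):
        self._check(lambda a, b: einsum("ijd,jkd->ikd", a, b).sum(),
                    (3, 3, 4), (3, 2, 4))

    def test_nonlinearity_grads(self):
        self._check(lambda a: (a.sigmoid() * a.tanh() + a.relu()).sum(),
                    (4, 4))

    def test_softmax_layernorm_grads(self):
        self._check(lambda a: (a.softmax() * a.layer_norm()).sum(), (3, 6))

    def test_gather_grads(self):
        idx = np.array([[0, 2], [1, 1]])
        self._check(lambda a: (a.take0(idx) ** 2).sum(), (4, 3))

    def test_concat_smoothl1_grads(self):
        target = np.random.default_rng(1).normal(size=(3, 8))
        self._check(
            lambda a, b: smooth_l1(concat([a, b], axis=-1), target).sum(),
            (3, 5), (3, 3))


class TestModelSymmetries:
    def test_dm_shape_and_bounds(self, tiny_model, lig_graph, pocket_graph):
        dm = tiny_model.predict_dm(lig_graph, pocket_graph)
        assert dm.shape == (pocket_graph.p, lig_graph.c)
        assert np.all(dm >= 0) and np.all(dm <= tiny_model.config.dm_max)
        assert np.all(np.isfinite(dm))

    def test_rigid_motion_invariance(self, tiny_model, lig_graph):
        prot = random_protein(45, seed=9)
        dm0 = tiny_model.predict_dm(
            lig_graph, build_pocket_graph(Pocket(atoms=prot)))
        rng = np.random.default_rng(11)
        for _ in range(10):
            rot = random_rotation(rng)
            t = rng.normal(0, 10, 3)
            moved = prot.with_coords(prot.coords @ rot.T + t)
            dm1 = tiny_model.predict_dm(
                lig_graph, build_pocket_graph(Pocket(atoms=moved)))
            assert np.abs(dm1 - dm0).max() <= 1e-4

    def test_pocket_encoder_equivariance(self, tiny_model):
        prot = random_protein(30, seed=13)
        g0 = build_pocket_graph(Pocket(atoms=prot))
        s0, v0 = tiny_model.poc_enc(g0)
        rot = random_rotation(np.random.default_rng(3))
        moved = prot.with_coords(prot.coords @ rot.T + np.array([2.0, -1, 4]))
        g1 = build_pocket_graph(Pocket(atoms=moved))
        s1, v1 = tiny_model.poc_enc(g1)
        assert np.abs(s1.data - s0.data).max() <= 1e-4     # invariant scalars
        rotated = v0.data @ rot.T                          # equivariant vectors
        assert np.abs(v1.data - rotated).max() <= 1e-4

    def test_pure_translation_identity(self, tiny_model, lig_graph):
        prot = random_protein(30, seed=17)
        dm0 = tiny_model.predict_dm(lig_graph,
                                    build_pocket_graph(Pocket(atoms=prot)))
        moved = prot.with_coords(prot.coords + np.array([7.0, -3.0, 1.5]))
        dm1 = tiny_model.predict_dm(lig_graph,
                                    build_pocket_graph(Pocket(atoms=moved)))
        # centroid-relative features make translation drop out entirely
        assert np.abs(dm1 - dm0).max() <= 1e-9

    def test_exact_permutation_equivariance(self, tiny_model, lig_graph,
                                            pocket_graph):
        dm = tiny_model.predict_dm(lig_graph, pocket_graph)
        rng = np.random.default_rng(5)
        perm_p = rng.permutation(pocket_graph.p)
        perm_c = rng.permutation(lig_graph.c)
        dm_perm = tiny_model.predict_dm(lig_graph.permute(perm_c),
                                        pocket_graph.permute(perm_p))
        assert np.array_equal(dm_perm, dm[np.ix_(perm_p, perm_c)])

    def test_determinism(self, lig_graph, pocket_graph):
        a = DockingModel(ModelConfig(**TINY), seed=3)
        b = DockingModel(ModelConfig(**TINY), seed=3)
        np.testing.assert_array_equal(a.predict_dm(lig_graph, pocket_graph),
                                      b.predict_dm(lig_graph, pocket_graph))


class TestLigandEncoder:
    def test_permutation_equivariance(self, tiny_model):
        g = build_ligand_graph(mol_from_smiles("CCO"), conformer_seed=1)
        h = tiny_model.lig_enc(g).data
        perm = np.array([2, 0, 1])
        h_perm = tiny_model.lig_enc(g.permute(perm)).data
        np.testing.assert_allclose(h_perm, h[perm], atol=1e-10)

    def test_automorphic_nodes_identical_without_positional_code(
            self, tiny_model):
        """The message-passing encoder treats automorphic atoms
        identically; only the conformer positional code (zeroed here)
        individuates them."""
        g = build_ligand_graph(mol_from_smiles("c1ccccc1"), conformer_seed=1)
        g.node_feats = g.node_feats.copy()
        g.node_feats[:, 25:] = 0.0
        h = tiny_model.lig_enc(g).data
        assert np.abs(h - h[0]).max() < 1e-9  # all six carbons equivalent


class TestInteractionBlock:
    def test_zero_input_zero_init_gives_zero(self):
        cfg = ModelConfig(**TINY)
        rng = np.random.default_rng(0)
        block = InteractionBlock(cfg, rng, out_scale=0.0)
        z = Tensor(np.zeros((5, 4, cfg.d)))
        zp = Tensor(np.random.default_rng(1).normal(size=(5, 5, cfg.d)))
        zc = Tensor(np.random.default_rng(2).normal(size=(4, 4, cfg.d)))
        out = block(z, zp, zc)
        np.testing.assert_array_equal(out.data, 0.0)


def test_training_throughput_sane():
    """Loose performance floor: one forward+backward pass on a large
    pocket (p~110, c~20) stays well under a second on a desktop CPU."""
    import time

    from dmdock.synthdata import make_complex, packaged_smiles
    from dmdock.trainkit import dm_loss

    cx = make_complex(packaged_smiles()["L015"], seed=2, n_pocket=(105, 118))
    model = DockingModel(ModelConfig(**TINY), seed=0)
    lig = cx.example.ligand_graph()
    pg = build_pocket_graph(cx.pocket,
                            rbf_centers=model.config.rbf_centers)

    def step():
        loss = dm_loss(model.forward(lig, pg), cx.true_pose, pg.coords)
        loss.backward()
        model.zero_grad()

    step()  # warm-up
    t0 = time.time()
    for _ in range(3):
        step()
    rate = 3 / (time.time() - t0)
    assert rate > 1.0  # complexes per second, generous sanity floor


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_model, lig_graph, pocket_graph):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        assert back.config == tiny_model.config
        np.testing.assert_array_equal(
            back.predict_dm(lig_graph, pocket_graph),
            tiny_model.predict_dm(lig_graph, pocket_graph))
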