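"""Loss, clustering, epoch sampling, augmentation, and short training runs."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dmdock.errors import InputError
from dmdock.mol_io import extract_pocket
from dmdock.net import ModelConfig
from dmdock.synthdata import make_dataset
from dmdock.trainkit import (
    ClusterAssignment,
    augment_pocket,
    cluster_examples,
    dm_loss,
    sample_epoch,
    train,
)

SMALL = dict(d=16, n_blocks=1, n_heads=2, ligand_depth=1, pocket_depth=1,
             n_vector=4)


@pytest.fixture(scope="module")
def small_dataset():
    return [c.example for c in make_dataset(4, seed=3, n_pocket=(30, 40))]


class TestDmLoss:
    def test_perfect_prediction_zero(self, flexible_complex):
        cx = flexible_complex
        td = cdist(cx.pocket.coords, cx.true_pose)
        assert dm_loss(td, cx.true_pose, cx.pocket.coords) == 0.0

    def test_unit_offset_closed_form(self):
        """All-near fixture: truth + 1 A everywhere gives smooth-L1 = 0.5."""
        rng = np.random.default_rng(0)
        pose = rng.normal(0, 2, (5, 3))
        pocket = pose + rng.normal(0, 1, (5, 3))  # distances all < 10
        td = cdist(pocket, pose)
        assert td.max() < 10.0
        assert dm_loss(td + 1.0, pose, pocket) == pytest.approx(0.5)

    def test_matches_two_loop_oracle(self, rigid_complex):
        cx = rigid_complex
        rng = np.random.default_rng(1)
        pred = np.clip(cx.true_dm + rng.normal(0, 2, cx.true_dm.shape), 0,
                       None)
        total = 0.0
        for i in range(pred.shape[0]):
            for k in range(pred.shape[1]):
                t = np.linalg.norm(cx.pocket.coords[i] - cx.true_pose[k])
                e = abs(pred[i, k] - t)
                h = 0.5 * e * e if e < 1 else e - 0.5
                total += (1.0 if t < 10.0 else 0.1) * h
        oracle = total / pred.size
        assert dm_loss(pred, cx.true_pose, cx.pocket.coords) == \
            pytest.approx(oracle, rel=1e-12)

    def test_nonnegative_and_zero_iff_exact(self, rigid_complex):
        cx = rigid_complex
        assert dm_loss(cx.true_dm + 0.3, cx.true_pose,
                       cx.pocket.coords) > 0.0


class TestClustering:
    def test_duplicated_example_one_cluster(self, small_dataset):
        asg = cluster_examples([small_dataset[0], small_dataset[0]])
        assert asg.n_clusters == 1

    def test_disjoint_examples_singletons(self, small_dataset):
        asg = cluster_examples(small_dataset)
        assert asg.n_clusters == len(small_dataset)

    def test_three_group_toy_set(self):
        cxs = make_dataset(9, cluster_structure=[3, 3, 3], seed=13,
                           n_pocket=(30, 40))
        asg = cluster_examples([c.example for c in cxs])
        assert asg.n_clusters == 3
        assert sorted(np.bincount(asg.labels).tolist()) == [3, 3, 3]


class TestSampleEpoch:
    def test_one_per_cluster(self):
        cxs = make_dataset(6, cluster_structure=[2, 2], seed=4,
                           n_pocket=(30, 40))
        asg = cluster_examples([c.example for c in cxs])
        epoch = sample_epoch(asg, rng_seed=0)
        assert len(epoch) == asg.n_clusters
        labels = []
        for ex in epoch:
            idx = next(i for i, e in enumerate(asg.examples) if e is ex)
            labels.append(asg.labels[idx])
        assert len(set(labels)) == asg.n_clusters

    def test_singleton_always_sampled(self, small_dataset):
        asg = cluster_examples(small_dataset[:1])
        for seed in range(5):
            assert sample_epoch(asg, rng_seed=seed) == small_dataset[:1]

    def test_ligand_cap_arithmetic(self, small_dataset):
        """2000 singleton clusters sharing one ligand code thin to
        ceil(0.001 * 2000) = 2 examples."""
        from dataclasses import replace
        base = small_dataset[0]
        examples = [replace(base, cluster_id=f"c{i}") for i in range(2000)]
        asg = ClusterAssignment(examples=examples,
                                labels=np.arange(2000))
        epoch = sample_epoch(asg, rng_seed=1, ligand_cap=0.001)
        assert len(epoch) == 2

    def test_cap_floor_is_one(self, small_dataset):
        asg = cluster_examples(small_dataset)
        epoch = sample_epoch(asg, rng_seed=0, ligand_cap=1e-9)
        codes = {}
        for ex in epoch:
            codes[ex.ligand_code] = codes.get(ex.ligand_code, 0) + 1
        assert max(codes.values()) == 1

    def test_within_cluster_uniformity(self):
        """Empirical pick frequencies inside a cluster stay within 3-sigma
        binomial bounds over many seeded epochs."""
        cxs = make_dataset(3, cluster_structure=[3], seed=6,
                           n_pocket=(30, 40))
        asg = cluster_examples([c.example for c in cxs])
        assert asg.n_clusters == 1
        counts = np.zeros(3)
        n_epochs = 600
        for seed in range(n_epochs):
            ex = sample_epoch(asg, rng_seed=seed)[0]
            idx = next(i for i, e in enumerate(asg.examples) if e is ex)
            counts[idx] += 1
        p = 1.0 / 3.0
        sigma = np.sqrt(n_epochs * p * (1 - p))
        assert np.all(np.abs(counts - n_epochs * p) <= 3 * sigma)


class TestAugmentPocket:
    def test_deterministic(self, small_dataset):
        ex = small_dataset[0]
        a = augment_pocket(ex, np.random.default_rng(5))
        b = augment_pocket(ex, np.random.default_rng(5))
        np.testing.assert_array_equal(a.pocket().coords, b.pocket().coords)

    def test_zero_magnitude_identity(self, small_dataset):
        ex = small_dataset[0]
        out = augment_pocket(ex, np.random.default_rng(0), jitter=0.0,
                             sigma=0.0)
        np.testing.assert_allclose(out.pocket().coords, ex.pocket().coords,
                                   atol=1e-12)

    def test_true_pose_untouched(self, small_dataset):
        ex = small_dataset[0]
        out = augment_pocket(ex, np.random.default_rng(1))
        np.testing.assert_array_equal(out.true_coords, ex.true_coords)

    def test_shifted_box_matches_reextraction(self, small_dataset):
        from dataclasses import replace
        from dmdock.mol_io import PocketSpec
        ex = small_dataset[0]
        rng = np.random.default_rng(2)
        shift = np.random.default_rng(2).uniform(-2, 2, 3)
        out = augment_pocket(ex, rng, sigma=0.0)
        spec = PocketSpec(center=ex.pocket_spec.center + shift,
                          box_edge=ex.pocket_spec.box_edge)
        expected = extract_pocket(ex.protein, spec)
        assert len(out.pocket()) == len(expected)


class TestTrain:
    def test_zero_epochs_returns_init(self, small_dataset):
        from dmdock.net import DockingModel
        model, trace = train(small_dataset, ModelConfig(**SMALL), epochs=0,
                             seed=7)
        assert trace == []
        ref = DockingModel(ModelConfig(**SMALL), seed=7)
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, ref.state_dict()[k])

    def test_same_seed_identical_trace(self, small_dataset):
        _, t1 = train(small_dataset, ModelConfig(**SMALL), epochs=3, seed=5)
        _, t2 = train(small_dataset, ModelConfig(**SMALL), epochs=3, seed=5)
        assert t1 == t2

    def test_loss_decreases(self, small_dataset):
        _, trace = train(small_dataset, ModelConfig(**SMALL), epochs=15,
                         seed=0)
        assert trace[-1] < trace[0]

    def test_empty_dataset_raises(self):
        with pytest.raises(InputError):
            train([], ModelConfig(**SMALL), epochs=1)
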