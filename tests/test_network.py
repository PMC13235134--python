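"""Masked network: construction, forward pass, loss, training, prediction."""

import math

import numpy as np
import pytest

from biodrp.hierarchy import LayerMask
from biodrp.network import (MaskedNetwork, TrainConfig, align_features, bce_loss,
                            design_matrices, forward, init_network, predict,
                            train)


def make_masks(shapes, rng=None, density=0.6):
    """Chain-compatible random masks with at least one edge per matrix."""
    ids = [[f"n{level}_{i}" for i in range(n)] for level, n in enumerate(shapes)]
    masks = []
    for lvl in range(3):
        m = np.ones((shapes[lvl], shapes[lvl + 1]))
        if rng is not None:
            m = (rng.random(m.shape) < density).astype(float)
            if m.sum() == 0:
                m.flat[0] = 1.0
        masks.append(LayerMask(ids[lvl], ids[lvl + 1], m))
    return masks


def chain_net(w1, w2, w3, a, b):
    """1-1-1-1 chain with one fingerprint bit and hand-set weights."""
    net = init_network(make_masks([1, 1, 1, 1]), 1, TrainConfig(seed=0))
    net.weights = [np.array([[w1]]), np.array([[w2]]), np.array([[w3]])]
    net.biases = [np.zeros(1) for _ in range(3)]
    net.output_weights = np.array([a, b])
    net.output_bias = 0.0
    return net


def dense_forward_oracle(net, x, fp):
    """Independent elementwise evaluation of the masked forward pass."""
    h = list(x)
    for lm, W, bias in zip(net.masks, net.weights, net.biases):
        nxt = []
        for j in range(len(bias)):
            s = bias[j] + sum(h[i] * lm.mask[i, j] * W[i, j]
                              for i in range(len(h)))
            nxt.append(max(s, 0.0))
        h = nxt
    concat = h + list(fp)
    z = net.output_bias + sum(c * w for c, w in zip(concat, net.output_weights))
    return 1.0 / (1.0 + math.exp(-z))


class TestInit:
    def test_output_length_one_drug(self):
        net = init_network(make_masks([1, 1, 1, 1]), 4, TrainConfig(seed=0))
        assert net.output_weights.shape == (5,)  # 1 drug node + 4 bits

    def test_same_seed_identical(self):
        rng = np.random.default_rng(0)
        masks = make_masks([5, 4, 3, 2], rng)
        a = init_network(masks, 8, TrainConfig(seed=3))
        b = init_network(masks, 8, TrainConfig(seed=3))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)

    def test_reference_shapes_give_1093_output(self):
        # 837-812-51-69 layer sizes with 1024 bits: output weights 69+1024
        net = init_network(make_masks([837, 812, 51, 69]), 1024,
                           TrainConfig(seed=0))
        assert net.output_weights.shape == (69 + 1024,)

    def test_incompatible_chain_rejected(self):
        m = make_masks([3, 2, 2, 1])
        bad = LayerMask(["x0", "x1", "x2"], m[2].target_ids, np.ones((3, 1)))
        with pytest.raises(ValueError, match="chain"):
            init_network((m[0], m[1], bad), 4, TrainConfig(seed=0))

    def test_masked_positions_start_zero(self):
        rng = np.random.default_rng(1)
        masks = make_masks([6, 5, 4, 3], rng, density=0.4)
        net = init_network(masks, 8, TrainConfig(seed=1))
        for lm, W in zip(net.masks, net.weights):
            assert (W[lm.mask == 0] == 0.0).all()


class TestForward:
    def test_hand_computed_hidden_layer(self):
        # mask [[1,0],[0,1]], W [[0.5,0.9],[0.3,0.2]], input [1,1]:
        # (M*W)^T x = [0.5, 0.2]
        mask = LayerMask(["a", "b"], ["u", "v"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        W = np.array([[0.5, 0.9], [0.3, 0.2]])
        h = np.maximum(np.array([1.0, 1.0]) @ (mask.mask * W), 0.0)
        np.testing.assert_allclose(h, [0.5, 0.2])

    def test_zero_input_gives_half(self):
        net = init_network(make_masks([3, 2, 2, 2]), 4, TrainConfig(seed=0))
        p = forward(net, np.zeros(3), np.zeros(4))
        assert p == pytest.approx(0.5)

    def test_hadamard_contract(self):
        rng = np.random.default_rng(2)
        masks = make_masks([6, 5, 4, 3], rng, density=0.5)
        net = init_network(masks, 8, TrainConfig(seed=2))
        x, fp = rng.normal(size=6), (rng.random(8) < 0.5).astype(float)
        before = forward(net, x, fp)
        for lm, W in zip(net.masks, net.weights):
            W[lm.mask == 0] = rng.normal(size=int((lm.mask == 0).sum())) * 100
        assert forward(net, x, fp) == before  # bit-identical

    def test_matches_dense_oracle_on_100_random_networks(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            shapes = [int(rng.integers(2, 6)) for _ in range(4)]
            masks = make_masks(shapes, rng, density=0.6)
            net = init_network(masks, 5, TrainConfig(seed=int(rng.integers(1000))))
            x = rng.normal(size=shapes[0])
            fp = (rng.random(5) < 0.5).astype(float)
            assert abs(forward(net, x, fp)
                       - dense_forward_oracle(net, x, fp)) < 1e-6

    def test_length_mismatch_raises(self):
        net = init_network(make_masks([3, 2, 2, 2]), 4, TrainConfig(seed=0))
        with pytest.raises(ValueError):
            forward(net, np.zeros(2), np.zeros(4))
        with pytest.raises(ValueError):
            forward(net, np.zeros(3), np.zeros(5))


class TestLoss:
    def test_confident_correct_is_near_zero(self):
        assert bce_loss(np.array([1 - 1e-9]), np.array([1.0])) < 1e-6

    def test_uninformative_is_ln2(self):
        assert bce_loss(np.array([0.5, 0.5]), np.array([0.0, 1.0])) \
            == pytest.approx(math.log(2))

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.01, 0.99, 50)
        y = (rng.random(50) < 0.5).astype(float)
        loop = -np.mean([yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
                         for pi, yi in zip(p, y)])
        assert bce_loss(p, y) == pytest.approx(loop, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))


class FakeFeatures:
    def __init__(self, cell_ids, feature_ids, values):
        self.cell_ids, self.feature_ids, self.values = cell_ids, feature_ids, values
        self.provenance = {}


class FakeDrugs:
    def __init__(self, fps):
        self.drug_ids = list(fps)
        self._fps = fps
        self.n_bits = len(next(iter(fps.values())))

    def fingerprint_of(self, d):
        return np.asarray(self._fps[d], dtype=float)


class FakeRecord:
    def __init__(self, cell_id, drug_id, label):
        self.cell_id, self.drug_id, self.label = cell_id, drug_id, label


class TestTrain:
    def one_sample_setup(self):
        feats = FakeFeatures(["c1"], ["n0_0"], np.array([[1.0]]))
        drugs = FakeDrugs({"n2_0": [1.0]})
        recs = [FakeRecord("c1", "n2_0", 1)]
        return feats, drugs, recs

    def test_zero_learning_rate_is_inert(self):
        net = chain_net(0.5, 0.8, 1.2, 0.7, -0.3)
        w_before = [w.copy() for w in net.weights]
        feats, drugs, recs = self.one_sample_setup()
        cfg = TrainConfig(batch_size=1, epochs=3, learning_rate=0.0, seed=0)
        net, history = train(net, feats, drugs, recs, cfg)
        for w, w0 in zip(net.weights, w_before):
            np.testing.assert_array_equal(w, w0)
        assert len(set(np.round(history, 12))) == 1  # flat history

    def test_single_adam_step_matches_hand_oracle(self):
        w1, w2, w3, a, b = 0.5, 0.8, 1.2, 0.7, -0.3
        x0, fp0, y = 1.0, 1.0, 1.0
        lr, eps = 0.001, 1e-8
        # hand-computed forward and chain-rule gradients
        h1, h2, h3 = w1 * x0, w2 * w1 * x0, w3 * w2 * w1 * x0
        z = a * h3 + b * fp0
        p = 1 / (1 + math.exp(-z))
        dz = p - y
        ga, gb, gbo = dz * h3, dz * fp0, dz
        d3 = dz * a
        gw3, gb3 = h2 * d3, d3
        d2 = d3 * w3
        gw2, gb2 = h1 * d2, d2
        d1 = d2 * w2
        gw1, gb1 = x0 * d1, d1

        def adam1(theta, g):  # first Adam step: mhat=g, vhat=g^2
            return theta - lr * g / (abs(g) + eps)

        net = chain_net(w1, w2, w3, a, b)
        feats, drugs, recs = self.one_sample_setup()
        cfg = TrainConfig(batch_size=1, epochs=1, learning_rate=lr, seed=0)
        net, _ = train(net, feats, drugs, recs, cfg)
        assert net.weights[0][0, 0] == pytest.approx(adam1(w1, gw1), abs=1e-12)
        assert net.weights[1][0, 0] == pytest.approx(adam1(w2, gw2), abs=1e-12)
        assert net.weights[2][0, 0] == pytest.approx(adam1(w3, gw3), abs=1e-12)
        assert net.biases[0][0] == pytest.approx(adam1(0.0, gb1), abs=1e-12)
        assert net.biases[2][0] == pytest.approx(adam1(0.0, gb3), abs=1e-12)
        assert net.output_weights[0] == pytest.approx(adam1(a, ga), abs=1e-12)
        assert net.output_weights[1] == pytest.approx(adam1(b, gb), abs=1e-12)
        assert net.output_bias == pytest.approx(adam1(0.0, gbo), abs=1e-12)

    def test_loss_decreases_on_easy_data(self, easy_dataset):
        from biodrp.evaluation import prepare_model_inputs
        feats, masks, pruned = prepare_model_inputs(easy_dataset.bundle)
        cfg = TrainConfig(epochs=5, seed=0)
        net = init_network(masks, easy_dataset.bundle.drugs.n_bits, cfg)
        net, history = train(net, feats, easy_dataset.bundle.drugs,
                             easy_dataset.bundle.responses, cfg)
        assert all(a > b for a, b in zip(history, history[1:]))

    def test_masked_weights_fixed_through_training(self, small_dataset,
                                                   small_inputs):
        feats, masks, _ = small_inputs
        cfg = TrainConfig(epochs=4, seed=5)
        net = init_network(masks, small_dataset.bundle.drugs.n_bits, cfg)
        net, _ = train(net, feats, small_dataset.bundle.drugs,
                       small_dataset.bundle.responses, cfg)
        for lm, W in zip(net.masks, net.weights):
            assert (W[lm.mask == 0] == 0.0).all()

    def test_unresolvable_ids_listed(self):
        net = chain_net(0.5, 0.8, 1.2, 0.7, -0.3)
        feats, drugs, _ = self.one_sample_setup()
        recs = [FakeRecord("cX", "n2_0", 1)]
        with pytest.raises(ValueError, match="cX"):
            train(net, feats, drugs, recs, TrainConfig(batch_size=1, epochs=1))


class TestPredict:
    def setup_net(self, dataset, inputs, epochs=2):
        feats, masks, pruned = inputs
        cfg = TrainConfig(epochs=epochs, seed=1)
        net = init_network(masks, dataset.bundle.drugs.n_bits, cfg)
        net, _ = train(net, feats, dataset.bundle.drugs,
                       dataset.bundle.responses, cfg)
        return net, feats, dataset.bundle.drugs

    def test_duplicates_and_batch_invariance(self, small_dataset, small_inputs):
        net, feats, drugs = self.setup_net(small_dataset, small_inputs)
        recs = small_dataset.bundle.responses[:10]
        pairs = [(r.cell_id, r.drug_id) for r in recs] * 2
        big = predict(net, pairs, feats, drugs, batch_size=1024)
        small = predict(net, pairs, feats, drugs, batch_size=3)
        # identical pairs in one call are bit-identical; across batch
        # partitions BLAS may reassociate sums, so allow 1e-12
        np.testing.assert_array_equal(big[:10], big[10:])
        np.testing.assert_allclose(big, small, rtol=1e-12, atol=1e-15)

    def test_matches_single_sample_forward(self, small_dataset, small_inputs):
        net, feats, drugs = self.setup_net(small_dataset, small_inputs)
        rng = np.random.default_rng(6)
        recs = [small_dataset.bundle.responses[i]
                for i in rng.integers(0, len(small_dataset.bundle.responses), 20)]
        pairs = [(r.cell_id, r.drug_id) for r in recs]
        batched = predict(net, pairs, feats, drugs)
        aligned = align_features(feats, net.genes)
        X, FP, _ = design_matrices(aligned, drugs, recs)
        for i in range(20):
            assert batched[i] == pytest.approx(forward(net, X[i], FP[i]),
                                               abs=1e-12)

    def test_unknown_pair_raises(self, small_dataset, small_inputs):
        net, feats, drugs = self.setup_net(small_dataset, small_inputs)
        with pytest.raises(ValueError, match="zz"):
            predict(net, [("zz", drugs.drug_ids[0])], feats, drugs)


class TestStructure:
    def test_effective_parameter_count(self):
        rng = np.random.default_rng(7)
        masks = make_masks([6, 5, 4, 3], rng, density=0.5)
        net = init_network(masks, 8, TrainConfig(seed=0))
        expected = sum(int(lm.mask.sum()) for lm in masks) + (5 + 4 + 3) \
            + (3 + 8) + 1
        assert net.effective_parameter_count() == expected
        assert net.effective_parameter_count() < net.dense_parameter_count()

    def test_checkpoint_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        masks = make_masks([5, 4, 3, 2], rng, density=0.7)
        net = init_network(masks, 6, TrainConfig(seed=9))
        net.save(tmp_path / "model")
        back = MaskedNetwork.load(tmp_path / "model")
        for wa, wb in zip(net.weights, back.weights):
            np.testing.assert_array_equal(wa, wb)
        assert back.genes == net.genes and back.drugs == net.drugs
        x = rng.normal(size=5)
        fp = (rng.random(6) < 0.5).astype(float)
        assert forward(back, x, fp) == forward(net, x, fp)
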