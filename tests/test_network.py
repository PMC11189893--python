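"""Architecture conformance and correctness of the NumPy network."""

import numpy as np
import pytest

from bbseg.network import BuildError, DualHeadCNN, NetworkSpec, _sigmoid, build


@pytest.fixture(scope="module")
def net():
    return build(NetworkSpec(n_channels=3), seed=0)


@pytest.fixture(scope="module")
def stacks():
    return np.random.default_rng(0).normal(size=(8, 25, 25, 3)).astype(np.float32)


class TestArchitecture:
    def test_counted_layers_are_fifteen(self):
        spec = NetworkSpec()
        assert spec.counted_layers == 15  # 6 conv + 3 pool + 4 dense + 2 heads

    def test_preflatten_map_is_2x2x96(self, net, stacks):
        # forward raises BuildError if the spatial plan misses 2x2x96
        assert net.spec.preflatten_shape == (2, 2, 96)
        net.forward(stacks)
        assert net.params["d0_W"].shape[0] == 2 * 2 * 96

    def test_four_dense_layers_and_two_scalar_heads(self, net):
        dense = [k for k in net.params if k.startswith("d") and k.endswith("_W")]
        assert len(dense) == 4
        assert net.params["head_class_W"].shape[1] == 1
        assert net.params["head_dist_W"].shape[1] == 1

    def test_class_head_is_a_probability(self, net, stacks):
        p, _ = net.predict(stacks)
        assert ((p >= 0) & (p <= 1)).all()

    def test_distance_head_is_linear_unbounded(self, stacks):
        # scaling the last-layer weights scales the output linearly
        net = build(NetworkSpec(n_channels=3), seed=1)
        _, d1 = net.forward(stacks)
        net.params["head_dist_W"] *= 3.0
        net.params["head_dist_b"] *= 3.0
        _, d3 = net.forward(stacks)
        assert np.allclose(d3, 3 * d1, atol=1e-4)

    def test_same_spec_and_seed_build_identically(self):
        a = build(NetworkSpec(n_channels=2), seed=5)
        b = build(NetworkSpec(n_channels=2), seed=5)
        assert a.n_parameters == b.n_parameters
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_unsupported_patch_side_refused(self):
        with pytest.raises(BuildError, match="patch_side"):
            NetworkSpec(patch_side=27)


class TestForward:
    def test_pure_function_bit_for_bit(self, net, stacks):
        l1, d1 = net.forward(stacks)
        l2, d2 = net.forward(stacks)
        assert np.array_equal(l1, l2) and np.array_equal(d1, d2)

    def test_batched_equals_singles(self, net, stacks):
        lb, db = net.forward(stacks)
        for i in range(len(stacks)):
            ls, ds = net.forward(stacks[i])
            assert abs(ls[0] - lb[i]) < 1e-4
            assert abs(ds[0] - db[i]) < 1e-4

    def test_shape_mismatch_rejected(self, net):
        with pytest.raises(ValueError, match="shape"):
            net.forward(np.zeros((2, 25, 25, 5), np.float32))


def test_backward_matches_finite_differences():
    """The analytic gradient of BCE+MAE agrees with central differences."""
    net = DualHeadCNN(NetworkSpec(n_channels=2), seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 25, 25, 2))
    y = np.array([1.0, 0.0])
    d = np.array([3.0, 0.0])

    def loss_val():
        logit, dist = net.forward(x)
        p = _sigmoid(logit)
        return float(
            np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p)))
            + np.mean(np.abs(dist - d))
        )

    logit, dist, cache = net.forward(x, keep_cache=True)
    p = _sigmoid(logit)
    grads = net.backward((p - y) / 2, np.sign(dist - d) / 2, cache)
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for name, P in net.params.items():
        for _ in range(3):
            idx = tuple(check_rng.integers(0, s) for s in P.shape)
            orig = P[idx]
            P[idx] = orig + eps
            lp = loss_val()
            P[idx] = orig - eps
            lm = loss_val()
            P[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name][idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), name


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, rng):
    net = build(NetworkSpec(n_channels=2), seed=9)
    x = rng.normal(size=(4, 25, 25, 2)).astype(np.float32)
    p0, d0 = net.predict(x)
    path = tmp_path / "net.npz"
    net.save(path, provenance={"seed": 9, "T": 0})
    loaded = DualHeadCNN.load(path)
    p1, d1 = loaded.predict(x)
    assert np.array_equal(p0, p1) and np.array_equal(d0, d1)
    assert loaded.provenance["seed"] == 9
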