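"""Architecture contracts: stages, attention algebra, heads, binarization."""

import numpy as np
import pytest

from onsdnet import NetConfig, ONSDNet, binarize, modulate
from onsdnet.nn import Tensor
from onsdnet.network import _AttentionBlock


@pytest.fixture(scope="module")
def image64(request):
    rng = np.random.default_rng(0)
    return rng.uniform(size=(64, 64))


class TestBackbone:
    def test_four_stages_strictly_decreasing_resolution(self, tiny_net, image64):
        feats = tiny_net.extract_shared_features(image64)
        assert len(feats) == 4
        sizes = [f.shape[2] for f in feats]
        assert sizes == sorted(sizes, reverse=True)
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_deterministic_with_fixed_weights(self, tiny_net, image64):
        a = tiny_net.extract_shared_features(image64)
        b = tiny_net.extract_shared_features(image64)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)

    def test_width_config_controls_channels(self, image64):
        wide = ONSDNet(NetConfig(width=8, seed=0))
        thin = ONSDNet(NetConfig(width=4, seed=0))
        fw = wide.extract_shared_features(image64)
        ft = thin.extract_shared_features(image64)
        assert len(fw) == len(ft)
        assert all(a.shape[1] == 2 * b.shape[1] for a, b in zip(fw, ft))

    def test_bad_input_size_names_divisibility(self, tiny_net):
        with pytest.raises(ValueError, match="divisible.*32"):
            tiny_net.extract_shared_features(np.zeros((60, 60)))


class TestAggregation:
    def test_preserves_stage_count_and_sizes(self, tiny_net, image64):
        feats = tiny_net.extract_shared_features(image64)
        agg = tiny_net.aggregate_features(feats)
        assert len(agg) == len(feats)
        for a, f in zip(agg, feats):
            assert a.shape[2:] == f.shape[2:]

    def test_mismatched_stage_list_rejected(self, tiny_net, image64):
        feats = tiny_net.extract_shared_features(image64)
        with pytest.raises(ValueError, match="expected 4 stages"):
            tiny_net.aggregate_features(feats[:2])

    def test_finite_outputs(self, tiny_net, image64):
        for a in tiny_net.aggregate_features(
                tiny_net.extract_shared_features(image64)):
            assert np.all(np.isfinite(a.data))


class TestAttention:
    def test_masks_in_unit_interval_over_random_inputs(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            net = ONSDNet(NetConfig(width=4, seed=trial))
            img = rng.uniform(size=(64, 64))
            out = net.forward_batch(Tensor(img[None, None]))
            for mask in out["seg_masks"] + out["reg_masks"]:
                assert mask.data.min() >= 0.0
                assert mask.data.max() <= 1.0

    def test_first_layer_rejects_previous_features(self, rng):
        blk = _AttentionBlock(4, None, rng)
        shared = Tensor(rng.normal(size=(1, 4, 8, 8)))
        with pytest.raises(ValueError, match="layer 1"):
            blk(shared, shared)

    def test_later_layer_requires_previous_features(self, rng):
        blk = _AttentionBlock(4, 4, rng)
        shared = Tensor(rng.normal(size=(1, 4, 8, 8)))
        with pytest.raises(ValueError, match="layer >= 2"):
            blk(shared, None)

    def test_sigmoid_midpoint_and_saturation(self, rng):
        blk = _AttentionBlock(3, None, rng)
        shared = Tensor(rng.normal(size=(1, 3, 8, 8)))
        # zero pre-activation: zero all conv/linear weights and biases
        for p in blk.parameters():
            p.data[...] = 0.0
        mask = blk(shared, None)
        np.testing.assert_allclose(mask.data, 0.5)
        # large positive bias saturates the sigmoid toward 1
        blk.spatial.bias.data[...] = 50.0
        np.testing.assert_allclose(blk(shared, None).data, 1.0, atol=1e-8)


class TestModulate:
    def test_identity_with_unit_mask(self, rng):
        v = rng.normal(size=(2, 3, 5, 5))
        np.testing.assert_array_equal(modulate(v, np.ones_like(v)), v)

    def test_annihilation_with_zero_mask(self, rng):
        v = rng.normal(size=(2, 3, 5, 5))
        assert np.all(modulate(v, np.zeros_like(v)) == 0)

    def test_half_mask_halves_features(self, rng):
        v = rng.normal(size=(4, 6))
        np.testing.assert_allclose(modulate(v, np.full_like(v, 0.5)), v / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            modulate(np.ones((2, 3)), np.ones((3, 2)))

    def test_random_shapes_property(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(1, 6, size=int(rng.integers(2, 5))))
            v = rng.normal(size=shape)
            np.testing.assert_array_equal(modulate(v, np.ones(shape)), v)
            assert np.all(modulate(v, np.zeros(shape)) == 0)


class TestForward:
    def test_output_shapes_ranges_and_determinism(self, tiny_net, image64):
        out1 = tiny_net.forward(image64)
        out2 = tiny_net.forward(image64)
        assert out1.prob_on.shape == image64.shape
        assert out1.prob_ons.shape == image64.shape
        for p in (out1.prob_on, out1.prob_ons):
            assert p.min() >= 0.0 and p.max() <= 1.0
        assert out1.onsd_regressed >= 0.0 and np.isfinite(out1.onsd_regressed)
        assert np.all(out1.sigmas >= 0)
        np.testing.assert_array_equal(out1.prob_on, out2.prob_on)
        assert out1.onsd_regressed == out2.onsd_regressed

    def test_forced_unit_masks_reduce_to_shared_features(self, tiny_net, image64):
        """With masks == 1 the branches return exactly the shared (aggregated)
        features: the model degrades to a standard shared multi-task net."""
        out = tiny_net.forward_batch(Tensor(image64[None, None]),
                                     force_mask_one=True)
        for branch in ("seg_features", "reg_features"):
            for f, a in zip(out[branch], out["aggregated"]):
                np.testing.assert_array_equal(f.data, a.data)

    def test_batch_composition_invariance(self, tiny_net, rng):
        imgs = rng.uniform(size=(3, 64, 64))
        tiny_net.set_training(False)
        single = [tiny_net.forward(im).prob_on for im in imgs]
        batch = tiny_net.forward_batch(Tensor(imgs[:, None]))
        for i in range(3):
            np.testing.assert_allclose(batch["probs"].data[i, 0], single[i],
                                       atol=1e-10)

    def test_gradients_flow_to_all_parameters(self, rng):
        """Analytic gradient exists/finite for every parameter; spot-check
        three of them against central finite differences."""
        from onsdnet.train_eval import _batch_losses, TrainConfig

        net = ONSDNet(NetConfig(width=2, seed=1))
        net.set_training(True)
        imgs = rng.uniform(size=(2, 64, 64))
        labs = np.zeros((2, 64, 64), dtype=np.uint8)
        labs[:, 20:40, 24:34] = 1
        labs[:, 20:40, 27:31] = 2
        onsd = np.array([5.0, 5.5])
        cfg = TrainConfig()
        total, _ = _batch_losses(net, imgs, labs, onsd, cfg)
        net.zero_grad()
        total.backward()
        params = net.named_parameters()
        assert all(p.grad is not None and np.all(np.isfinite(p.grad))
                   for _, p in params)

        picks = [params[i] for i in rng.choice(len(params), size=3, replace=False)]
        eps = 1e-5
        for name, p in picks:
            idx = tuple(rng.integers(0, s) for s in p.data.shape) or ()
            orig = p.data[idx] if p.data.shape else float(p.data)
            analytic = p.grad[idx] if p.data.shape else float(p.grad)

            def value(v, p=p, idx=idx):
                p.data[idx] = v
                out, _ = _batch_losses(net, imgs, labs, onsd, cfg)
                return float(out.data)

            num = (value(orig + eps) - value(orig - eps)) / (2 * eps)
            p.data[idx] = orig
            assert analytic == pytest.approx(num, rel=5e-3, abs=1e-6), name


class TestBinarize:
    def test_constant_above_threshold(self):
        assert binarize(np.full((4, 4), 0.7)).all()

    def test_tie_maps_to_background(self):
        assert not binarize(np.full((4, 4), 0.5)).any()

    def test_matches_elementwise_oracle(self, rng):
        prob = rng.uniform(size=(32, 32))
        got = binarize(prob, 0.5)
        expect = np.array([[v > 0.5 for v in row] for row in prob])
        np.testing.assert_array_equal(got, expect)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            binarize(np.zeros((2, 2)), 1.5)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            binarize(np.full((2, 2), 1.2))
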