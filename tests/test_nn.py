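"""Segmentation networks: shape contract, determinism, gradients, capacity."""

import numpy as np
import pytest

from fatseg.nn import ArchitectureSpec, build_model, normalize_slice, predict_slice
from fatseg.nn.layers import Adam, segmentation_loss, softmax
from fatseg.nn.models import load_checkpoint, save_checkpoint

ARCHS = ("unet", "denseunet", "cdfnet")


def tiny(name, **kw):
    defaults = dict(name=name, depth=2, base_channels=4, growth_rate=3,
                    layers_per_block=2, input_size=16)
    defaults.update(kw)
    return ArchitectureSpec(**defaults)


class TestSpecValidation:
    def test_unknown_architecture(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            ArchitectureSpec(name="resnet")

    def test_input_size_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureSpec(name="unet", depth=4, input_size=100)


class TestShapeContract:
    @pytest.mark.parametrize("name", ARCHS)
    @pytest.mark.parametrize("size", [64, 128])
    def test_output_matches_input_resolution(self, name, size):
        model = build_model(tiny(name, input_size=size), init_seed=0)
        x = np.random.default_rng(0).normal(size=(1, size, size, 1)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (1, size, size, 3)
        assert np.isfinite(y).all()

    @pytest.mark.parametrize("name", ARCHS)
    def test_constant_zero_image(self, name):
        model = build_model(tiny(name), init_seed=1)
        y = model.forward(np.zeros((1, 16, 16, 1), dtype=np.float32))
        assert y.shape == (1, 16, 16, 3) and np.isfinite(y).all()

    def test_seeded_build_is_bit_identical(self):
        a = build_model(tiny("cdfnet"), init_seed=5)
        b = build_model(tiny("cdfnet"), init_seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestParameterCounts:
    def test_dense_variants_use_fewer_parameters(self):
        counts = {
            n: build_model(ArchitectureSpec(
                name=n, depth=4, base_channels=64, growth_rate=16,
                layers_per_block=4, input_size=256), 0).parameter_count
            for n in ARCHS
        }
        assert counts["denseunet"] < counts["unet"]
        assert counts["cdfnet"] < counts["unet"]

    def test_unet_count_matches_block_formula(self):
        """Closed-form enumeration of a small UNet's parameters."""
        spec = tiny("unet", base_channels=4, depth=2)
        w = [4, 8, 16]

        def conv(cin, cout, k=3):
            return cin * cout * k * k + cout

        def block(cin, cout):
            return conv(cin, cout) + conv(cout, cout)

        expected = (
            block(1, w[0]) + block(w[0], w[1])            # encoder
            + block(w[1], w[2])                            # bottleneck
            + (w[2] * w[1] * 4 + w[1]) + block(2 * w[1], w[1])   # decoder level 1
            + (w[1] * w[0] * 4 + w[0]) + block(2 * w[0], w[0])   # decoder level 0
            + conv(w[0], 3, k=1)                           # head
        )
        assert build_model(spec, 0).parameter_count == expected


class TestGradients:
    @pytest.mark.parametrize("name", ARCHS)
    def test_backward_matches_directional_derivative(self, name):
        model = build_model(tiny(name), init_seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 16, 16, 1)).astype(np.float32)
        t = rng.integers(0, 3, size=(2, 16, 16))

        def loss():
            return segmentation_loss(model.forward(x), t)

        _, dlog = loss()
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(dlog)
        grads = [p.grad.copy() for p in model.params()]
        norm = np.sqrt(sum((g**2).sum() for g in grads))
        us = [g / norm for g in grads]
        analytic = float(sum((g * u).sum() for g, u in zip(grads, us)))
        eps = 1e-2
        for p, u in zip(model.params(), us):
            p.value += eps * u
        l1, _ = loss()
        for p, u in zip(model.params(), us):
            p.value -= 2 * eps * u
        l2, _ = loss()
        numeric = (l1 - l2) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=0.15)


class TestPrediction:
    def test_probabilities_normalised_and_ties_lowest_index(self):
        model = build_model(tiny("unet"), init_seed=0)
        img = np.random.default_rng(3).uniform(size=(16, 16)).astype(np.float32)
        labels, probs = predict_slice(model, img)
        assert labels.shape == (16, 16) and probs.shape == (16, 16, 3)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        tie = np.zeros((2, 2, 3))
        assert np.all(tie.argmax(axis=-1) == 0)  # argmax tie rule: lowest class

    def test_native_grid_resampling_round_trip(self):
        model = build_model(tiny("unet", input_size=16), init_seed=0)
        img = np.random.default_rng(4).uniform(size=(24, 24)).astype(np.float32)
        labels, probs = predict_slice(model, img)
        assert labels.shape == (24, 24)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_normalize_slice_robust_range(self):
        img = np.concatenate([np.zeros(98), [1000.0, -1000.0]])
        out = normalize_slice(img.reshape(10, 10))
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert normalize_slice(np.full((4, 4), 3.0)).max() == 0.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = build_model(tiny("cdfnet"), init_seed=9)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.spec == model.spec
        x = np.random.default_rng(1).normal(size=(1, 16, 16, 1)).astype(np.float32)
        np.testing.assert_array_equal(back.forward(x), model.forward(x))


class TestCapacity:
    def test_single_slice_overfit(self, noiseless_spec):
        """A small network can drive the training loss below 0.01 on one slice."""
        from fatseg.phantoms import generate_slice

        sl = generate_slice(noiseless_spec, 12, 99)
        x = normalize_slice(sl.in_phase)[None, ..., None].astype(np.float32)
        t = sl.truth[None].astype(np.int64)
        spec = ArchitectureSpec(name="cdfnet", depth=3, base_channels=16, growth_rate=16,
                                layers_per_block=3, input_size=128)
        model = build_model(spec, 0)
        opt = Adam(model.params(), lr=3e-3)
        loss = np.inf
        for _ in range(250):
            loss, dlog = segmentation_loss(model.forward(x), t)
            if loss < 0.01:
                break
            opt.zero_grad()
            model.backward(dlog)
            opt.step()
        assert loss < 0.01
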