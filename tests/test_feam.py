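"""FEAM: spectral modulation algebra, gates, fusion, parameters, gradients."""

import numpy as np
import pytest

from aphidseg import FEAM, ComplexWeightMap, FeamConfig
from aphidseg.feam import (
    channel_gate,
    feam_param_count,
    freq_modulate,
    fuse_scales,
    project_weights,
    spatial_gate,
)
from aphidseg.nn import Tensor
from aphidseg.nn.functional import bilinear_resize

from conftest import finite_difference


def make_weight(alpha, beta):
    a = Tensor(np.asarray(alpha, dtype=np.float32), requires_grad=True)
    b = Tensor(np.asarray(beta, dtype=np.float32), requires_grad=True)
    return ComplexWeightMap(scale=a.shape[0], alpha=a, beta=b)


class TestProjection:
    def test_identity_when_sizes_match(self, rng):
        g = rng.normal(size=(30, 30))
        w = make_weight(g, np.zeros((30, 30)))
        a, b = project_weights(w, 30, 30)
        np.testing.assert_array_equal(a.data, g.astype(np.float32))
        np.testing.assert_array_equal(b.data, 0.0)

    def test_constants_preserved(self):
        w = make_weight(np.full((5, 5), 2.5), np.full((5, 5), -1.25))
        a, b = project_weights(w, 12, 7)
        np.testing.assert_allclose(a.data, 2.5, rtol=1e-6)
        np.testing.assert_allclose(b.data, -1.25, rtol=1e-6)

    def test_two_by_two_grid_against_closed_form(self):
        """Corner-aligned bilinear: output column j samples input position
        j*(W_in-1)/(W_out-1), so [[0,1],[0,1]] -> columns [0, 1/3, 2/3, 1]."""
        w = make_weight([[0.0, 1.0], [0.0, 1.0]], np.zeros((2, 2)))
        a, _ = project_weights(w, 2, 4)
        expected = np.tile([0.0, 1 / 3, 2 / 3, 1.0], (2, 1))
        np.testing.assert_allclose(a.data, expected, atol=1e-6)

    def test_projection_gradient(self, rng):
        g = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        gout = rng.normal(size=(5, 7)).astype(np.float32)

        def loss():
            return (bilinear_resize(g, (5, 7)) * Tensor(gout)).sum()

        loss().backward()
        auto = g.grad.copy()
        num = finite_difference(lambda: float(loss().data), g.data)
        np.testing.assert_allclose(auto, num, rtol=5e-2, atol=1e-3)


class TestFrequencyBranch:
    def test_identity_filter(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        out = freq_modulate(x, Tensor(np.ones((8, 8))), Tensor(np.zeros((8, 8))))
        assert np.abs(out.data - x.data).max() < 1e-5

    def test_scalar_filter_scales(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
        out = freq_modulate(x, Tensor(np.full((6, 6), 2.0)), Tensor(np.zeros((6, 6))))
        np.testing.assert_allclose(out.data, 2 * x.data, atol=1e-5)

    def test_dc_only_filter_projects_to_mean(self, rng):
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        alpha = np.zeros((4, 4)); alpha[0, 0] = 1.0
        out = freq_modulate(Tensor(x), Tensor(alpha), Tensor(np.zeros((4, 4))))
        means = x.mean(axis=(2, 3), keepdims=True)
        np.testing.assert_allclose(out.data, np.broadcast_to(means, x.shape), atol=1e-5)

    def test_binary_mask_never_gains_energy(self, rng):
        """Parseval under the unitary FFT: a 0/1 real mask with beta = 0 can
        only remove spectral energy, never add it."""
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        out = freq_modulate(Tensor(x), Tensor(mask), Tensor(np.zeros((8, 8)))).data
        for c in range(4):
            assert (out[0, c] ** 2).sum() <= (x[0, c] ** 2).sum() + 1e-4

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            freq_modulate(Tensor(np.zeros((1, 1, 4, 4))),
                          Tensor(np.ones((3, 3))), Tensor(np.zeros((3, 3))))


class TestSpatialGate:
    def test_identity_zero_and_loop_oracle(self, rng):
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        ones = Tensor(np.ones((4, 4)))
        np.testing.assert_array_equal(spatial_gate(Tensor(x), ones).data, x)
        zeros = Tensor(np.zeros((4, 4)))
        np.testing.assert_array_equal(spatial_gate(Tensor(x), zeros).data, 0.0)

        a = rng.normal(size=(4, 4)).astype(np.float32)
        out = spatial_gate(Tensor(x), Tensor(a)).data
        for n in range(2):
            for c in range(3):
                for i in range(4):
                    for j in range(4):
                        assert out[n, c, i, j] == pytest.approx(
                            x[n, c, i, j] * a[i, j], rel=1e-6
                        )

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spatial_gate(Tensor(np.zeros((1, 1, 4, 4))), Tensor(np.ones((2, 2))))


class TestFusion:
    def test_identity_branches_double(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        fused = fuse_scales([(x, x), (x, x)])  # two scales, both identity
        np.testing.assert_allclose(fused.data, 2 * x.data, rtol=1e-6)

    def test_zero_branches(self):
        z = Tensor(np.zeros((1, 1, 2, 2)))
        np.testing.assert_array_equal(fuse_scales([(z, z)]).data, 0.0)

    def test_single_scale_hand_sum(self, rng):
        a = Tensor(rng.normal(size=(1, 1, 3, 3)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 1, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(fuse_scales([(a, b)]).data, a.data + b.data,
                                   rtol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fuse_scales([])


class TestChannelGate:
    def test_zero_input_zero_output(self, rng):
        out = channel_gate(np.zeros((1, 8, 4, 4), dtype=np.float32), reduction=4,
                           rng=rng)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_gate_shrinks(self, rng):
        y = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        out = channel_gate(y, reduction=4, rng=rng).data
        assert (np.abs(out) <= np.abs(y)).all()

    def test_gate_vector_matches_naive_recomputation(self, rng):
        from aphidseg.feam import ChannelGate

        gate = ChannelGate(8, reduction=4, rng=rng)
        y = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        got = gate.gate_vector(Tensor(y)).data

        w1, b1 = gate.fc1.weight.data, gate.fc1.bias.data
        w2, b2 = gate.fc2.weight.data, gate.fc2.bias.data
        avg = y.mean(axis=(2, 3))
        mx = y.max(axis=(2, 3))
        mlp = lambda d: np.maximum(d @ w1.T + b1, 0) @ w2.T + b2
        expected = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-6)

    def test_excessive_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_gate(np.zeros((1, 4, 2, 2), dtype=np.float32), reduction=8)


class TestBlock:
    def test_identity_init_pre_gate_is_twice_input(self, rng):
        block = FEAM(8, FeamConfig(scales=(4, 8)), rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(block.pre_gate(x).data, 2 * x.data, atol=1e-5)

    def test_parameter_count_closed_form(self, rng):
        block = FEAM(512, FeamConfig(scales=(30, 60), gate_reduction=4), rng=rng)
        spectral = 2 * (30 ** 2 + 60 ** 2)
        assert spectral == 9000
        gate = 2 * 512 * 128 + 128 + 512
        assert block.num_parameters() == spectral + gate == feam_param_count(
            512, (30, 60), 4
        )

    def test_output_real_and_shape_preserving(self, rng):
        block = FEAM(8, FeamConfig(scales=(3, 6), init="random"), rng=rng)
        x = rng.normal(size=(1, 8, 12, 12)).astype(np.float32)
        out = block(Tensor(x))
        assert out.data.dtype == np.float32
        assert out.shape == x.shape and np.isfinite(out.data).all()

    def test_gradients_reach_spectral_weights(self, rng):
        block = FEAM(4, FeamConfig(scales=(2, 4)), rng=rng)
        x = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        block(x).sum().backward()
        for w in block.weights:
            auto_a = w.alpha.grad.copy()
            assert np.isfinite(auto_a).all() and np.abs(auto_a).max() > 0
            w.alpha.zero_grad()
            num = finite_difference(
                lambda: float(block(x).sum().data), w.alpha.data, eps=2e-3
            )
            np.testing.assert_allclose(auto_a, num, rtol=8e-2, atol=2e-3)

    def test_oversized_scale_rejected(self, rng):
        block = FEAM(4, FeamConfig(scales=(16,)), rng=rng)
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
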