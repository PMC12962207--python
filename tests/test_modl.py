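"""Complex convolutions, CReLU, DC step, unrolling, blockwise processing."""

import copy

import numpy as np
import pytest

from conftest import random_coils, random_image
from learnedwave import autodiff as ad
from learnedwave import modl
from learnedwave.encoding import EncodingOperator
from learnedwave.modl import (
    ComplexConvLayer,
    MoDLConfig,
    blockwise_apply,
    complex_conv,
    crelu,
    dc_step,
    denoiser_forward,
    init_denoiser,
    parameter_count,
    unrolled_recon,
    zero_denoiser,
)


class TestCrelu:
    @pytest.mark.parametrize(
        "val,expected",
        [(1 + 2j, 1 + 2j), (-1 - 2j, 0 + 0j), (-1 + 2j, 2j), (3 - 1j, 3 + 0j)],
    )
    def test_quadrant_behavior(self, val, expected):
        assert crelu(np.array([val]))[0] == expected

    def test_acts_independently_on_components(self, rng):
        d = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        out = crelu(d)
        np.testing.assert_array_equal(out.real, np.maximum(d.real, 0))
        np.testing.assert_array_equal(out.imag, np.maximum(d.imag, 0))


class TestComplexConv:
    def test_multiplication_by_i(self, rng):
        """A 1x1x1 kernel W = i rotates the input by 90 degrees."""
        d = (rng.standard_normal((1, 4, 4, 4)) + 1j * rng.standard_normal((1, 4, 4, 4)))
        layer = ComplexConvLayer(
            X=np.zeros((1, 1, 1, 1, 1)), Y=np.ones((1, 1, 1, 1, 1)),
            bias_re=np.zeros(1), bias_im=np.zeros(1),
        )
        np.testing.assert_allclose(complex_conv(d, layer), 1j * d, rtol=1e-12)

    def test_real_kernel_convolves_components_independently(self, rng):
        d = rng.standard_normal((1, 5, 5, 5)) + 1j * rng.standard_normal((1, 5, 5, 5))
        X = rng.standard_normal((1, 1, 3, 3, 3))
        layer = ComplexConvLayer(
            X=X, Y=np.zeros_like(X), bias_re=np.zeros(1), bias_im=np.zeros(1)
        )
        out = complex_conv(d, layer)
        re = complex_conv((d.real).astype(complex), layer)
        im = complex_conv((d.imag).astype(complex), layer)
        np.testing.assert_allclose(out.real, re.real, atol=1e-12)
        np.testing.assert_allclose(out.imag, im.real, atol=1e-12)

    def test_against_direct_mac_oracle(self, rng):
        """Random 3^3 kernel vs a brute-force complex multiply-accumulate."""
        cin, cout, n = 2, 3, 5
        d = rng.standard_normal((cin, n, n, n)) + 1j * rng.standard_normal((cin, n, n, n))
        X = rng.standard_normal((cout, cin, 3, 3, 3))
        Y = rng.standard_normal((cout, cin, 3, 3, 3))
        br, bi = rng.standard_normal(cout), rng.standard_normal(cout)
        layer = ComplexConvLayer(X=X, Y=Y, bias_re=br, bias_im=bi)
        out = complex_conv(d, layer)

        W = X + 1j * Y
        dp = np.pad(d, ((0, 0), (1, 1), (1, 1), (1, 1)))
        expected = np.zeros((cout, n, n, n), dtype=complex)
        for o in range(cout):
            for x in range(n):
                for y in range(n):
                    for z in range(n):
                        acc = 0.0 + 0.0j
                        for c in range(cin):
                            for i in range(3):
                                for j in range(3):
                                    for k in range(3):
                                        acc += W[o, c, i, j, k] * dp[c, x + i, y + j, z + k]
                        expected[o, x, y, z] = acc + br[o] + 1j * bi[o]
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-10)


class TestDenoiser:
    def test_zero_weights_residual_identity(self, rng):
        cfg = MoDLConfig(n_layers=3, features=4)
        z = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        out = denoiser_forward(z, cfg, zero_denoiser(cfg))
        np.testing.assert_array_equal(out, z)

    def test_output_finite_over_seeds(self):
        cfg = MoDLConfig(n_layers=3, features=3)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            w = init_denoiser(cfg, seed=seed, scale=1.0)
            z = rng.standard_normal((6, 6, 6)) + 1j * rng.standard_normal((6, 6, 6))
            assert np.all(np.isfinite(denoiser_forward(z, cfg, w)))

    def test_parameter_count_formula_matches_builder(self):
        for features, layers in [(4, 3), (8, 5), (29, 5)]:
            cfg = MoDLConfig(n_layers=layers, features=features)
            weights = init_denoiser(cfg, seed=0)
            built = sum(
                l.X.size + l.Y.size + l.bias_re.size + l.bias_im.size for l in weights
            )
            assert built == parameter_count(cfg)

    def test_reference_width_is_nearest_to_reported_count(self):
        """Five complex layers at width 29 give 139,608 trainable
        parameters — the closest realizable width to the reported 139,680."""
        count29 = parameter_count(MoDLConfig(n_layers=5, features=29))
        assert count29 == 139608
        for f in (28, 30):
            other = parameter_count(MoDLConfig(n_layers=5, features=f))
            assert abs(other - 139680) > abs(count29 - 139680)


class TestDcStep:
    def test_zero_residual_is_identity(self, rng):
        n = 8
        op = EncodingOperator(
            random_coils(n, 2, seed=0),
            rng.uniform(-3.5, 3.5, size=(30, 3)),
            engine="ndft",
        )
        m = random_image(n, seed=1)
        y = op.forward(m)
        np.testing.assert_allclose(dc_step(m, y, op, 0.3), m, atol=1e-10)

    def test_zero_alpha_is_identity(self, rng):
        n = 8
        op = EncodingOperator(
            random_coils(n, 2, seed=2), rng.uniform(-3.5, 3.5, size=(30, 3)),
        )
        m = random_image(n, seed=3)
        y = np.zeros((2, 30), dtype=complex)
        np.testing.assert_array_equal(dc_step(m, y, op, 0.0), m)

    def test_matches_dense_matrix_oracle(self):
        """8^3 single-coil Cartesian: z = (I - 2a E^H E) m + 2a E^H y with an
        explicitly assembled DFT matrix."""
        n = 8
        ax = np.arange(n) - n // 2
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        cart = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], 1).astype(float)
        coils = random_coils(n, 1, seed=4)
        coils.maps[:] = 1.0
        op = EncodingOperator(coils, cart, engine="ndft")
        rng = np.random.default_rng(5)
        m = random_image(n, seed=6)
        y = rng.standard_normal(n**3) + 1j * rng.standard_normal(n**3)
        alpha = 0.2

        xn = cart / n  # exponent positions are the same grid
        E = np.exp(-2j * np.pi * (cart @ xn.T)) / np.sqrt(n**3)
        z_dense = m.reshape(-1) - 2 * alpha * (
            E.conj().T @ (E @ m.reshape(-1) - y)
        )
        z = dc_step(m, y[None], op, alpha)
        rel = np.linalg.norm(z.reshape(-1) - z_dense) / np.linalg.norm(z_dense)
        assert rel < 1e-6

    def test_nonexpansive_below_spectral_bound(self):
        """For 0 < 2 alpha < 2/L the DC map contracts toward the
        data-consistent solution (power-iteration-estimated L)."""
        n = 8
        rng = np.random.default_rng(7)
        op = EncodingOperator(
            random_coils(n, 2, seed=8), rng.uniform(-3.5, 3.5, size=(200, 3)),
            engine="ndft",
        )
        L = op.max_eigenvalue(seed=0)
        alpha = 0.45 / L
        m_star = random_image(n, seed=9)
        y = op.forward(m_star)
        m = random_image(n, seed=10)
        d0 = np.linalg.norm(m - m_star)
        for _ in range(5):
            m = dc_step(m, y, op, alpha)
        # only the component inside range(A^H) contracts; the distance still
        # must not grow
        assert np.linalg.norm(m - m_star) <= d0 * (1 + 1e-9)


class TestUnrolledRecon:
    def test_reduces_to_gradient_descent_with_identity_denoiser(self, rng):
        n = 8
        op = EncodingOperator(
            random_coils(n, 2, seed=11), rng.uniform(-3.5, 3.5, size=(100, 3)),
            engine="ndft",
        )
        cfg = MoDLConfig(n_unrolls=1, n_layers=3, features=2, alpha=0.1,
                         block_size=16, block_overlap=2)
        m_true = random_image(n, seed=12)
        y = op.forward(m_true)
        out = unrolled_recon(y, op, cfg, zero_denoiser(cfg))
        m0 = op.adjoint(y)
        expected = dc_step(m0, y, op, 0.1)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_error_decreases_monotonically_on_full_sampling(self):
        """Noiseless fully sampled Cartesian data with the identity
        denoiser: each unroll is a gradient-descent step, so the error
        shrinks monotonically for a small step size."""
        n = 8
        ax = np.arange(n) - n // 2
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        cart = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], 1).astype(float)
        coils = random_coils(n, 2, seed=13)
        op = EncodingOperator(coils, cart, engine="ndft")
        m_true = random_image(n, seed=14)
        y = op.forward(m_true)
        errs = []
        for unrolls in (1, 3, 6):
            cfg = MoDLConfig(n_unrolls=unrolls, n_layers=3, features=2,
                             alpha=0.4, block_size=16, block_overlap=2)
            out = unrolled_recon(y, op, cfg, zero_denoiser(cfg))
            errs.append(np.linalg.norm(out - m_true))
        assert errs[0] > errs[1] > errs[2]

    def test_phase_ramp_object_recovers_ramp_slope(self):
        """A pure phase-ramp object keeps its ramp slope within 1% after
        reconstruction from noiseless full Cartesian sampling (phase
        fidelity of the fully complex pipeline)."""
        n = 12
        ax = np.arange(n) - n // 2
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        cart = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], 1).astype(float)
        coils = random_coils(n, 2, seed=15)
        op = EncodingOperator(coils, cart, engine="ndft")
        slope = 0.13
        m_true = np.exp(2j * np.pi * slope * gx)
        y = op.forward(m_true)
        cfg = MoDLConfig(n_unrolls=6, n_layers=3, features=2, alpha=0.45,
                         block_size=24, block_overlap=2)
        out = unrolled_recon(y, op, cfg, zero_denoiser(cfg))
        dphi = np.angle(out[1:, :, :] * np.conj(out[:-1, :, :]))
        slope_est = np.median(dphi) / (2 * np.pi)
        assert slope_est == pytest.approx(slope, rel=0.01)

    def test_divergence_is_flagged(self, rng):
        n = 8
        op = EncodingOperator(
            random_coils(n, 2, seed=16), rng.uniform(-3.5, 3.5, size=(50, 3)),
        )
        cfg = MoDLConfig(n_unrolls=30, n_layers=3, features=2, alpha=500.0,
                         block_size=16, block_overlap=2)
        y = op.forward(random_image(n, seed=17))
        with pytest.raises(modl.ReconstructionDiverged):
            unrolled_recon(y, op, cfg, zero_denoiser(cfg))


class TestBlockwise:
    def test_identity_is_bit_exact(self, rng):
        vol = rng.standard_normal((20, 20, 20)) + 1j * rng.standard_normal((20, 20, 20))
        out = blockwise_apply(vol, lambda b: b, 8, 4)
        assert np.array_equal(out, vol)

    def test_constant_function_consistency(self, rng):
        vol = rng.standard_normal((17, 17, 17))
        out = blockwise_apply(vol, lambda b: 2 * b, 6, 2)
        assert np.array_equal(out, 2 * vol)

    def test_block_larger_than_volume_single_block(self, rng):
        vol = rng.standard_normal((5, 5, 5))
        calls = []
        out = blockwise_apply(vol, lambda b: calls.append(b.shape) or b, 16, 4)
        assert calls == [(5, 5, 5)]
        assert np.array_equal(out, vol)

    def test_blockwise_denoiser_close_to_whole_volume(self):
        """A trained-scale denoiser applied in 8-voxel-overlap blocks stays
        within 5% of the whole-volume result (discrepancy near borders)."""
        cfg = MoDLConfig(n_layers=3, features=3, block_size=16, block_overlap=8)
        weights = init_denoiser(cfg, seed=18, scale=1.0)
        # give the last layer nonzero weights so the CNN actually acts
        rng = np.random.default_rng(19)
        weights[-1].X = 0.05 * rng.standard_normal(weights[-1].X.shape)
        weights[-1].Y = 0.05 * rng.standard_normal(weights[-1].Y.shape)
        vol = rng.standard_normal((32, 32, 32)) + 1j * rng.standard_normal((32, 32, 32))
        whole = denoiser_forward(vol, cfg, weights)
        blocked = blockwise_apply(
            vol, lambda b: denoiser_forward(b, cfg, weights), 16, 8
        )
        dyn = np.abs(whole).max() - np.abs(whole).min()
        assert np.max(np.abs(blocked - whole)) < 0.05 * dyn


class TestCheckpointing:
    def _loss(self, weights, z, ref, cfg, use_ckpt):
        wv = modl.weights_to_vars(weights)
        zv = ad.leaf(z, requires_grad=True)
        out = modl.denoiser_op(zv, cfg, wv, use_checkpoint=use_ckpt)
        loss = ad.nrmse(out, ad.constant(ref))
        ad.backward(loss)
        return loss, wv, zv

    def test_forward_and_gradients_bit_identical(self, rng):
        cfg = MoDLConfig(n_layers=3, features=3, block_size=16, block_overlap=2)
        weights = init_denoiser(cfg, seed=20, scale=0.7)
        z = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        ref = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        l1, wv1, zv1 = self._loss(weights, z, ref, cfg, True)
        l2, wv2, zv2 = self._loss(copy.deepcopy(weights), z, ref, cfg, False)
        assert float(l1.value) == float(l2.value)
        assert np.array_equal(zv1.grad, zv2.grad)
        for (a, b) in zip(wv1, wv2):
            for va, vb in zip(a, b):
                assert np.array_equal(va.grad, vb.grad)

    def test_checkpointing_stores_fewer_intermediates(self, rng):
        """The retained graph holds less array memory with checkpointing
        (activations are recomputed, not stored)."""
        cfg = MoDLConfig(n_layers=5, features=8, block_size=64, block_overlap=2)
        weights = init_denoiser(cfg, seed=21)
        z = rng.standard_normal((24, 24, 24)) + 1j * rng.standard_normal((24, 24, 24))
        ref = z * 0.9
        sizes = {}
        for ckpt in (True, False):
            wv = modl.weights_to_vars(weights)
            zv = ad.leaf(z, requires_grad=True)
            out = modl.denoiser_op(zv, cfg, wv, use_checkpoint=ckpt)
            loss = ad.nrmse(out, ad.constant(ref))
            sizes[ckpt] = ad.graph_saved_bytes(loss)
        assert sizes[True] < 0.5 * sizes[False]
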