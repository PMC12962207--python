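"""Analytic coordinate Jacobians vs float64 central finite differences.

The finite-difference oracle runs the encoding operator in its exact
direct-summation (NDFT) mode, where the spectral Jacobian is the exact
derivative of the operator being differentiated; the gridded path is
covered by the NDFT-consistency and kernel-autodiff comparison tests.
"""

import numpy as np
import pytest

from conftest import random_coils, random_coords, random_image
from learnedwave import autodiff as ad
from learnedwave import modl
from learnedwave.encoding import EncodingOperator
from learnedwave.gradients import (
    chain_to_wave_params,
    jacobian_vector_adjoint,
    jacobian_vector_forward,
    kernel_autodiff_coord_gradient,
)
from learnedwave.trajectory import HelixSet, WaveParams

FD_STEP = 1e-4


def _setup(seed, n=12, n_coils=2, n_samples=50):
    coils = random_coils(n, n_coils, seed=seed)
    m = random_image(n, seed=seed + 1)
    coords = random_coords(n_samples, n, seed=seed + 2, margin=0.6)
    rng = np.random.default_rng(seed + 3)
    y0 = rng.standard_normal((n_coils, n_samples)) + 1j * rng.standard_normal(
        (n_coils, n_samples)
    )
    return coils, m, coords, y0


def _make_op(coils):
    return lambda c: EncodingOperator(coils, c, engine="ndft")


class TestForwardJacobian:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        """grad of L = ||A(w) m - y0||^2 vs central FD, rel err < 1e-4."""
        coils, m, coords, y0 = _setup(seed)
        make_op = _make_op(coils)
        op = make_op(coords)
        gy = op.forward(m) - y0  # dL/d(conj y)
        grad = jacobian_vector_forward(m, op, gy)

        def loss(c):
            return float(np.sum(np.abs(make_op(c).forward(m) - y0) ** 2))

        rng = np.random.default_rng(seed)
        for _ in range(3):
            k, d = rng.integers(coords.shape[0]), rng.integers(3)
            cp, cm = coords.copy(), coords.copy()
            cp[k, d] += FD_STEP
            cm[k, d] -= FD_STEP
            fd = (loss(cp) - loss(cm)) / (2 * FD_STEP)
            assert abs(fd - grad[k, d]) / max(abs(fd), 1e-10) < 1e-4

    def test_zero_cotangent_gives_zero(self):
        coils, m, coords, _ = _setup(0)
        op = _make_op(coils)(coords)
        g = jacobian_vector_forward(m, op, np.zeros((2, 50), dtype=complex))
        assert np.all(g == 0)

    def test_center_sample_of_even_real_image_has_zero_gradient(self):
        """A real, even-symmetric image has a real even spectrum whose
        derivative vanishes at k = 0."""
        n = 12
        coils = random_coils(n, 1, seed=0)
        coils.maps[:] = 1.0
        x = np.arange(n) - n // 2
        prof = np.maximum(0.0, 1.0 - (x / 4.0) ** 2)  # compact, exactly even
        img = (
            prof[:, None, None] * prof[None, :, None] * prof[None, None, :]
        ).astype(complex)
        coords = np.zeros((1, 3))
        op = _make_op(coils)(coords)
        grad = jacobian_vector_forward(img, op, np.ones((1, 1), dtype=complex))
        assert np.max(np.abs(grad)) < 1e-10


class TestAdjointJacobian:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        """grad of L = ||A^H(w) y0 - mref||^2 vs central FD, rel < 1e-4."""
        coils, m, coords, y0 = _setup(seed + 100)
        make_op = _make_op(coils)
        mref = random_image(12, seed=seed + 104)
        op = make_op(coords)
        gm = op.adjoint(y0) - mref
        grad = jacobian_vector_adjoint(y0, op, gm)

        def loss(c):
            return float(np.sum(np.abs(make_op(c).adjoint(y0) - mref) ** 2))

        rng = np.random.default_rng(seed)
        for _ in range(3):
            k, d = rng.integers(coords.shape[0]), rng.integers(3)
            cp, cm = coords.copy(), coords.copy()
            cp[k, d] += FD_STEP
            cm[k, d] -= FD_STEP
            fd = (loss(cp) - loss(cm)) / (2 * FD_STEP)
            assert abs(fd - grad[k, d]) / max(abs(fd), 1e-10) < 1e-4

    def test_zero_cotangent_gives_zero(self):
        coils, _, coords, y0 = _setup(1)
        op = _make_op(coils)(coords)
        g = jacobian_vector_adjoint(y0, op, np.zeros((12,) * 3, dtype=complex))
        assert np.all(g == 0)

    def test_forward_adjoint_duality(self):
        """d/dw <A m, y>* computed through the forward Jacobian equals the
        same derivative computed through the adjoint Jacobian."""
        coils, m, coords, y0 = _setup(2)
        op = _make_op(coils)(coords)
        # L = Re<y0, A m> = Re<A^H y0, m>
        g_fwd = jacobian_vector_forward(m, op, y0 / 2.0)
        g_adj = jacobian_vector_adjoint(y0, op, m / 2.0)
        assert np.linalg.norm(g_fwd - g_adj) / np.linalg.norm(g_fwd) < 1e-5


class TestWaveParameterChain:
    def _wave_setup(self, seed):
        n = 12
        wp = WaveParams(
            r=2.0, cycles=3, echo_fraction=0.75, nro=10,
            dwell=2.7e-4, fov=24.0, matrix=n,
        )
        rng = np.random.default_rng(seed)
        npe = 6
        hs = HelixSet(
            kyc=rng.uniform(-3, 3, npe), kzc=rng.uniform(-3, 3, npe),
            sr=rng.uniform(0.4, 0.95, npe), theta=rng.uniform(0, 2 * np.pi, npe),
        )
        return wp, hs

    def test_zero_coordinate_gradient_chains_to_zeros(self):
        wp, hs = self._wave_setup(0)
        z = np.zeros((hs.npe, wp.nro, 3))
        for part in chain_to_wave_params(z, hs, wp):
            assert np.all(part == 0)

    def test_center_gradient_is_readout_sum(self):
        wp, hs = self._wave_setup(1)
        rng = np.random.default_rng(2)
        d = rng.standard_normal((hs.npe, wp.nro, 3))
        _, _, d_kyc, d_kzc = chain_to_wave_params(d, hs, wp)
        np.testing.assert_allclose(d_kyc, d[:, :, 1].sum(axis=1))
        np.testing.assert_allclose(d_kzc, d[:, :, 2].sum(axis=1))

    @pytest.mark.parametrize("param", ["sr", "theta", "kyc", "kzc"])
    def test_full_loss_gradient_matches_finite_differences(self, param):
        """End-to-end loss gradient w.r.t. each wave learnable vs FD."""
        wp, hs = self._wave_setup(3)
        coils = random_coils(12, 2, seed=4)
        m = random_image(12, seed=5)
        make_op = _make_op(coils)

        def loss_and_grads(values):
            kw = {k: getattr(hs, k).copy() for k in ("kyc", "kzc", "sr", "theta")}
            kw[param] = values
            leaves = {k: ad.leaf(v, k == param) for k, v in kw.items()}
            coords = ad.wave_coords_op(
                leaves["kyc"], leaves["kzc"], leaves["sr"], leaves["theta"], wp, hs
            )
            y = ad.nufft_forward_op(ad.constant(m), coords, make_op)
            loss = ad.nrmse(
                ad.nufft_adjoint_op(y, coords, make_op), ad.constant(m)
            )
            return loss, leaves[param]

        base = getattr(hs, param).copy()
        loss, leaf = loss_and_grads(base)
        ad.backward(loss)
        rng = np.random.default_rng(6)
        j = int(rng.integers(hs.npe))
        vp, vm = base.copy(), base.copy()
        vp[j] += FD_STEP
        vm[j] -= FD_STEP
        fd = (
            float(loss_and_grads(vp)[0].value) - float(loss_and_grads(vm)[0].value)
        ) / (2 * FD_STEP)
        assert abs(fd - leaf.grad[j]) / max(abs(fd), 1e-10) < 1e-4


class TestEndToEndCustomBackward:
    def test_unrolled_loss_coordinate_gradient_matches_fd(self):
        """NRMSE loss through a 2-unroll reconstruction: analytic gradient
        of one raw coordinate vs FD, rel err < 1e-3."""
        coils, m, coords0, _ = _setup(7, n_samples=40)
        make_op = _make_op(coils)
        cfg = modl.MoDLConfig(
            n_unrolls=2, n_layers=3, features=2, alpha=0.05,
            block_size=64, block_overlap=2,
        )
        weights = modl.init_denoiser(cfg, seed=8, scale=0.5)

        def loss_fn(c, requires=False):
            cv = ad.leaf(c, requires)
            y = ad.nufft_forward_op(ad.constant(m), cv, make_op)
            wv = modl.weights_to_vars(weights, requires_grad=False)
            m_hat = modl.unrolled_recon_op(
                y, cv, make_op, cfg, wv, ad.leaf(np.asarray(0.05), False)
            )
            return ad.nrmse(m_hat, ad.constant(m)), cv

        loss, cv = loss_fn(coords0, requires=True)
        ad.backward(loss)
        rng = np.random.default_rng(9)
        k, d = int(rng.integers(40)), int(rng.integers(3))
        step = 1e-5  # smaller step: the unrolled loss has strong curvature
        cp, cm = coords0.copy(), coords0.copy()
        cp[k, d] += step
        cm[k, d] -= step
        fd = (float(loss_fn(cp)[0].value) - float(loss_fn(cm)[0].value)) / (2 * step)
        assert abs(fd - cv.grad[k, d]) / max(abs(fd), 1e-10) < 1e-3

    def test_image_cotangent_is_exact_linear_transpose(self):
        coils, m, coords, _ = _setup(10)
        make_op = _make_op(coils)
        op = make_op(coords)
        mv = ad.leaf(m, True)
        y = ad.nufft_forward_op(mv, ad.leaf(coords, False), make_op)
        rng = np.random.default_rng(11)
        g = rng.standard_normal(y.value.shape) + 1j * rng.standard_normal(y.value.shape)
        y.grad = g
        y._backward(g)
        np.testing.assert_allclose(mv.grad, op.adjoint(g), rtol=1e-12)

    def test_kernel_autodiff_route_is_less_accurate(self):
        """Differentiating the interpolation kernel (the native-autodiff
        route through a gridded NUFFT) deviates more from the exact-operator
        FD gradient than the analytic spectral Jacobian does."""
        n = 12
        coils = random_coils(n, 1, seed=12)
        m = random_image(n, seed=13)
        coords = random_coords(40, n, seed=14, margin=0.6)
        rng = np.random.default_rng(15)
        y0 = rng.standard_normal((1, 40)) + 1j * rng.standard_normal((1, 40))
        op_exact = EncodingOperator(coils, coords, engine="ndft")
        op_grid = EncodingOperator(coils, coords, engine="nufft")
        gy = op_exact.forward(m) - y0
        g_true = jacobian_vector_forward(m, op_exact, gy)
        g_jac_grid = jacobian_vector_forward(m, op_grid, gy)
        g_kernel = kernel_autodiff_coord_gradient(m, op_grid, gy)
        err_jac = np.linalg.norm(g_jac_grid - g_true)
        err_kernel = np.linalg.norm(g_kernel - g_true)
        assert err_kernel > 1.5 * err_jac

    def test_gradients_are_real_valued(self):
        coils, m, coords, y0 = _setup(16)
        op = _make_op(coils)(coords)
        g = jacobian_vector_forward(m, op, op.forward(m) - y0)
        assert np.isrealobj(g)
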