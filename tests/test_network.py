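"""Unrolled network: denoiser, CG data consistency, and the gradient
checkpointing contract."""

import numpy as np
import pytest

import qmrecon as q
from qmrecon import autodiff as ad
from qmrecon import network as nw
from conftest import random_sensitivities


def arr(x):
    """Unwrap a Tensor to its ndarray."""
    return x.data if hasattr(x, "requires_grad") else np.asarray(x)


def small_instance(seed, p=2, c=2, h=8, w=8, density=0.5):
    rng = np.random.default_rng(seed)
    sens = random_sensitivities(rng, c, h, w)
    masks = rng.random((p, h, w)) < density
    masks[:, h // 2, :] = True  # keep the system reasonably conditioned
    y = (rng.normal(size=(p, c, h, w)) + 1j * rng.normal(size=(p, c, h, w))) \
        * masks[:, None]
    z = rng.normal(size=(p, h, w)) + 1j * rng.normal(size=(p, h, w))
    return y, z, sens, masks


class TestDenoiser:
    def test_zero_weights_give_identity(self):
        rng = np.random.default_rng(0)
        params = nw.DenoiserParams.init(3, n_blocks=2, n_filters=4, init_scale=0)
        x = rng.normal(size=(3, 8, 8)) + 1j * rng.normal(size=(3, 8, 8))
        np.testing.assert_array_equal(arr(nw.denoise(x, params)), x)

    def test_fresh_initialization_is_identity_via_zero_output_conv(self):
        rng = np.random.default_rng(1)
        params = nw.DenoiserParams.init(2, n_blocks=2, n_filters=4, seed=3)
        x = rng.normal(size=(2, 8, 8)) + 1j * rng.normal(size=(2, 8, 8))
        np.testing.assert_allclose(arr(nw.denoise(x, params)), x, atol=1e-12)

    @pytest.mark.parametrize("p,h,w", [(1, 8, 8), (4, 12, 10)])
    def test_output_shape_matches_input(self, p, h, w):
        rng = np.random.default_rng(2)
        params = nw.DenoiserParams.init(p, n_blocks=1, n_filters=4, seed=1)
        x = rng.normal(size=(p, h, w)) + 1j * rng.normal(size=(p, h, w))
        assert arr(nw.denoise(x, params)).shape == x.shape

    def test_channel_mismatch_rejected(self):
        params = nw.DenoiserParams.init(2, n_blocks=1, n_filters=4)
        with pytest.raises(ValueError):
            nw.denoise(np.zeros((3, 8, 8), complex), params)

    def test_weight_gradient_matches_central_difference(self):
        rng = np.random.default_rng(3)
        params = nw.DenoiserParams.init(2, n_blocks=2, n_filters=4, seed=5)
        # make the output conv nonzero so every layer participates
        params.weights[-2].data = rng.normal(scale=0.05,
                                             size=params.weights[-2].data.shape)
        x = rng.normal(size=(2, 8, 8)) + 1j * rng.normal(size=(2, 8, 8))

        def loss_value():
            with ad.no_grad():
                out = arr(nw.denoise(x, params))
            return float(np.sum(np.abs(out) ** 2))

        out = nw.denoise(x, params)
        loss = ad.tsum(ad.mul(ad.conj(out), out))
        ad.real(loss).backward()
        for wi, flat in ((0, 3), (2, 10), (-2, 4)):
            w = params.weights[wi]
            g = w.grad.flat[flat]
            eps = 1e-6
            w.data.flat[flat] += eps
            lp = loss_value()
            w.data.flat[flat] -= 2 * eps
            lm = loss_value()
            w.data.flat[flat] += eps
            fd = (lp - lm) / (2 * eps)
            assert abs(g - fd) < 1e-4 * max(1.0, abs(fd))


class TestDCSolve:
    def test_huge_lambda_returns_prior(self):
        y, z, sens, masks = small_instance(0)
        cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=20, lam=1e6)
        out = nw.dc_solve(z, y, sens, masks, cfg)
        assert np.abs(out - z).max() / np.abs(z).max() < 1e-4

    def test_full_mask_uniform_coil_single_step_solution(self):
        rng = np.random.default_rng(4)
        h = w = 8
        sens = q.CoilSensitivitySet(np.ones((1, h, w), complex),
                                    np.ones((h, w), bool))
        masks = np.ones((1, h, w), bool)
        y = rng.normal(size=(1, 1, h, w)) + 1j * rng.normal(size=(1, 1, h, w))
        z = rng.normal(size=(1, h, w)) + 1j * rng.normal(size=(1, h, w))
        lam = 0.3
        cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=1, lam=lam)
        out = nw.dc_solve(z, y, sens, masks, cfg)
        # Q = (1 + lam) I, solved exactly in one CG step
        expected = (q.apply_EH(y, sens, masks) + lam * z) / (1 + lam)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_cg_matches_dense_solve_oracle(self, seed):
        y, z, sens, masks = small_instance(seed, p=1, c=1, h=4, w=4, density=0.6)
        lam = 0.05
        cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=40, lam=lam)
        out = nw.dc_solve(z, y, sens, masks, cfg)
        n = z.size
        Q = np.zeros((n, n), complex)
        for i in range(n):
            e = np.zeros(n, complex)
            e[i] = 1.0
            Q[:, i] = q.normal_op(e.reshape(z.shape), sens, masks, lam=lam).ravel()
        b = (q.apply_EH(y, sens, masks) + lam * z).ravel()
        dense = np.linalg.solve(Q, b).reshape(z.shape)
        assert np.abs(out - dense).max() < 1e-8

    def test_cg_residual_decreases_monotonically(self):
        y, z, sens, masks = small_instance(6)
        lam = 0.1
        b = q.apply_EH(y, sens, masks) + lam * z
        res = []
        for iters in range(1, 15):
            cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=iters, lam=lam)
            x = nw.dc_solve(z, y, sens, masks, cfg)
            res.append(np.linalg.norm(q.normal_op(x, sens, masks, lam=lam) - b)
                       / np.linalg.norm(b))
        assert all(b2 <= a2 + 1e-12 for a2, b2 in zip(res, res[1:]))
        cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=40, lam=lam)
        x = nw.dc_solve(z, y, sens, masks, cfg)
        assert np.linalg.norm(q.normal_op(x, sens, masks, lam=lam) - b) \
            / np.linalg.norm(b) < 1e-6

    def test_nonfinite_inputs_rejected(self):
        y, z, sens, masks = small_instance(7)
        z[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            nw.dc_solve(z, y, sens, masks, nw.UnrollConfig())


class TestUnrolledRecon:
    def test_fully_sampled_identity_denoiser_recovers_truth(self):
        rng = np.random.default_rng(8)
        h = w = 8
        sens = q.CoilSensitivitySet(np.ones((1, h, w), complex),
                                    np.ones((h, w), bool))
        masks = np.ones((1, h, w), bool)
        gt = rng.normal(size=(1, h, w)) + 1j * rng.normal(size=(1, h, w))
        y = q.apply_E(gt, sens, masks)
        params = nw.DenoiserParams.init(1, n_blocks=1, n_filters=4, init_scale=0)
        cfg = nw.UnrollConfig(n_unrolls=3, cg_iters=10, lam=0.05)
        out = arr(nw.unrolled_recon(y, sens, masks, params, cfg))
        assert np.abs(out - gt).max() < 1e-6

    def test_single_unroll_equals_denoise_then_dc(self):
        y, _, sens, masks = small_instance(9)
        params = nw.DenoiserParams.init(2, n_blocks=1, n_filters=4, seed=2)
        params.weights[-2].data = np.random.default_rng(0).normal(
            scale=0.05, size=params.weights[-2].data.shape)
        cfg = nw.UnrollConfig(n_unrolls=1, cg_iters=5, lam=0.05)
        out = arr(nw.unrolled_recon(y, sens, masks, params, cfg))
        x0 = q.apply_EH(y, sens, masks)
        expected = arr(nw.dc_solve(nw.denoise(x0, params), y, sens, masks, cfg))
        np.testing.assert_array_equal(out, expected)


class TestCheckpointing:
    def _training_setup(self, n_blocks=2, seed=10):
        rng = np.random.default_rng(seed)
        p, c, h, w = 2, 2, 16, 16
        sens = random_sensitivities(rng, c, h, w)
        masks = rng.random((p, h, w)) < 0.4
        masks[:, h // 2] = True
        y = (rng.normal(size=(p, c, h, w)) + 1j * rng.normal(size=(p, c, h, w))) \
            * masks[:, None]
        u = rng.normal(size=(p, c, h, w)) + 1j * rng.normal(size=(p, c, h, w))
        params = nw.DenoiserParams.init(p, n_blocks=n_blocks, n_filters=8, seed=seed)
        params.weights[-2].data = rng.normal(scale=0.05,
                                             size=params.weights[-2].data.shape)
        cfg = nw.UnrollConfig(n_unrolls=2, cg_iters=5, lam=0.05)
        return y, u, sens, masks, params, cfg

    def _loss_and_grads(self, fn, y, u, sens, masks, params, cfg):
        for w in params.weights:
            w.grad = None
        x = fn(y, sens, masks, params, cfg)
        loss = q.recon_loss(u, q.apply_E(x, sens, np.ones_like(masks)))
        loss.backward()
        return x.data.copy(), [w.grad.copy() for w in params.weights]

    def test_forward_outputs_bit_identical(self):
        setup = self._training_setup()
        x1, _ = self._loss_and_grads(nw.unrolled_recon, *setup)
        x2, _ = self._loss_and_grads(nw.checkpointed_unrolled_recon, *setup)
        assert np.array_equal(x1, x2)

    def test_gradients_match_within_tolerance(self):
        setup = self._training_setup()
        _, g1 = self._loss_and_grads(nw.unrolled_recon, *setup)
        _, g2 = self._loss_and_grads(nw.checkpointed_unrolled_recon, *setup)
        for a, b in zip(g1, g2):
            scale = max(np.abs(a).max(), 1e-30)
            assert np.abs(a - b).max() / scale < 1e-5

    def test_retained_graph_independent_of_block_count(self):
        sizes = {}
        for n_blocks in (1, 2, 6):
            y, u, sens, masks, params, cfg = self._training_setup(n_blocks=n_blocks)
            x = nw.checkpointed_unrolled_recon(y, sens, masks, params, cfg)
            sizes[n_blocks] = ad.graph_size(x)
        assert len(set(sizes.values())) == 1
        # while the plain version grows with depth
        y, u, sens, masks, params, cfg = self._training_setup(n_blocks=1)
        plain1 = ad.graph_size(nw.unrolled_recon(y, sens, masks, params, cfg))
        y, u, sens, masks, params, cfg = self._training_setup(n_blocks=6)
        plain6 = ad.graph_size(nw.unrolled_recon(y, sens, masks, params, cfg))
        assert plain6 > plain1

    def test_denoiser_evaluated_twice_per_unroll(self):
        setup = self._training_setup()
        cfg = setup[5]
        nw.DENOISE_CALLS = 0
        self._loss_and_grads(nw.checkpointed_unrolled_recon, *setup)
        assert nw.DENOISE_CALLS == 2 * cfg.n_unrolls
        nw.DENOISE_CALLS = 0
        self._loss_and_grads(nw.unrolled_recon, *setup)
        assert nw.DENOISE_CALLS == cfg.n_unrolls
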