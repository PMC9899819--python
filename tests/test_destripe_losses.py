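"""Analytic and oracle tests of the composite de-striping objective."""

import numpy as np
import pytest
from scipy.optimize import minimize

from octaclear.destripe_losses import (
    DestripeWeights,
    atv,
    atv_loss,
    destripe_loss,
    reconstruction_loss,
    shrink_singular_values,
    stripe_degrade,
    stripe_loss,
)
from octaclear.nn.tensor import Tensor

from conftest import numgrad


# ---------------------------------------------------------------------------
# reconstruction loss
# ---------------------------------------------------------------------------

class TestReconstructionLoss:
    def test_zero_residual(self, rng):
        n = rng.random((8, 8))
        c = rng.random((8, 8))
        assert reconstruction_loss(n + c, n, c) == 0.0

    def test_constant_residual_closed_form(self):
        m, n, d = 5, 7, 0.3
        i_in = np.full((m, n), d)
        zero = np.zeros((m, n))
        assert reconstruction_loss(i_in, zero, zero) == pytest.approx(
            0.5 * abs(d) * np.sqrt(m * n), abs=1e-12
        )

    def test_matches_elementwise_oracle(self, rng):
        i_in, n_out, c_out = rng.random((3, 8, 8))
        r = i_in - (n_out + c_out)
        oracle = np.sqrt((r**2).sum()) / 2
        assert reconstruction_loss(i_in, n_out, c_out) == pytest.approx(oracle, abs=1e-10)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss(rng.random((8, 8)), rng.random((8, 8)), rng.random((4, 4)))


# ---------------------------------------------------------------------------
# singular-value shrinkage and stripe degradation
# ---------------------------------------------------------------------------

class TestShrink:
    def test_worked_example(self):
        np.testing.assert_allclose(
            shrink_singular_values([3.0, 1.0, 0.001], 0.5), [2.5, 0.5, 0.0]
        )

    def test_zero_threshold_is_identity(self, rng):
        s = np.sort(rng.random(6))[::-1]
        np.testing.assert_array_equal(shrink_singular_values(s, 0.0), s)

    def test_full_suppression(self):
        assert np.all(shrink_singular_values([0.1, 0.05], 0.5) == 0.0)

    def test_output_sorted_nonincreasing(self, rng):
        s = np.sort(rng.random(8))[::-1]
        out = shrink_singular_values(s, 0.3)
        assert np.all(np.diff(out) <= 0)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            shrink_singular_values([1.0, -0.1], 0.5)


def nuclear_norm(m):
    return np.linalg.svd(m, compute_uv=False).sum()


class TestStripeDegrade:
    def test_rank_one_closed_form(self, rng):
        u = rng.normal(size=6)
        u /= np.linalg.norm(u)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        s, lam = 2.0, 0.5
        out = stripe_degrade(s * np.outer(u, v), lam)
        np.testing.assert_allclose(out, (s - lam) * np.outer(u, v), atol=1e-10)

    def test_zero_matrix(self):
        np.testing.assert_array_equal(stripe_degrade(np.zeros((5, 5)), 0.1), np.zeros((5, 5)))

    def test_singular_values_are_shrunk(self, rng):
        n = rng.normal(size=(8, 8))
        lam = 0.4
        s_in = np.linalg.svd(n, compute_uv=False)
        s_out = np.linalg.svd(stripe_degrade(n, lam), compute_uv=False)
        np.testing.assert_allclose(s_out, np.maximum(s_in - lam, 0.0), atol=1e-10)

    def test_matches_nuclear_norm_prox_by_minimization(self, rng):
        """Soft-thresholding is the closed-form proximal operator of the
        nuclear norm: argmin_X 1/2||X-N||_F^2 + lam*||X||_*.  Verified by
        smooth numerical minimization from multiple starts."""
        n = rng.normal(size=(6, 6))
        lam = 0.4 * np.linalg.svd(n, compute_uv=False).min()  # full-rank optimum

        def obj_grad(xflat):
            x = xflat.reshape(6, 6)
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            f = 0.5 * ((x - n) ** 2).sum() + lam * s.sum()
            g = (x - n) + lam * (u @ vt)
            return f, g.ravel()

        best = None
        for start in (n, n + 0.1 * rng.normal(size=(6, 6)), 0.5 * n):
            res = minimize(obj_grad, start.ravel(), jac=True, method="BFGS",
                           options={"gtol": 1e-12, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        np.testing.assert_allclose(
            stripe_degrade(n, lam), best.x.reshape(6, 6), atol=1e-6
        )

    def test_contraction_of_nuclear_norm(self, rng):
        n = rng.normal(size=(8, 8))
        assert nuclear_norm(stripe_degrade(n, 0.3)) < nuclear_norm(n)
        np.testing.assert_allclose(
            nuclear_norm(stripe_degrade(n, 0.0)), nuclear_norm(n), atol=1e-9
        )

    def test_non_finite_raises(self):
        bad = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            stripe_degrade(bad, 0.1)


class TestStripeLoss:
    def test_identical_arguments_zero(self, rng):
        n = rng.random((8, 8))
        assert stripe_loss(n, n, 0.002) == 0.0

    def test_symmetry(self, rng):
        a, b = rng.random((2, 8, 8))
        assert stripe_loss(a, b, 0.1) == pytest.approx(stripe_loss(b, a, 0.1), abs=1e-12)

    def test_composition_oracle(self, rng):
        a, b = rng.random((2, 8, 8))
        lam = 0.05
        oracle = np.linalg.norm(stripe_degrade(a, lam) - stripe_degrade(b, lam), "fro")
        assert stripe_loss(a, b, lam) == pytest.approx(oracle, abs=1e-8)


# ---------------------------------------------------------------------------
# anisotropic total variation
# ---------------------------------------------------------------------------

class TestATV:
    def test_constant_image_zero(self):
        assert atv(np.full((8, 8), 0.7)) == 0.0

    def test_hand_counted_2x2(self):
        assert atv(np.array([[0.0, 1.0], [0.0, 1.0]])) == 2.0

    @pytest.mark.parametrize("k", [-2.0, 0.5, 3.0])
    def test_homogeneity(self, k, rng):
        c = rng.random((16, 16))
        assert atv(k * c) == pytest.approx(abs(k) * atv(c), rel=1e-12)

    def test_shift_invariance(self, rng):
        c = rng.random((16, 16))
        assert atv(c + 0.37) == pytest.approx(atv(c), rel=1e-10)

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="2x2"):
            atv(np.ones((1, 5)))


class TestATVLoss:
    def test_identical_zero(self, rng):
        c = rng.random((8, 8))
        assert atv_loss(c, c) == 0.0

    def test_constant_shift_zero(self, rng):
        c = rng.random((8, 8))
        assert atv_loss(c, c + 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_oracle(self, rng):
        a, b = rng.random((2, 8, 8))
        assert atv_loss(a, b) == pytest.approx(abs(atv(a) - atv(b)), abs=1e-12)

    def test_map_variant_detects_rearranged_edges(self, rng):
        # same total variation, differently placed: scalar form is blind,
        # the map variant is not
        a = np.zeros((8, 8))
        a[:, 4:] = 1.0
        b = np.zeros((8, 8))
        b[4:, :] = 1.0
        assert atv_loss(a, b) == pytest.approx(0.0, abs=1e-12)
        assert atv_loss(a, b, variant="map") > 1.0


# ---------------------------------------------------------------------------
# combined objective
# ---------------------------------------------------------------------------

class TestDestripeLoss:
    def test_perfect_prediction_is_zero(self, rng):
        n_ref, c_ref = rng.random((2, 8, 8))
        i_in = n_ref + c_ref
        assert destripe_loss(i_in, n_ref, c_ref, n_ref, c_ref) == 0.0

    def test_weight_masking_reduces_to_reconstruction(self, rng):
        i_in, n_out, c_out, n_ref, c_ref = rng.random((5, 8, 8))
        w = DestripeWeights(alpha=1.0, beta=0.0, gamma=0.0)
        assert destripe_loss(i_in, n_out, c_out, n_ref, c_ref, w) == pytest.approx(
            reconstruction_loss(i_in, n_out, c_out), abs=1e-12
        )

    def test_linear_combination_oracle_with_defaults(self, rng):
        i_in, n_out, c_out, n_ref, c_ref = rng.random((5, 8, 8))
        w = DestripeWeights()  # (0.5, 2, 1, 0.002)
        expected = (
            w.alpha * reconstruction_loss(i_in, n_out, c_out)
            + w.beta * stripe_loss(n_ref, n_out, w.lam)
            + w.gamma * atv_loss(c_ref, c_out)
        )
        assert destripe_loss(i_in, n_out, c_out, n_ref, c_ref, w) == pytest.approx(
            expected, abs=1e-8
        )

    def test_continuity_in_n_out(self, rng):
        i_in, n_out, c_out, n_ref, c_ref = rng.random((5, 8, 8))
        base = destripe_loss(i_in, n_out, c_out, n_ref, c_ref)
        for eps in (1e-3, 1e-4, 1e-5):
            pert = destripe_loss(i_in, n_out + eps, c_out, n_ref, c_ref)
            assert abs(pert - base) < 100 * eps

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            DestripeWeights(alpha=-1.0)
        with pytest.raises(ValueError):
            DestripeWeights(lam=0.0)

    @pytest.mark.parametrize("wrt", ["n_out", "c_out"])
    def test_gradient_matches_finite_differences(self, wrt, rng):
        """Autodiff gradient of the full objective vs central differences
        (random inputs keep us away from the non-smooth points)."""
        i_in, n_out, c_out, n_ref, c_ref = rng.random((5, 8, 8))
        w = DestripeWeights(lam=0.05)
        args = {"n_out": n_out, "c_out": c_out}

        def f(arr):
            cur = dict(args)
            cur[wrt] = arr
            return destripe_loss(i_in, cur["n_out"], cur["c_out"], n_ref, c_ref, w)

        t = Tensor(args[wrt], requires_grad=True)
        cur = {k: (t if k == wrt else v) for k, v in args.items()}
        destripe_loss(i_in, cur["n_out"], cur["c_out"], n_ref, c_ref, w).backward()
        ng = numgrad(f, args[wrt])
        assert np.abs(t.grad - ng).max() / np.abs(ng).max() < 1e-4
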