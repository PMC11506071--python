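"""Loss functions: closed forms, limits, and an independent SSIM oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laryngoseg.losses import (
    LossWeights,
    clip_weights,
    latent_consistency_loss,
    reconstruction_loss,
    smooth_labels,
    ssim,
    validity_loss,
)
from laryngoseg.nn import Tensor


def ssim_oracle(a, b, window=7, k1=0.01, k2=0.03):
    """Loop-based windowed SSIM with zero padding (independent of autograd)."""
    c1, c2 = k1**2, k2**2
    half = window // 2
    n, c, h, w = a.shape
    pa = np.pad(a, ((0, 0), (0, 0), (half, half), (half, half)))
    pb = np.pad(b, ((0, 0), (0, 0), (half, half), (half, half)))
    vals = []
    for ni in range(n):
        for ci in range(c):
            for y in range(h):
                for x in range(w):
                    wa = pa[ni, ci, y : y + window, x : x + window]
                    wb = pb[ni, ci, y : y + window, x : x + window]
                    ma, mb = wa.mean(), wb.mean()
                    va = (wa * wa).mean() - ma * ma
                    vb = (wb * wb).mean() - mb * mb
                    cov = (wa * wb).mean() - ma * mb
                    vals.append(
                        ((2 * ma * mb + c1) * (2 * cov + c2))
                        / ((ma * ma + mb * mb + c1) * (va + vb + c2))
                    )
    return float(np.mean(vals))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((1, 3, 12, 12)).astype(np.float32)
        assert ssim(x, x).item() == pytest.approx(1.0, abs=1e-5)

    def test_constant_pair_is_one(self):
        x = np.full((1, 1, 8, 8), 0.4, np.float32)
        assert ssim(x, x.copy()).item() == pytest.approx(1.0, abs=1e-5)

    def test_inverted_checkerboard_is_negative(self):
        yy, xx = np.mgrid[0:8, 0:8]
        board = ((yy + xx) % 2).astype(np.float32)[None, None]
        value = ssim(board, 1.0 - board).item()
        assert value < 0.0
        assert value == pytest.approx(ssim_oracle(board, 1.0 - board), abs=1e-4)

    def test_matches_loop_oracle_on_random_pair(self, rng):
        a = rng.random((1, 2, 6, 6)).astype(np.float32)
        b = rng.random((1, 2, 6, 6)).astype(np.float32)
        assert ssim(a, b).item() == pytest.approx(ssim_oracle(a, b), abs=1e-4)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)), window=4)


class TestReconstructionLoss:
    def test_perfect_prediction_is_zero_for_any_epoch(self, rng):
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        for epoch in (0, 5, 14):
            assert reconstruction_loss(x, x.copy(), epoch).item() == pytest.approx(0.0, abs=1e-5)

    def test_alpha_one_reduces_to_mse(self, rng):
        pred = rng.random((1, 3, 8, 8)).astype(np.float32)
        gt = rng.random((1, 3, 8, 8)).astype(np.float32)
        loss = reconstruction_loss(pred, gt, epoch=0)  # schedule starts at α=1
        assert loss.item() == pytest.approx(float(((pred - gt) ** 2).mean()), rel=1e-5)

    def test_alpha_zero_equals_one_minus_ssim(self, rng):
        w = LossWeights(alpha_floor=0.0, total_epochs=2)
        gt = rng.random((1, 3, 8, 8)).astype(np.float32)
        pred = np.clip(gt + 0.1, 0.0, 1.0).astype(np.float32)
        loss = reconstruction_loss(pred, gt, epoch=1, weights=w)
        assert loss.item() == pytest.approx(1.0 - ssim(pred, gt).item(), abs=1e-5)

    def test_negative_epoch_rejected(self, rng):
        x = rng.random((1, 3, 4, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            reconstruction_loss(x, x, epoch=-1)

    def test_decreases_toward_zero_along_interpolation(self, rng):
        w = LossWeights(alpha_floor=0.5, total_epochs=2)
        gt = rng.random((1, 3, 8, 8)).astype(np.float32)
        far = rng.random((1, 3, 8, 8)).astype(np.float32)
        losses = [
            reconstruction_loss(gt + t * (far - gt), gt, epoch=1, weights=w).item()
            for t in (1.0, 0.5, 0.0)
        ]
        assert losses[0] > losses[1] > losses[2] >= 0.0

    def test_alpha_schedule_monotone_non_increasing(self):
        w = LossWeights(total_epochs=10, alpha_floor=0.5)
        alphas = [w.mse_ssim_blend(e) for e in range(12)]
        assert alphas[0] == 1.0
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))
        assert alphas[9] == pytest.approx(0.5)


class TestSmoothLabels:
    def test_eps_zero_is_identity(self):
        one_hot = np.eye(7)[3]
        np.testing.assert_array_equal(smooth_labels(one_hot, 0.0), one_hot)

    def test_seven_class_values(self):
        out = smooth_labels(np.eye(7)[2], 0.1)
        assert out[2] == pytest.approx(0.9 + 0.1 / 7)
        off = np.delete(out, 2)
        np.testing.assert_allclose(off, 0.1 / 7)
        assert out.sum() == pytest.approx(1.0)

    def test_bad_eps_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(np.eye(3)[0], 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(2, 12), st.floats(0.0, 0.99), st.data())
    def test_always_sums_to_one(self, k, eps, data):
        hot = data.draw(st.integers(0, k - 1))
        out = smooth_labels(np.eye(k)[hot], eps)
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()


class TestValidityLoss:
    def test_logit_zero_gives_ln_two_for_both_targets(self):
        assert validity_loss(0.0, 1.0).item() == pytest.approx(math.log(2), rel=1e-5)
        assert validity_loss(0.0, 0.0).item() == pytest.approx(math.log(2), rel=1e-5)

    def test_confident_correct_logit_drives_loss_to_zero(self):
        assert validity_loss(30.0, 1.0).item() == pytest.approx(0.0, abs=1e-6)
        assert validity_loss(-30.0, 0.0).item() == pytest.approx(0.0, abs=1e-6)

    def test_non_finite_logit_rejected(self):
        with pytest.raises(ValueError):
            validity_loss(float("nan"), 1.0)


class TestLatentConsistency:
    def test_identical_latents_give_zero(self, rng):
        z = rng.normal(size=32).astype(np.float32)
        assert latent_consistency_loss(z, z.copy()).item() == 0.0

    def test_unit_offset_gives_one(self):
        z = np.zeros(32, np.float32)
        assert latent_consistency_loss(z, z + 1.0).item() == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a = rng.normal(size=32).astype(np.float32)
        b = rng.normal(size=32).astype(np.float32)
        assert latent_consistency_loss(a, b).item() == pytest.approx(
            latent_consistency_loss(b, a).item()
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            latent_consistency_loss(np.zeros(32), np.zeros(16))


class TestClipWeights:
    def test_in_range_params_unchanged(self):
        original = np.array([0.005, -0.009], np.float32)
        p = Tensor(original.copy(), requires_grad=True)
        clip_weights([p], 0.01)
        np.testing.assert_array_equal(p.data, original)

    def test_out_of_range_param_clamped(self):
        p = Tensor(np.array([5.0], np.float32), requires_grad=True)
        clip_weights([p], 0.01)
        assert p.data[0] == pytest.approx(0.01)

    def test_idempotent(self, rng):
        p = Tensor(rng.normal(size=20).astype(np.float32), requires_grad=True)
        clip_weights([p], 0.05)
        once = p.data.copy()
        clip_weights([p], 0.05)
        np.testing.assert_array_equal(p.data, once)

    def test_non_positive_c_rejected(self):
        with pytest.raises(ValueError):
            clip_weights([], 0.0)


def test_all_loss_terms_non_negative_and_finite(rng):
    pred = rng.random((1, 3, 8, 8)).astype(np.float32)
    gt = rng.random((1, 3, 8, 8)).astype(np.float32)
    terms = [
        reconstruction_loss(pred, gt, epoch=3).item(),
        validity_loss(rng.normal(), 1.0).item(),
        latent_consistency_loss(rng.normal(size=8), rng.normal(size=8)).item(),
    ]
    assert all(np.isfinite(t) and t >= 0 for t in terms)
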