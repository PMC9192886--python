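"""Loss definitions against independent elementwise/windowed re-computation,
plus the identities the composite and deep-supervision losses must satisfy."""

import numpy as np
import pytest

from spectboost.loss import (LossWeights, combined_loss, l1_loss,
                             lesion_attention_loss, ssim_index, ssim_loss,
                             total_loss)
from spectboost.nn import tensor as T
from spectboost.exceptions import ContractError


def brute_l1(pred, target, mask=None):
    total, n = 0.0, 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if mask is None or mask[i, j]:
                total += abs(pred[i, j] - target[i, j])
                n += 1
    return total / n if n else 0.0


def brute_ssim_map(x, y, win, data_range, k1=0.01, k2=0.03):
    """Direct sliding-window evaluation of the SSIM formula with population
    moments — independent of the conv-based implementation."""
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    H, W = x.shape
    out = np.empty((H - win + 1, W - win + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            xw = x[i:i + win, j:j + win]
            yw = y[i:i + win, j:j + win]
            mx, my = xw.mean(), yw.mean()
            vx, vy = xw.var(), yw.var()
            cov = ((xw - mx) * (yw - my)).mean()
            out[i, j] = ((2 * mx * my + c1) * (2 * cov + c2)
                         / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return out


@pytest.fixture
def pair(rng):
    pred = rng.normal(1.0, 0.4, size=(16, 16))
    target = np.abs(rng.normal(1.0, 0.4, size=(16, 16)))
    return pred, target


class TestL1:
    def test_equal_inputs_zero(self, pair):
        _, t = pair
        assert l1_loss(t, t) == 0.0

    def test_constant_offset(self, pair):
        _, t = pair
        assert l1_loss(t + 0.5, t) == pytest.approx(0.5, abs=1e-12)

    def test_matches_elementwise_oracle(self, pair, rng):
        p, t = pair
        mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        assert l1_loss(p, t) == pytest.approx(brute_l1(p, t), abs=1e-7)
        assert l1_loss(p, t, mask) == pytest.approx(brute_l1(p, t, mask), abs=1e-7)

    def test_empty_mask_returns_zero(self, pair):
        p, t = pair
        assert l1_loss(p, t, np.zeros_like(t, dtype=np.uint8)) == 0.0


class TestSSIM:
    def test_equal_inputs_zero_loss(self, pair):
        _, t = pair
        assert ssim_loss(t, t, weights=LossWeights(ssim_window=7)) == pytest.approx(0.0, abs=1e-9)

    def test_independent_noise_in_range(self, rng):
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        loss = ssim_loss(a, b, weights=LossWeights(ssim_window=7))
        assert 0 < loss <= 2.0

    def test_matches_windowed_oracle(self, rng):
        x = rng.normal(2.0, 1.0, size=(8, 8))
        y = rng.normal(2.0, 1.0, size=(8, 8))
        w = LossWeights(ssim_window=5)
        r = float(np.ptp(y))
        ref = 1.0 - brute_ssim_map(x, y, 5, r).mean()
        assert ssim_loss(x, y, weights=w) == pytest.approx(ref, abs=1e-6)
        assert ssim_index(x, y, window=5) == pytest.approx(1.0 - ref, abs=1e-6)

    def test_masked_matches_oracle(self, rng):
        x = rng.normal(2.0, 1.0, size=(10, 10))
        y = rng.normal(2.0, 1.0, size=(10, 10))
        mask = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        w = LossWeights(ssim_window=5)
        smap = brute_ssim_map(x, y, 5, float(np.ptp(y)))
        mv = mask[2:-2, 2:-2]
        ref = 1.0 - smap[mv.astype(bool)].mean()
        assert ssim_loss(x, y, mask, w) == pytest.approx(ref, abs=1e-6)

    def test_even_window_rejected(self):
        with pytest.raises(ContractError):
            LossWeights(ssim_window=8)

    def test_window_larger_than_image_rejected(self, rng):
        x = rng.normal(size=(8, 8))
        with pytest.raises(ContractError):
            ssim_loss(x, x, weights=LossWeights(ssim_window=11))


class TestComposite:
    def test_zero_at_equality(self, pair):
        _, t = pair
        assert combined_loss(t, t, LossWeights(ssim_window=7)) == pytest.approx(0.0, abs=1e-9)

    def test_alpha_zero_is_l1(self, pair):
        p, t = pair
        w = LossWeights(alpha=0.0, ssim_window=7)
        assert combined_loss(p, t, w) == pytest.approx(l1_loss(p, t), abs=1e-12)

    def test_weighted_sum_of_components(self, pair):
        p, t = pair
        w = LossWeights(alpha=0.5, ssim_window=7)
        expect = l1_loss(p, t) + 0.5 * ssim_loss(p, t, weights=w)
        assert combined_loss(p, t, w) == pytest.approx(expect, rel=1e-12)


class TestLesionAttention:
    def test_empty_mask_reduces_to_whole_image_loss(self, pair):
        p, t = pair
        w = LossWeights(ssim_window=7)
        m = np.zeros_like(t, dtype=np.uint8)
        assert lesion_attention_loss(p, t, m, w) == pytest.approx(
            combined_loss(p, t, w), rel=1e-12)

    def test_full_mask_scales_by_one_plus_beta(self, pair):
        p, t = pair
        w = LossWeights(beta=100.0, ssim_window=7)
        m = np.ones_like(t, dtype=np.uint8)
        got = lesion_attention_loss(p, t, m, w)
        assert got == pytest.approx(101.0 * combined_loss(p, t, w), rel=1e-9)

    def test_zero_at_equality_any_mask(self, pair, rng):
        _, t = pair
        m = (rng.random(t.shape) < 0.5).astype(np.uint8)
        assert lesion_attention_loss(t, t, m, LossWeights(ssim_window=7)) == pytest.approx(
            0.0, abs=1e-9)


class TestTotalLoss:
    def test_all_outputs_equal_target_gives_zero(self, pair):
        _, t = pair
        w = LossWeights(ssim_window=7)
        m = np.zeros_like(t, dtype=np.uint8)
        assert total_loss(t, [t] * 6, t, m, w) == pytest.approx(0.0, abs=1e-9)

    def test_identical_outputs_unit_weights_give_seven_ell(self, pair, rng):
        p, t = pair
        m = (rng.random(t.shape) < 0.2).astype(np.uint8)
        w = LossWeights(ssim_window=7)
        ell = lesion_attention_loss(p, t, m, w)
        assert total_loss(p, [p] * 6, t, m, w) == pytest.approx(7.0 * ell, rel=1e-9)

    def test_zero_side_weights_leave_final_term(self, pair, rng):
        p, t = pair
        m = (rng.random(t.shape) < 0.2).astype(np.uint8)
        w = LossWeights(w_side=(0.0,) * 6, w_final=2.0, ssim_window=7)
        assert total_loss(p, [t] * 6, t, m, w) == pytest.approx(
            2.0 * lesion_attention_loss(p, t, m, w), rel=1e-9)

    def test_wrong_side_count_rejected(self, pair):
        p, t = pair
        with pytest.raises(ContractError):
            total_loss(p, [p] * 5, t, np.zeros_like(t, dtype=np.uint8),
                       LossWeights(ssim_window=7))


class TestGradients:
    @pytest.mark.parametrize("loss_name", ["l1", "ssim", "lesion"])
    def test_analytic_gradient_matches_finite_differences(self, loss_name, rng):
        p0 = rng.normal(1.0, 0.5, size=(8, 8))
        t0 = rng.normal(1.0, 0.5, size=(8, 8))
        m = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        w = LossWeights(ssim_window=5, beta=3.0)
        pt = T.Tensor(p0.copy(), requires_grad=True)

        def f():
            if loss_name == "l1":
                return l1_loss(pt, T.Tensor(t0))
            if loss_name == "ssim":
                return ssim_loss(pt, T.Tensor(t0), weights=w, data_range=float(np.ptp(t0)))
            return lesion_attention_loss(pt, T.Tensor(t0), m, w, data_range=float(np.ptp(t0)))

        pt.grad = None
        out = f()
        out.backward()
        num = np.zeros_like(p0)
        eps = 1e-6
        for i in range(8):
            for j in range(8):
                old = pt.data[i, j]
                pt.data[i, j] = old + eps
                plus = f().item()
                pt.data[i, j] = old - eps
                minus = f().item()
                pt.data[i, j] = old
                num[i, j] = (plus - minus) / (2 * eps)
        scale = np.abs(num).max()
        np.testing.assert_allclose(pt.grad, num, rtol=0, atol=1e-4 * scale)


def test_noise_amplitude_monotonicity(rng):
    """More input noise means larger expected L1 and SSIM losses."""
    t = np.abs(rng.normal(1.0, 0.3, size=(24, 24)))
    noise = rng.normal(size=(24, 24))
    w = LossWeights(ssim_window=7)
    l1s, ssims = [], []
    for amp in (0.05, 0.15, 0.45, 1.2):
        p = t + amp * noise
        l1s.append(l1_loss(p, t))
        ssims.append(ssim_loss(p, t, weights=w, data_range=float(np.ptp(t))))
    assert l1s == sorted(l1s)
    assert ssims == sorted(ssims)
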