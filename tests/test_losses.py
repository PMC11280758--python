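"""Algebra of the CE / Dice / Focal losses and their learnable combination."""

import numpy as np
import pytest

from coatseg.losses import (
    LossConfig,
    LossWeights,
    ce_loss,
    combined_loss,
    dice_loss,
    focal_loss,
)
from coatseg.nn import Adam
from coatseg.nn.autodiff import Tensor


def logits_for(target, confidence=12.0):
    """Logits that place high probability on the true class."""
    t = np.asarray(target)
    lg = np.zeros((1, 2) + t.shape, np.float64)
    lg[0, 1][t == 1] = confidence
    lg[0, 0][t == 0] = confidence
    return Tensor(lg)


@pytest.fixture
def toy_target(rng):
    return (rng.random((1, 6, 6)) > 0.5).astype(np.int64)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self, toy_target):
        assert float(ce_loss(logits_for(toy_target[0], 50.0), toy_target).data) < 1e-8

    def test_uniform_prediction_is_ln2(self, toy_target):
        lg = Tensor(np.zeros((1, 2, 6, 6)))
        assert np.isclose(float(ce_loss(lg, toy_target).data), np.log(2.0))

    def test_matches_explicit_loop(self, rng, toy_target):
        lg = rng.normal(size=(1, 2, 6, 6))
        expected = 0.0
        for i in range(6):
            for j in range(6):
                z = lg[0, :, i, j]
                p = np.exp(z) / np.exp(z).sum()
                expected += -np.log(p[toy_target[0, i, j]])
        expected /= 36
        assert np.isclose(float(ce_loss(Tensor(lg), toy_target).data), expected)

    def test_rejects_non_binary_target(self):
        with pytest.raises(ValueError):
            ce_loss(Tensor(np.zeros((1, 2, 2, 2))), np.full((1, 2, 2), 3))


class TestDice:
    def test_perfect_overlap_smooth_limit(self, toy_target):
        p = toy_target.astype(np.float64)
        val = float(dice_loss(Tensor(p), toy_target,
                              LossConfig(dice_smooth=1e-9)).data)
        assert abs(val) < 1e-6

    def test_zero_overlap_is_one(self):
        target = np.zeros((1, 4, 4), np.int64)
        target[0, :2] = 1  # half coating
        p = 1.0 - target.astype(np.float64)
        val = float(dice_loss(Tensor(p), target,
                              LossConfig(dice_smooth=1e-9)).data)
        assert abs(val - 1.0) < 1e-6

    def test_half_probability_toy_matches_hand_value(self):
        # 4x4, p = 0.5 everywhere, 8 true pixels, smooth = 1:
        # dice = (2*4 + 1) / (8 + 8 + 1) = 9/17
        target = np.zeros((1, 4, 4), np.int64)
        target[0, :2] = 1
        p = np.full((1, 4, 4), 0.5)
        val = float(dice_loss(Tensor(p), target, LossConfig(dice_smooth=1.0)).data)
        assert np.isclose(val, 1.0 - 9.0 / 17.0)

    def test_rejects_out_of_range_probability(self, toy_target):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.full((1, 6, 6), 1.7)), toy_target)


class TestFocal:
    def test_gamma_zero_equals_ce(self, rng, toy_target):
        lg = Tensor(rng.normal(size=(1, 2, 6, 6)))
        f = float(focal_loss(lg, toy_target, LossConfig(focal_gamma=0.0)).data)
        c = float(ce_loss(lg, toy_target).data)
        assert abs(f - c) < 1e-7

    def test_perfect_prediction_is_zero_for_any_gamma(self, toy_target):
        for gamma in (0.5, 2.0, 5.0):
            val = float(
                focal_loss(logits_for(toy_target[0], 60.0), toy_target,
                           LossConfig(focal_gamma=gamma)).data
            )
            assert val < 1e-8

    def test_two_pixel_toy_matches_hand_expansion(self):
        # pixel A: true 1 with logits (0, 1); pixel B: true 0 with logits (2, 0)
        lg = np.array([[[[0.0, 2.0]], [[1.0, 0.0]]]])  # (1, 2, 1, 2)
        target = np.array([[[1, 0]]])
        pa = np.exp(1) / (np.exp(0) + np.exp(1))
        pb = np.exp(2) / (np.exp(2) + np.exp(0))
        expected = 0.5 * ((1 - pa) ** 2 * -np.log(pa)
                          + (1 - pb) ** 2 * -np.log(pb))
        val = float(focal_loss(Tensor(lg), target, LossConfig(focal_gamma=2.0)).data)
        assert np.isclose(val, expected)

    def test_negative_gamma_rejected(self, toy_target):
        with pytest.raises(ValueError):
            focal_loss(Tensor(np.zeros((1, 2, 6, 6))), toy_target,
                       LossConfig(focal_gamma=-1.0))


class TestCombined:
    @pytest.mark.parametrize("constraint", ["simplex", "none"])
    def test_initial_weights(self, constraint):
        np.testing.assert_allclose(
            LossWeights(constraint).values(), (0.3, 0.4, 0.3), atol=1e-12
        )

    def test_basis_weight_reduces_to_ce(self, rng, toy_target):
        lg = Tensor(rng.normal(size=(1, 2, 6, 6)))
        w = LossWeights(constraint="none")
        w.w1.data = np.array(1.0)
        w.w2.data = np.array(0.0)
        w.w3.data = np.array(0.0)
        assert np.isclose(
            float(combined_loss(lg, toy_target, w).data),
            float(ce_loss(lg, toy_target).data),
        )

    def test_recomposition_matches_components(self, rng, toy_target):
        lg = Tensor(rng.normal(size=(1, 2, 6, 6)))
        cfg = LossConfig()
        total, parts = combined_loss(lg, toy_target, LossWeights(), cfg,
                                     return_parts=True)
        expected = (0.3 * float(parts["ce"].data)
                    + 0.4 * float(parts["dice"].data)
                    + 0.3 * float(parts["focal"].data))
        assert np.isclose(float(total.data), expected)

    def test_perfect_prediction_total_vanishes(self, toy_target):
        cfg = LossConfig(dice_smooth=1e-9)
        total = combined_loss(logits_for(toy_target[0], 60.0), toy_target,
                              LossWeights(), cfg)
        assert float(total.data) < 1e-6

    def test_weight_gradient_equals_component_value(self, rng, toy_target):
        lg = Tensor(rng.normal(size=(1, 2, 6, 6)))
        w = LossWeights(constraint="none")
        cfg = LossConfig()
        total, parts = combined_loss(lg, toy_target, w, cfg, return_parts=True)
        total.backward()
        assert np.isclose(float(w.w1.grad), float(parts["ce"].data))
        assert np.isclose(float(w.w2.grad), float(parts["dice"].data))
        assert np.isclose(float(w.w3.grad), float(parts["focal"].data))

    def test_non_negative_when_weights_non_negative(self, rng):
        for trial in range(5):
            t = (rng.random((1, 5, 5)) > 0.5).astype(np.int64)
            lg = Tensor(rng.normal(size=(1, 2, 5, 5)))
            assert float(combined_loss(lg, t, LossWeights()).data) >= 0.0

    def test_weights_update_under_optimizer(self, rng, toy_target):
        w = LossWeights()
        opt = Adam(w.parameters(), lr=0.01)
        lg = Tensor(rng.normal(size=(1, 2, 6, 6)))
        for _ in range(3):
            opt.zero_grad()
            combined_loss(lg, toy_target, w).backward()
            opt.step()
        assert w.values() != LossWeights.INIT
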