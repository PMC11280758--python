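"""Subtraction feature pyramid: oracle equivalence and identities."""

import numpy as np
import pytest

from coatseg.nn import autodiff as ad
from coatseg.nn.autodiff import Tensor
from coatseg.sfp import SFP, SubtractionUnit, _align


@pytest.fixture
def sfp(rng):
    return SFP([8, 16, 32], reduced=16, rng=rng)


def skips_for(rng, channels=16, sizes=((16, 16), (8, 8), (4, 4))):
    return [
        Tensor(rng.normal(size=(1, channels, h, w)).astype(np.float32))
        for h, w in sizes
    ]


class TestSubtractionUnit:
    def test_symmetric_in_arguments(self, rng):
        su = SubtractionUnit(8, rng=rng)
        a = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(su(a, b).data, su(b, a).data)

    def test_equal_inputs_give_constant_channels(self, rng):
        """|x - x| = 0; conv+BN of an all-zero map is spatially constant."""
        su = SubtractionUnit(8, rng=rng)
        su.eval()  # use running stats so BN of zeros is well defined
        a = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        out = su(a, a).data
        for c in range(out.shape[1]):
            assert np.ptp(out[0, c]) < 1e-6

    def test_matches_naive_loop_oracle(self, rng):
        su = SubtractionUnit(4, rng=rng)
        a = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        b = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        diff = np.empty_like(a)
        for c in range(4):
            for i in range(8):
                for j in range(8):
                    diff[0, c, i, j] = abs(a[0, c, i, j] - b[0, c, i, j])
        expected = su.cbr(Tensor(diff)).data
        # fresh BN running stats so both routes see identical statistics
        got = su(Tensor(a), Tensor(b)).data
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        su = SubtractionUnit(4, rng=rng)
        with pytest.raises(ValueError):
            su(Tensor(np.zeros((1, 4, 4, 4))), Tensor(np.zeros((1, 4, 8, 8))))


class TestSfpForward:
    def test_alpha_zero_is_exact_identity(self, rng, sfp):
        skips = skips_for(rng)
        outs = sfp.sfp_forward(skips)
        for s, o in zip(skips, outs):
            np.testing.assert_array_equal(s.data, o.data)

    def test_output_shapes_match_inputs(self, rng, sfp):
        for p in sfp.level_weights:
            p.data = np.array(0.5, np.float32)
        outs = sfp.sfp_forward(skips_for(rng))
        assert [o.shape for o in outs] == [(1, 16, 16, 16), (1, 16, 8, 8),
                                           (1, 16, 4, 4)]

    def test_matches_straight_line_oracle(self, rng, sfp):
        """Independent transcription of the two-round difference pyramid."""
        for i, p in enumerate(sfp.level_weights):
            p.data = np.array(0.1 * (i + 1), np.float32)
        skips = skips_for(rng)
        alphas = [float(p.data) for p in sfp.level_weights]
        # eval mode: batch-norm statistics are frozen, so the two routes see
        # identical SU blocks
        sfp.eval()
        got = [o.data for o in sfp.sfp_forward(skips)]
        d01 = sfp.su_round1[0](skips[0], _align(skips[1], 16, 16))
        d12 = sfp.su_round1[1](skips[1], _align(skips[2], 8, 8))
        d012 = sfp.su_round2[0](d01, _align(d12, 16, 16))
        exp0 = skips[0].data - alphas[0] * (d01.data + d012.data)
        exp1 = skips[1].data - alphas[1] * (
            _align(d01, 8, 8).data + d12.data + _align(d012, 8, 8).data
        )
        exp2 = skips[2].data - alphas[2] * (
            _align(d12, 4, 4).data + _align(d012, 4, 4).data
        )
        for g, e in zip(got, (exp0, exp1, exp2)):
            np.testing.assert_allclose(g, e, rtol=1e-5, atol=1e-6)

    def test_add_mode_flips_sign_of_correction(self, rng):
        rng_state = np.random.default_rng(3)
        sub = SFP([8, 8, 8], reduced=8, mode="subtract", rng=np.random.default_rng(3))
        add = SFP([8, 8, 8], reduced=8, mode="add", rng=np.random.default_rng(3))
        for m in (sub, add):
            for p in m.level_weights:
                p.data = np.array(0.7, np.float32)
            m.eval()
        skips = skips_for(rng_state, channels=8)
        outs_sub = sub.sfp_forward(skips)
        outs_add = add.sfp_forward(skips)
        for s, o_sub, o_add in zip(skips, outs_sub, outs_add):
            corr_sub = s.data - o_sub.data
            corr_add = o_add.data - s.data
            np.testing.assert_allclose(corr_sub, corr_add, rtol=1e-5, atol=1e-6)

    def test_gradient_reaches_every_parameter(self, rng, sfp):
        for p in sfp.level_weights:
            p.data = np.array(0.3, np.float32)
        raw = [
            Tensor(rng.normal(size=(1, c, h, w)).astype(np.float32))
            for c, (h, w) in zip([8, 16, 32], [(16, 16), (8, 8), (4, 4)])
        ]
        outs = sfp(raw)
        loss = outs[0].sum() + outs[1].sum() + outs[2].sum()
        loss.backward()
        for name, p in sfp.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.any(p.grad != 0) or "beta" not in name, name

    def test_wrong_level_count_rejected(self, rng, sfp):
        with pytest.raises(ValueError):
            sfp.sfp_forward(skips_for(rng)[:2])
        with pytest.raises(ValueError):
            SFP([64], rng=rng)


class TestReduceChannels:
    def test_shape_contract(self, rng):
        sfp = SFP([256, 512, 1024], reduced=64, rng=rng)
        x = Tensor(rng.normal(size=(1, 256, 16, 16)).astype(np.float32))
        out = sfp.reduce_channels(x, 0)
        assert out.shape == (1, 64, 16, 16)
        assert (out.data >= 0).all()  # terminal ReLU

    def test_unknown_level_rejected(self, rng, sfp):
        with pytest.raises(IndexError):
            sfp.reduce_channels(Tensor(np.zeros((1, 8, 4, 4))), 7)
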