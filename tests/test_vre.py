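"""Visual regional enhancer: codebook math against a brute-force oracle."""

import numpy as np
import pytest

from coatseg.nn.autodiff import Tensor
from coatseg.vre import LVC, VRE, Codebook


def brute_force_weights(x, lvc):
    """Term-by-term transcription of the codebook gating computation.

    x: (N, C).  Every sum is an explicit Python loop over pixels and
    codewords; BN statistics are taken over all (pixel, codeword) entries
    per channel, exactly as the shared batch norm in the module does.
    """
    b = lvc.codebook.codewords.data.astype(np.float64)
    s = lvc.codebook.factors.data.astype(np.float64)
    n, c = x.shape
    k = b.shape[0]
    resid = np.zeros((n, k, c))
    for i in range(n):
        scores = np.array(
            [-s[kk] * np.sum((x[i] - b[kk]) ** 2) for kk in range(k)]
        )
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        for kk in range(k):
            resid[i, kk] = a[kk] * (x[i] - b[kk])
    flat = resid.reshape(n * k, c)
    mu = flat.mean(axis=0)
    var = flat.var(axis=0)
    xhat = (resid - mu) / np.sqrt(var + lvc.brm_bn.eps)
    bn = xhat * lvc.brm_bn.gamma.data + lvc.brm_bn.beta.data
    fused = np.maximum(bn, 0.0)
    per_codeword = fused.mean(axis=0)          # mean over the N pixels
    summed = per_codeword.sum(axis=0)          # sum over the K codewords
    z = summed @ lvc.linear.weight.data + lvc.linear.bias.data
    return 1.0 / (1.0 + np.exp(-z))


class TestLvcWeights:
    def test_matches_brute_force_oracle(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(4, 65))
            c = int(rng.integers(2, 17))
            k = int(rng.integers(1, 9))
            lvc = LVC(c, k, rng=rng)
            lvc.codebook.factors.data = rng.uniform(0.2, 2.0, k).astype(np.float32)
            lvc.brm_bn.gamma.data = rng.normal(1, 0.2, c).astype(np.float32)
            x = rng.normal(size=(n, c)).astype(np.float32)
            got = lvc.lvc_weights(Tensor(x)).data[0]
            want = brute_force_weights(x.astype(np.float64), lvc)
            np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-6)

    def test_weights_strictly_inside_unit_interval(self, rng):
        lvc = LVC(8, 4, rng=rng)
        w = lvc.lvc_weights(Tensor(rng.normal(size=(16, 8)).astype(np.float32)))
        assert np.all(w.data > 0.0) and np.all(w.data < 1.0)

    def test_assignments_sum_to_one_over_codewords(self, rng):
        # the softmax inside the gating: recompute assignments explicitly
        lvc = LVC(6, 5, rng=rng)
        x = rng.normal(size=(10, 6))
        b = lvc.codebook.codewords.data
        s = lvc.codebook.factors.data
        d = ((x[:, None, :] - b[None]) ** 2).sum(-1)
        a = np.exp(-s * d)
        a = a / a.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, rtol=1e-6)

    def test_dimension_mismatch_and_empty_codebook(self, rng):
        lvc = LVC(8, 4, rng=rng)
        with pytest.raises(ValueError):
            lvc.lvc_weights(Tensor(np.zeros((5, 9), np.float32)))
        with pytest.raises(ValueError):
            Codebook(0, 8)


class TestLvcForward:
    def test_channelwise_scaling_definition(self, rng):
        lvc = LVC(4, 3, rng=rng)
        f = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        out = lvc(Tensor(f)).data
        x = f.reshape(4, 25).T
        w = lvc.lvc_weights(Tensor(x[None])).data[0]
        for c in range(4):
            np.testing.assert_allclose(out[0, c], f[0, c] * w[c], rtol=2e-4,
                                       atol=1e-6)

    def test_zero_input_with_nonzero_codewords_gives_zero(self, rng):
        lvc = LVC(4, 3, rng=rng)
        out = lvc(Tensor(np.zeros((1, 4, 6, 6), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_never_exceeds_input_magnitude(self, rng):
        lvc = LVC(8, 4, rng=rng)
        f = rng.normal(size=(1, 8, 7, 7)).astype(np.float32)
        out = lvc(Tensor(f)).data
        assert np.all(np.abs(out) <= np.abs(f) + 1e-7)


class TestVre:
    def test_projection_restores_decoder_width(self, rng):
        vre = VRE(64, 512, k=4, rng=rng)
        f = Tensor(rng.normal(size=(1, 64, 28, 28)).astype(np.float32))
        assert vre(f).shape == (1, 512, 28, 28)

    @pytest.mark.parametrize("arrangement,n_lvcs",
                             [("series", 2), ("parallel", 3), ("single", 1)])
    def test_arrangements_share_io_contract(self, rng, arrangement, n_lvcs):
        vre = VRE(8, 16, k=3, arrangement=arrangement, rng=rng)
        assert len(vre.lvcs) == n_lvcs
        f = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        assert vre(f).shape == (1, 16, 6, 6)

    def test_unknown_arrangement_rejected(self, rng):
        with pytest.raises(ValueError):
            VRE(8, 16, arrangement="tangled", rng=rng)

    def test_eval_mode_is_deterministic(self, rng):
        vre = VRE(8, 16, k=3, rng=rng)
        vre.eval()
        f = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(vre(f).data, vre(f).data)

    def test_near_passthrough_with_saturated_gate(self, rng):
        """Large positive linear bias drives w -> 1, so the series enhancer
        reduces to its output projection."""
        vre = VRE(6, 6, k=3, rng=rng)
        for lvc in vre.lvcs:
            lvc.linear.bias.data = np.full(6, 30.0, np.float32)
        vre.eval()
        f = Tensor(rng.normal(size=(1, 6, 5, 5)).astype(np.float32))
        out = vre(f).data
        ref = vre.proj(f).data
        np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)

    def test_gradients_reach_codebook_factors_and_linear(self, rng):
        vre = VRE(8, 16, k=3, rng=rng)
        f = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        vre(f).sum().backward()
        for lvc in vre.lvcs:
            assert lvc.codebook.codewords.grad is not None
            assert np.any(lvc.codebook.codewords.grad != 0)
            assert lvc.codebook.factors.grad is not None
            assert lvc.linear.weight.grad is not None
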