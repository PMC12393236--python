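"""Segmentation building blocks: depthwise convolution, parameter accounting,
self-similarity mixing, decoder softmax, skip addition, hybrid loss, and an
end-to-end gradient check of the assembled toy network."""

import numpy as np
import pytest

from svfatlas.emmseg import (
    BlockParams,
    ToySegNet,
    decoder_softmax,
    dwconv,
    hybrid_loss,
    param_count,
    rvm_block,
    skip_add,
    train_toy,
    trilinear_upsample2,
)
from svfatlas.fields import InvalidInputError


class TestDWConv:
    def test_unit_point_kernel_is_identity(self, rng):
        X = rng.random((5, 5, 5, 2))
        K = np.ones((2, 1, 1, 1))
        assert np.allclose(dwconv(X, K), X)

    def test_channels_processed_independently(self, rng):
        X = rng.random((6, 6, 6, 2))
        K = rng.random((2, 3, 3, 3))
        base = dwconv(X, K)
        X2 = X.copy()
        X2[..., 1] += 1.0
        out = dwconv(X2, K)
        assert np.allclose(out[..., 0], base[..., 0])
        assert not np.allclose(out[..., 1], base[..., 1])

    def test_center_voxel_matches_hand_correlation_sum(self, rng):
        X = rng.random((3, 3, 3, 1))
        K = rng.random((1, 3, 3, 3))
        out = dwconv(X, K)
        hand = sum(X[u, v, w, 0] * K[0, u, v, w]
                   for u in range(3) for v in range(3) for w in range(3))
        assert out[1, 1, 1, 0] == pytest.approx(hand)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            dwconv(rng.random((4, 4, 4, 3)), rng.random((2, 3, 3, 3)))

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            dwconv(rng.random((4, 4, 4, 1)), rng.random((1, 2, 2, 2)))


class TestParamCount:
    def test_unit_case(self):
        assert param_count(1, 1, 1) == (2, 1)

    def test_matches_exhaustive_kernel_bank_enumeration(self):
        c_in, c_out, k = 16, 32, 3
        depthwise = np.zeros((c_in, k, k))          # one k x k kernel per channel
        pointwise = np.zeros((c_in, c_out))         # channel-mixing weights
        standard = np.zeros((c_in, c_out, k, k))    # full kernel bank
        p_sep, p_std = param_count(c_in, c_out, k)
        assert p_sep == depthwise.size + pointwise.size
        assert p_std == standard.size

    def test_cubic_variant_counts_k3_kernels(self):
        c_in, c_out, k = 4, 8, 3
        p_sep, p_std = param_count(c_in, c_out, k, cubic=True)
        assert p_sep == c_in * k ** 3 + c_in * c_out
        assert p_std == c_in * c_out * k ** 3

    @pytest.mark.parametrize("c_in,c_out,k", [(2, 2, 2), (8, 16, 3), (3, 5, 7)])
    def test_separable_strictly_cheaper(self, c_in, c_out, k):
        p_sep, p_std = param_count(c_in, c_out, k)
        assert p_sep < p_std


class TestRVMBlock:
    def test_single_position_softmax_is_one(self):
        F = np.array([[1.0, 2.0]])
        params = BlockParams(d=2)
        out, Fp, S = rvm_block(F, params, return_parts=True)
        assert S == pytest.approx(np.array([[1.0]]))
        assert np.allclose(out, 2 * Fp)

    def test_similarity_rows_sum_to_one(self, rng):
        F = rng.random((7, 4))
        params = BlockParams(d=4)
        _, _, S = rvm_block(F, params, return_parts=True)
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-9)

    def test_two_positions_hand_computed(self):
        F = np.array([[1.0, 0.0], [0.0, 1.0]])
        # identity-free projection: gamma=1, beta=0 layernorm still applies,
        # so compute the full expression by hand
        params = BlockParams(d=2, W1=np.zeros((2, 2)), b1=np.zeros(2))
        out, Fp, S = rvm_block(F, params, return_parts=True)
        z = F @ F.T / np.sqrt(2)
        expS = np.exp(z - z.max(axis=1, keepdims=True))
        expS /= expS.sum(axis=1, keepdims=True)
        assert np.allclose(S, expS, atol=1e-12)
        assert np.allclose(out, Fp + expS @ Fp, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            rvm_block(rng.random((5, 3)), BlockParams(d=4))


class TestDecoderSoftmax:
    def test_zero_logits_give_uniform_probabilities(self):
        P = decoder_softmax(np.zeros((4, 4, 4, 5)))
        assert np.allclose(P, 0.2, atol=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.random((3, 3, 3, 4))
        assert np.allclose(decoder_softmax(logits), decoder_softmax(logits + 7.3), atol=1e-12)

    def test_two_class_hand_values(self):
        logits = np.zeros((1, 1, 1, 2)); logits[..., 0] = 2.0
        P = decoder_softmax(logits)
        e2 = np.exp(2.0)
        assert P[0, 0, 0, 0] == pytest.approx(e2 / (e2 + 1))
        assert P[0, 0, 0, 1] == pytest.approx(1 / (e2 + 1))

    def test_voxel_sums_are_one(self, rng):
        P = decoder_softmax(rng.standard_normal((4, 4, 4, 3)))
        assert np.allclose(P.sum(axis=-1), 1.0, atol=1e-9)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            decoder_softmax(np.zeros((2, 2, 2, 1)))


class TestSkipAdd:
    def test_zero_skip_is_pure_upsampling(self, rng):
        low = rng.random((4, 4, 4, 2))
        out = skip_add(low, np.zeros((8, 8, 8, 2)))
        assert np.allclose(out, trilinear_upsample2(low))

    def test_matching_dims_is_elementwise_sum(self, rng):
        a = rng.random((6, 6, 6, 3)); b = rng.random((6, 6, 6, 3))
        assert np.allclose(skip_add(a, b), a + b)

    def test_upsampled_constant_stays_constant(self):
        low = np.full((4, 4, 4, 1), 2.5)
        up = trilinear_upsample2(low)
        assert np.allclose(up, 2.5, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            skip_add(rng.random((4, 4, 4, 2)), rng.random((8, 8, 8, 3)))


class TestHybridLoss:
    def test_exact_one_hot_prediction_scores_zero(self):
        Y = np.zeros((2, 2, 2, 3)); Y[..., 1] = 1
        assert hybrid_loss(Y, Y) == pytest.approx(0.0, abs=1e-5)

    def test_eps_zero_reduces_to_cross_entropy(self, rng):
        logits = rng.standard_normal((3, 3, 3, 4))
        from svfatlas.emmseg import decoder_softmax

        P = decoder_softmax(logits)
        labs = rng.integers(0, 4, (3, 3, 3))
        Y = np.eye(4)[labs]
        ce = -np.log(np.take_along_axis(P, labs[..., None], axis=-1)).mean()
        assert hybrid_loss(P, Y, eps=0.0) == pytest.approx(ce)

    def test_uniform_two_class_single_voxel_hand_value(self):
        P = np.full((1, 1, 1, 2), 0.5)
        Y = np.zeros((1, 1, 1, 2)); Y[..., 0] = 1
        # CE = ln 2; soft dice: class0 = 2*0.5/(0.5+1), class1 = 0/(0.5+0)
        dice0 = 2 * 0.5 / 1.5
        expected = np.log(2) + (1 - (dice0 + 0.0) / 2)
        assert hybrid_loss(P, Y) == pytest.approx(expected)

    def test_unnormalized_probabilities_rejected(self):
        P = np.full((2, 2, 2, 2), 0.4)
        Y = np.zeros((2, 2, 2, 2)); Y[..., 0] = 1
        with pytest.raises(InvalidInputError):
            hybrid_loss(P, Y)


class TestToyNetwork:
    def test_analytic_gradients_match_finite_differences(self):
        net = ToySegNet(channels=4, n_classes=3, seed=0)
        rng = np.random.default_rng(1)
        X = rng.random((8, 8, 8))
        Y = np.eye(3)[rng.integers(0, 3, (8, 8, 8))]
        _, grads = net.loss_and_grads(X, Y)
        eps = 1e-6
        for name in net.params:
            flat = net.params[name].ravel()
            for ix in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[ix]
                flat[ix] = orig + eps
                lp = hybrid_loss(net.forward(X), Y)
                flat[ix] = orig - eps
                lm = hybrid_loss(net.forward(X), Y)
                flat[ix] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[ix]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), name

    def test_param_count_equals_tensor_enumeration(self):
        net = ToySegNet(channels=8, n_classes=3)
        total = sum(p.size for p in net.params.values())
        assert net.num_params() == total
        # the two depthwise stages follow the separable accounting (k^3 kernels)
        p_sep_dw_only = param_count(8, 8, 3, cubic=True)[0]
        assert net.params["dw1"].size + net.params["pw2"].size == p_sep_dw_only

    def test_short_overfit_reduces_loss(self):
        from svfatlas.phantom import make_phantom, scaled_params

        subj, labels = make_phantom(28.0, scaled_params((16, 16, 16)), seed=2)
        lab = np.where(labels.labels == 0, 0, np.where(labels.labels == 3, 2, 1))
        Y = np.eye(3)[lab]
        net = ToySegNet(channels=8, n_classes=3, seed=0)
        trace = train_toy(net, subj.image.values, Y, steps=120)
        assert trace[-1] < 0.5 * trace[0]
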