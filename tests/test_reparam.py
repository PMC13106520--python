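"""The six equivalence transforms: worked examples and forward equivalence."""

import numpy as np
import pytest

from mfdseg.errors import (
    DimensionError,
    InvalidStatisticsError,
    UnsupportedCompositionError,
)
from mfdseg.reparam import (
    BNStats,
    ConvTensor,
    avg_pool2d,
    avgpool_as_conv,
    conv_forward,
    fuse_conv_bn,
    merge_branch_concat,
    merge_parallel_sum,
    merge_seq_1x1_kxk,
    merge_seq_kxk_1x1,
    pad_kernel_to_target,
)

from conftest import random_bn, random_conv


class TestConvBNFusion:
    def test_identity_bn_is_noop(self, rng, make_conv):
        conv = make_conv(rng, 3, 2, 3)
        bn = BNStats(mean=np.zeros(3), std=np.ones(3), gamma=np.ones(3), beta=np.zeros(3))
        fused = fuse_conv_bn(conv, bn)
        np.testing.assert_array_equal(fused.weights, conv.weights)
        np.testing.assert_array_equal(fused.bias, conv.bias)

    def test_pure_shift_statistics(self, rng):
        # gamma=1, sigma=1, mu=5, beta=2, b=0: weights unchanged, bias = 2 - 5 = -3
        conv = ConvTensor(weights=rng.normal(size=(2, 1, 3, 3)), bias=np.zeros(2),
                          padding=(1, 1))
        bn = BNStats(mean=np.full(2, 5.0), std=np.ones(2), gamma=np.ones(2),
                     beta=np.full(2, 2.0))
        fused = fuse_conv_bn(conv, bn)
        np.testing.assert_allclose(fused.weights, conv.weights)
        np.testing.assert_allclose(fused.bias, [-3.0, -3.0])
        # cross-check on a constant input against the staged forward
        x = np.full((1, 6, 6), 1.7)
        np.testing.assert_allclose(conv_forward(fused, x), bn.apply(conv_forward(conv, x)),
                                   atol=1e-10)

    def test_random_fusion_matches_staged_forward(self, rng, make_conv, make_bn):
        conv = make_conv(rng, 3, 2, 3)
        bn = make_bn(rng, 3)
        x = rng.normal(size=(2, 8, 8))
        ref = bn.apply(conv_forward(conv, x))
        got = conv_forward(fuse_conv_bn(conv, bn), x)
        assert np.abs(ref - got).max() <= 1e-9

    def test_channel_mismatch_raises(self, rng, make_conv, make_bn):
        with pytest.raises(DimensionError):
            fuse_conv_bn(random_conv(rng, 3, 2, 3), random_bn(rng, 4))

    def test_nonpositive_std_rejected(self):
        with pytest.raises(InvalidStatisticsError):
            BNStats(mean=np.zeros(2), std=np.array([1.0, 0.0]),
                    gamma=np.ones(2), beta=np.zeros(2))


class TestParallelSum:
    def test_zero_branch_is_identity(self, rng, make_conv):
        a = make_conv(rng, 3, 2, 3)
        zero = ConvTensor(weights=np.zeros_like(a.weights), bias=np.zeros(3),
                          stride=a.stride, padding=a.padding)
        merged = merge_parallel_sum([a, zero])
        np.testing.assert_array_equal(merged.weights, a.weights)
        np.testing.assert_array_equal(merged.bias, a.bias)

    def test_scalar_kernels_add(self):
        a = ConvTensor(weights=np.full((1, 1, 1, 1), 2.0), bias=np.array([1.0]))
        b = ConvTensor(weights=np.full((1, 1, 1, 1), 3.0), bias=np.array([2.0]))
        merged = merge_parallel_sum([a, b])
        # forward on scalar x: (2x+1)+(3x+2) = 5x+3
        assert merged.weights.item() == 5.0 and merged.bias.item() == 3.0

    def test_forward_equals_summed_forwards(self, rng, make_conv):
        a, b = (make_conv(rng, 4, 3, 3) for _ in range(2))
        x = rng.normal(size=(3, 7, 7))
        ref = conv_forward(a, x) + conv_forward(b, x)
        got = conv_forward(merge_parallel_sum([a, b]), x)
        assert np.abs(ref - got).max() <= 1e-9

    def test_commutative_associative(self, rng, make_conv):
        convs = [make_conv(rng, 3, 2, 3) for _ in range(3)]
        x = rng.normal(size=(2, 6, 6))
        ref = conv_forward(merge_parallel_sum(convs), x)
        perm = conv_forward(merge_parallel_sum(convs[::-1]), x)
        nested = conv_forward(
            merge_parallel_sum([merge_parallel_sum(convs[:2]), convs[2]]), x)
        np.testing.assert_allclose(ref, perm, atol=1e-9)
        np.testing.assert_allclose(ref, nested, atol=1e-9)

    def test_geometry_mismatch_and_empty(self, rng, make_conv):
        with pytest.raises(DimensionError):
            merge_parallel_sum([random_conv(rng, 3, 2, 3), random_conv(rng, 3, 2, 1)])
        with pytest.raises(ValueError):
            merge_parallel_sum([])


class TestSequentialMerges:
    def test_identity_pointwise_factor(self, rng, make_conv):
        second = make_conv(rng, 3, 4, 3)
        ident = ConvTensor(weights=np.eye(4).reshape(4, 4, 1, 1), bias=np.zeros(4))
        merged = merge_seq_1x1_kxk(ident, second)
        np.testing.assert_allclose(merged.weights, second.weights)
        np.testing.assert_allclose(merged.bias, second.bias)

    def test_single_channel_hand_example(self):
        # 1x1 factor [[2]], b1=3 into 3x3 all-ones, b2=1: F' = 2*ones, b' = 1+9*3 = 28
        first = ConvTensor(weights=np.full((1, 1, 1, 1), 2.0), bias=np.array([3.0]))
        second = ConvTensor(weights=np.ones((1, 1, 3, 3)), bias=np.array([1.0]))
        merged = merge_seq_1x1_kxk(first, second)
        np.testing.assert_allclose(merged.weights, 2.0 * np.ones((1, 1, 3, 3)))
        assert merged.bias.item() == pytest.approx(28.0)
        # staged forward agrees (no spatial padding, so borders are exact too)
        x = np.full((1, 5, 5), 0.3)
        staged = conv_forward(second, conv_forward(first, x))
        np.testing.assert_allclose(conv_forward(merged, x), staged, atol=1e-9)

    def test_staged_forward_reproduced(self, rng):
        first = ConvTensor(weights=rng.normal(size=(8, 4, 1, 1)), bias=rng.normal(size=8))
        second = ConvTensor(weights=rng.normal(size=(4, 8, 3, 3)), bias=rng.normal(size=4))
        merged = merge_seq_1x1_kxk(first, second)
        x = rng.normal(size=(4, 9, 9))
        staged = conv_forward(second, conv_forward(first, x))
        assert np.abs(conv_forward(merged, x) - staged).max() <= 1e-9

    def test_kxk_then_pointwise(self, rng):
        first = ConvTensor(weights=rng.normal(size=(5, 3, 3, 3)), bias=rng.normal(size=5),
                           padding=(1, 1))
        second = ConvTensor(weights=rng.normal(size=(2, 5, 1, 1)), bias=rng.normal(size=2))
        merged = merge_seq_kxk_1x1(first, second)
        x = rng.normal(size=(3, 8, 8))
        staged = conv_forward(second, conv_forward(first, x))
        assert np.abs(conv_forward(merged, x) - staged).max() <= 1e-9

    def test_kxk_then_pointwise_scalar_example(self):
        # all-ones 3x3, b1=1 then [[2]], b2=0: F' = 2*ones, b' = 2
        first = ConvTensor(weights=np.ones((1, 1, 3, 3)), bias=np.array([1.0]))
        second = ConvTensor(weights=np.full((1, 1, 1, 1), 2.0), bias=np.array([0.0]))
        merged = merge_seq_kxk_1x1(first, second)
        np.testing.assert_allclose(merged.weights, 2.0 * np.ones((1, 1, 3, 3)))
        assert merged.bias.item() == pytest.approx(2.0)

    def test_unsupported_compositions(self, rng):
        k3 = ConvTensor(weights=rng.normal(size=(2, 2, 3, 3)), bias=np.zeros(2))
        p1 = ConvTensor(weights=rng.normal(size=(2, 2, 1, 1)), bias=np.zeros(2),
                        padding=(1, 1))
        with pytest.raises(UnsupportedCompositionError):
            merge_seq_1x1_kxk(k3, k3)
        with pytest.raises(UnsupportedCompositionError):
            merge_seq_1x1_kxk(p1, k3)  # padded pointwise factor
        bad = ConvTensor(weights=rng.normal(size=(5, 3, 1, 1)), bias=np.zeros(5))
        with pytest.raises(DimensionError):
            merge_seq_1x1_kxk(bad, ConvTensor(weights=rng.normal(size=(2, 4, 3, 3)),
                                              bias=np.zeros(2)))


class TestBranchConcat:
    def test_single_branch_unchanged(self, rng, make_conv):
        a = make_conv(rng, 3, 2, 3)
        merged = merge_branch_concat([a])
        np.testing.assert_array_equal(merged.weights, a.weights)

    def test_rows_stack_in_branch_order(self, rng):
        a = ConvTensor(weights=rng.normal(size=(2, 3, 3, 3)), bias=rng.normal(size=2))
        b = ConvTensor(weights=rng.normal(size=(3, 3, 3, 3)), bias=rng.normal(size=3))
        merged = merge_branch_concat([a, b])
        assert merged.out_channels == 5
        np.testing.assert_array_equal(merged.weights[:2], a.weights)
        np.testing.assert_array_equal(merged.weights[2:], b.weights)
        x = rng.normal(size=(3, 6, 6))
        ref = np.concatenate([conv_forward(a, x), conv_forward(b, x)], axis=0)
        np.testing.assert_allclose(conv_forward(merged, x), ref, atol=1e-9)


class TestAvgPoolAsConv:
    def test_kernel_values_are_inverse_k_squared(self):
        conv = avgpool_as_conv(1, 3)
        np.testing.assert_allclose(conv.weights, np.full((1, 1, 3, 3), 1 / 9))

    def test_constant_input_preserved_in_interior(self):
        conv = avgpool_as_conv(2, 3, stride=1, padding=0)
        x = np.full((2, 6, 6), 3.25)
        np.testing.assert_allclose(conv_forward(conv, x), 3.25, atol=1e-12)

    def test_matches_direct_pooling_with_border(self, rng):
        conv = avgpool_as_conv(2, 3, stride=1, padding=1)
        x = rng.normal(size=(2, 6, 6))
        np.testing.assert_allclose(conv_forward(conv, x), avg_pool2d(x, 3, 1, 1),
                                   atol=1e-12)

    def test_channel_weights_sum_to_one_and_block_diagonal(self, rng):
        for c, k in [(1, 3), (3, 5), (4, 7)]:
            conv = avgpool_as_conv(c, k)
            sums = conv.weights.sum(axis=(1, 2, 3))
            np.testing.assert_allclose(sums, 1.0, atol=1e-12)
            off = conv.weights * (1 - np.eye(c).reshape(c, c, 1, 1))
            assert np.all(off == 0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            avgpool_as_conv(2, 4)


class TestKernelPadding:
    def test_same_size_is_identity(self, rng, make_conv):
        conv = make_conv(rng, 2, 2, 3)
        padded = pad_kernel_to_target(conv, 3)
        np.testing.assert_array_equal(padded.weights, conv.weights)

    def test_pointwise_centered_in_3x3(self):
        conv = ConvTensor(weights=np.full((1, 1, 1, 1), 0.7), bias=np.array([0.2]))
        padded = pad_kernel_to_target(conv, 3)
        expect = np.zeros((1, 1, 3, 3))
        expect[0, 0, 1, 1] = 0.7
        np.testing.assert_allclose(padded.weights, expect)
        assert padded.padding == (1, 1)

    def test_padded_forward_identical(self, rng):
        conv = ConvTensor(weights=rng.normal(size=(3, 2, 1, 1)), bias=rng.normal(size=3))
        padded = pad_kernel_to_target(conv, 3)
        x = rng.normal(size=(2, 7, 7))
        np.testing.assert_allclose(conv_forward(padded, x), conv_forward(conv, x),
                                   atol=1e-9)

    def test_parity_violation_rejected(self, rng, make_conv):
        with pytest.raises(ValueError):
            pad_kernel_to_target(random_conv(rng, 2, 2, 3), 4)
        with pytest.raises(ValueError):
            pad_kernel_to_target(random_conv(rng, 2, 2, 3), 1)


class TestComposability:
    """Random two-level branch trees stay forward-equivalent after fusion."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_branch_tree(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 4))
        d = int(rng.integers(1, 4))
        x = rng.normal(size=(c, 8, 8))
        branches, refs = [], []
        for _ in range(int(rng.integers(2, 4))):
            kind = rng.integers(0, 3)
            if kind == 0:  # conv+BN
                conv = random_conv(rng, d, c, 3)
                bn = random_bn(rng, d)
                branches.append(fuse_conv_bn(conv, bn))
                refs.append(bn.apply(conv_forward(conv, x)))
            elif kind == 1:  # 1x1 then kxk sequence
                mid = int(rng.integers(1, 5))
                f1 = ConvTensor(weights=rng.normal(size=(mid, c, 1, 1)),
                                bias=rng.normal(size=mid))
                f2 = ConvTensor(weights=rng.normal(size=(d, mid, 3, 3)),
                                bias=rng.normal(size=d), padding=(1, 1))
                branches.append(merge_seq_1x1_kxk(f1, f2))
                # staged semantics: the intermediate map's padding ring is the
                # first stage's zero-input response (its bias), not zero
                mid_map = conv_forward(f1, x)
                mid_p = np.pad(mid_map, ((0, 0), (1, 1), (1, 1)))
                for ring in (np.s_[:, :1, :], np.s_[:, -1:, :],
                             np.s_[:, :, :1], np.s_[:, :, -1:]):
                    mid_p[ring] = f1.bias.reshape(-1, 1, 1)
                f2_nopad = ConvTensor(weights=f2.weights, bias=f2.bias)
                refs.append(conv_forward(f2_nopad, mid_p))
            else:  # pooling then 1x1
                pool = avgpool_as_conv(c, 3, padding=1)
                f2 = ConvTensor(weights=rng.normal(size=(d, c, 1, 1)),
                                bias=rng.normal(size=d))
                branches.append(merge_seq_kxk_1x1(pool, f2))
                refs.append(conv_forward(f2, avg_pool2d(x, 3, 1, 1)))
        fused = merge_parallel_sum(branches)
        ref = sum(refs)
        assert np.abs(conv_forward(fused, x) - ref).max() <= 1e-9
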