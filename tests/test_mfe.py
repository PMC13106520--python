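"""The four-branch MFE block: forward semantics, lossless fusion, counts."""

import numpy as np
import pytest

from mfdseg.errors import DimensionError, ModeError
from mfdseg.mfe import (
    MFEConfig,
    deploy,
    init_mfe_state,
    mfe_forward_deploy,
    mfe_forward_train,
    mfe_fuse,
    mfe_param_counts,
    silu,
)
from mfdseg.reparam import avg_pool2d, conv_forward

from conftest import random_bn


def randomize_bn(state, rng):
    for name in ("main_bn", "pointwise_bn", "pool_bn", "seq1_bn", "seq2_bn"):
        setattr(state, name, random_bn(rng, getattr(state, name).channels))
    return state


class TestTrainingForward:
    def test_zero_parameters_give_zero_output(self, rng):
        cfg = MFEConfig(2, 3)
        state = init_mfe_state(cfg, rng)
        for conv_name in ("main", "pointwise", "pool_pw", "seq1", "seq2"):
            conv = getattr(state, conv_name)
            object.__setattr__(conv, "weights", np.zeros_like(conv.weights))
        out = mfe_forward_train(cfg, state, rng.normal(size=(2, 6, 6)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_main_branch_hand_value(self, rng):
        # all-ones 3x3 main kernel, identity BN, other branches zeroed,
        # constant input 1 on 5x5: interior response is SiLU(9)
        cfg = MFEConfig(1, 1)
        state = init_mfe_state(cfg, rng)
        object.__setattr__(state.main, "weights", np.ones((1, 1, 3, 3)))
        for name in ("pointwise", "pool_pw", "seq1", "seq2"):
            conv = getattr(state, name)
            object.__setattr__(conv, "weights", np.zeros_like(conv.weights))
        out = mfe_forward_train(cfg, state, np.ones((1, 5, 5)))
        np.testing.assert_allclose(out[0, 1:-1, 1:-1], silu(np.array(9.0)), atol=1e-12)

    def test_matches_branchwise_reference(self, rng):
        cfg = MFEConfig(3, 4, alpha=1.5)
        state = randomize_bn(init_mfe_state(cfg, rng), rng)
        x = rng.normal(size=(3, 7, 7))
        # independent branch-by-branch evaluation; compared on the interior,
        # where the sequential branch's border convention cannot matter
        pooled = avg_pool2d(x, 3, 1, 1)
        mid = state.seq1_bn.apply(conv_forward(state.seq1, x))
        ref = silu(
            state.main_bn.apply(conv_forward(state.main, x))
            + state.pointwise_bn.apply(conv_forward(state.pointwise, x))
            + state.pool_bn.apply(conv_forward(state.pool_pw, pooled))
            + state.seq2_bn.apply(conv_forward(state.seq2, mid))
        )
        out = mfe_forward_train(cfg, state, x)
        np.testing.assert_allclose(out[:, 1:-1, 1:-1], ref[:, 1:-1, 1:-1], atol=1e-9)

    def test_channel_mismatch(self, rng):
        cfg = MFEConfig(3, 4)
        state = init_mfe_state(cfg, rng)
        with pytest.raises(DimensionError):
            mfe_forward_train(cfg, state, rng.normal(size=(2, 5, 5)))


class TestFusion:
    def test_main_only_reduces_to_fused_main(self, rng):
        cfg = MFEConfig(2, 3)
        state = init_mfe_state(cfg, rng)
        for name in ("pointwise", "pool_pw", "seq1", "seq2"):
            conv = getattr(state, name)
            object.__setattr__(conv, "weights", np.zeros_like(conv.weights))
        fused = mfe_fuse(cfg, state)
        np.testing.assert_allclose(fused.weights, state.main.weights, atol=1e-12)

    @pytest.mark.parametrize("cin,cout,alpha", [(2, 3, 1.0), (4, 4, 0.5), (3, 5, 2.0)])
    def test_forward_equivalence(self, rng, cin, cout, alpha):
        cfg = MFEConfig(cin, cout, alpha=alpha)
        state = randomize_bn(init_mfe_state(cfg, rng), rng)
        fused = mfe_fuse(cfg, state)
        worst = 0.0
        for _ in range(20):
            x = rng.normal(size=(cin, 9, 9))
            ref = mfe_forward_train(cfg, state, x)
            got = silu(conv_forward(fused, x))
            worst = max(worst, np.abs(ref - got).max())
        assert worst <= 1e-9

    def test_fused_parameter_count_formula(self):
        for cin, cout, k in [(2, 3, 3), (8, 8, 3), (5, 7, 5)]:
            cfg = MFEConfig(cin, cout, k)
            fused_params = cout * (cin * k * k + 1)
            assert mfe_param_counts(cfg)[1] == fused_params

    def test_fusing_deployed_state_raises(self, rng):
        cfg = MFEConfig(2, 2)
        state = deploy(cfg, init_mfe_state(cfg, rng))
        with pytest.raises(ModeError):
            mfe_fuse(cfg, state)
        with pytest.raises(ModeError):
            mfe_forward_train(cfg, state, np.zeros((2, 5, 5)))

    def test_deployed_forward_matches_training(self, rng):
        cfg = MFEConfig(3, 3)
        state = randomize_bn(init_mfe_state(cfg, rng), rng)
        deployed = deploy(cfg, state)
        x = rng.normal(size=(3, 8, 8))
        ref = mfe_forward_train(cfg, state, x)
        got = mfe_forward_deploy(cfg, deployed, x)
        assert np.abs(ref - got).max() <= 1e-9


class TestParamCounts:
    def test_reference_value(self):
        cfg = MFEConfig(64, 64)
        assert mfe_param_counts(cfg)[1] == 36_928  # 64 * (64*9 + 1)

    def test_train_exceeds_deploy(self):
        for cin, cout, alpha in [(4, 4, 0.5), (16, 32, 1.0), (8, 8, 2.0)]:
            train, dep = mfe_param_counts(MFEConfig(cin, cout, alpha=alpha))
            assert train > dep

    def test_formula_matches_instantiated_state(self, rng):
        cfg = MFEConfig(5, 6, alpha=1.4)
        state = init_mfe_state(cfg, rng)
        n = 0
        for conv_name in ("main", "pointwise", "pool_pw", "seq1", "seq2"):
            n += getattr(state, conv_name).weights.size  # bias-free before BN
        for bn_name in ("main_bn", "pointwise_bn", "pool_bn", "seq1_bn", "seq2_bn"):
            n += 2 * getattr(state, bn_name).channels  # gamma and beta
        assert n == mfe_param_counts(cfg)[0]

    def test_shape_preservation(self, rng):
        cfg = MFEConfig(3, 7)
        state = init_mfe_state(cfg, rng)
        out = mfe_forward_train(cfg, state, rng.normal(size=(3, 11, 13)))
        assert out.shape == (7, 11, 13)
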