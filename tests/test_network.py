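"""Model assembly, profiling, ASFF fusion and whole-model re-parameterization."""

import numpy as np
import pytest

from mfdseg import nn
from mfdseg.errors import ConfigError, ModeError
from mfdseg.layers import ASFF3
from mfdseg.network import (
    Model,
    build_model,
    count_params,
    feature_strides,
    load_checkpoint,
    reparameterize_model,
    save_checkpoint,
)

TINY = None


def tiny_model():
    global TINY
    if TINY is None:
        TINY = build_model("tiny", np.random.default_rng(0))
    return TINY


class TestBuildAndShapes:
    def test_head_scale_shapes(self, rng):
        m = tiny_model()
        m.eval()
        with nn.no_grad():
            out = m.forward(rng.normal(size=(1, 3, 160, 160)).astype(np.float32))
        shapes = [s[0].shape[2] for s in out["scales"]]
        assert shapes == [20, 10, 5]
        assert out["protos"].shape[2:] == (40, 40)  # 1/4 input resolution

    def test_feature_pyramid_stride_law(self):
        assert feature_strides(tiny_model()) == [8, 16, 32]

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            Model({"stages": [[-1, 1, "Conv", [8, 3, 2]]]})  # no head
        with pytest.raises(ConfigError):
            Model({"stages": [[-1, 1, "Nope", []]]})

    def test_single_conv_flops_closed_form(self):
        # one 3x3 conv 1->1 on a 10x10 map with padding 1: 2*9*100 = 1800 FLOPs
        from mfdseg.nn import Conv2d, Tensor

        conv = Conv2d(1, 1, 3, 1, 1, bias=False, rng=np.random.default_rng(0))
        nn.PROFILE = []
        try:
            with nn.no_grad():
                conv(Tensor(np.zeros((1, 1, 10, 10), dtype=np.float32)))
            macs = sum(nn.PROFILE)
        finally:
            nn.PROFILE = None
        assert 2 * macs == 1800


class TestAblationAccounting:
    def test_variant_ordering(self):
        base = count_params(build_model("baseline", np.random.default_rng(0)))
        mfe = count_params(build_model("mfe_only", np.random.default_rng(0)))
        sd = count_params(build_model("sd_only", np.random.default_rng(0)))
        assert mfe > base and sd > base

    def test_reparam_shrinks_mfe_bearing_model(self):
        m = build_model("tiny", np.random.default_rng(1))
        before = m.num_params()
        d = reparameterize_model(m)
        assert d.num_params() < before
        with pytest.raises(ModeError):
            reparameterize_model(d)

    def test_reparam_of_mfe_free_model_keeps_count(self):
        cfg = {
            "nc": 1,
            "stages": [
                [-1, 1, "Conv", [8, 3, 2]],
                [-1, 1, "Conv", [16, 3, 2]],
                [-1, 1, "Conv", [16, 3, 2]],
                [-1, 1, "Conv", [24, 3, 2]],
                [-1, 1, "Conv", [32, 3, 2]],
                [[2, 3, 4], 1, "Segment", [1, 8, 16]],
            ],
        }
        m = Model(cfg, np.random.default_rng(0))
        assert reparameterize_model(m).num_params() == m.num_params()


class TestASFF:
    def test_weights_sum_to_one_everywhere(self, rng):
        asff = ASFF3([8, 16, 16], target=0, rng=np.random.default_rng(0))
        xs = [nn.Tensor(rng.normal(size=(1, c, s, s)).astype(np.float32))
              for c, s in [(8, 16), (16, 8), (16, 4)]]
        feats = []
        for i, x in enumerate(xs):
            f = asff.resize[i](x) if asff.resize[i] is not None else x
            h = f.shape[2]
            if h < 16:
                f = nn.upsample_nearest2(f, 16 // h)
            feats.append(f)
        logits = nn.concat([asff.wconv[i](f) for i, f in enumerate(feats)], 1)
        w = nn.softmax(asff.wmerge(logits), axis=1)
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-6)

    def test_output_equals_manual_weighted_sum(self, rng):
        asff = ASFF3([4, 4, 4], target=1, rng=np.random.default_rng(2))
        xs = [nn.Tensor(rng.normal(size=(2, 4, s, s)).astype(np.float32))
              for s in (8, 4, 2)]
        with nn.no_grad():
            out = asff(xs)
            # manual recomputation
            feats = []
            for i, x in enumerate(xs):
                h = x.shape[2]
                if h < 4:
                    x = nn.upsample_nearest2(x, 4 // h)
                elif h > 4:
                    x = nn.max_pool2d(x, h // 4, h // 4, 0)
                feats.append(x.data)
            logits = np.concatenate(
                [asff.wconv[i].forward(nn.Tensor(f)).data for i, f in enumerate(feats)], 1)
            wl = asff.wmerge.forward(nn.Tensor(logits)).data
            e = np.exp(wl - wl.max(axis=1, keepdims=True))
            w = e / e.sum(axis=1, keepdims=True)
            ref = sum(feats[i] * w[:, i:i + 1] for i in range(3))
        np.testing.assert_allclose(out.data, ref, atol=1e-5)

    def test_single_level_passthrough(self, rng):
        asff = ASFF3([4], target=0, rng=np.random.default_rng(0))
        x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        with nn.no_grad():
            assert asff([x]) is x


class TestCheckpoints:
    def test_roundtrip_preserves_outputs(self, rng, tmp_path):
        m = build_model("tiny", np.random.default_rng(3))
        m.eval()
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        with nn.no_grad():
            ref = m.forward(x)
        save_checkpoint(m, tmp_path / "ck.npz")
        m2 = load_checkpoint(tmp_path / "ck.npz")
        m2.eval()
        with nn.no_grad():
            got = m2.forward(x)
        np.testing.assert_allclose(ref["protos"].data, got["protos"].data, atol=1e-6)

    def test_deployed_flag_roundtrip(self, tmp_path, rng):
        d = reparameterize_model(build_model("tiny", np.random.default_rng(4)))
        save_checkpoint(d, tmp_path / "d.npz")
        d2 = load_checkpoint(tmp_path / "d.npz")
        assert d2.deployed
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        with nn.no_grad():
            np.testing.assert_allclose(
                d.forward(x)["protos"].data, d2.forward(x)["protos"].data, atol=1e-6)
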