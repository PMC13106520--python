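import numpy as np
import pytest

from mfdseg.reparam import BNStats, ConvTensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_conv(rng, d, c, k, stride=1, padding=None, bias=True):
    pad = k // 2 if padding is None else padding
    return ConvTensor(
        weights=rng.normal(size=(d, c, k, k)),
        bias=rng.normal(size=d) if bias else np.zeros(d),
        stride=stride,
        padding=(pad, pad),
    )


def random_bn(rng, c, eps=1e-3):
    return BNStats(
        mean=rng.normal(size=c),
        std=np.abs(rng.normal(size=c)) + 0.3,
        gamma=rng.normal(size=c) + 0.1,
        beta=rng.normal(size=c),
        eps=eps,
    )


@pytest.fixture
def make_conv():
    return random_conv


@pytest.fixture
def make_bn():
    return random_bn
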