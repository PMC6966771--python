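import numpy as np
import pytest

from mtenet.estimators import EmbeddingSpec, MultiChannelSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(rows, labels=None, sample_rate=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if labels is None:
        labels = [f"p{i}" for i in range(rows.shape[0])]
    return MultiChannelSeries(rows, labels, sample_rate)


def noisy_binary_chain(rng, n, hop_flip=0.02):
    """Binary Markov driver X with lag-1 copy hops X -> Y -> Z.

    Each hop flips the copied bit with a small probability so the direct
    parent is strictly more informative than the grandparent (exact copies
    would make them perfectly redundant and the chain unidentifiable).
    The driver has persistence (flip prob 0.25) so X's past also carries
    information about its deeper past, which exposes the spurious two-hop
    X -> Z dependence to bivariate TE while Y screens it exactly.
    """
    x = np.empty(n)
    x[0] = 1.0
    flips = rng.random(n) < 0.25
    for t in range(1, n):
        x[t] = 1.0 - x[t - 1] if flips[t] else x[t - 1]
    y = np.abs(np.roll(x, 1) - (rng.random(n) < hop_flip))
    y[0] = 0.0
    z = np.abs(np.roll(y, 1) - (rng.random(n) < hop_flip))
    z[0] = 0.0
    return make_series(np.vstack([x, y, z]), ["X", "Y", "Z"])


@pytest.fixture
def binary_copy_chain(rng):
    return noisy_binary_chain(rng, 20_000)


@pytest.fixture
def xor_series(rng):
    """Y(t) = X1(t-1) XOR X2(t-1) with iid fair-bit parents."""
    n = 20_000
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.integers(0, 2, n).astype(float)
    y = np.zeros(n)
    y[1:] = np.logical_xor(x1[:-1], x2[:-1]).astype(float)
    return make_series(np.vstack([x1, x2, y]), ["X1", "X2", "Y"])
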