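import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtenet.estimators import (
    DegenerateBinsError,
    EmbeddingSpec,
    MultiChannelSeries,
    SeriesTooShortError,
    conditional_transfer_entropy,
    discretize,
    embed,
    surrogate_test,
    transfer_entropy,
)

from conftest import make_series


# ---------------------------------------------------------------------------
# MultiChannelSeries / EmbeddingSpec invariants
# ---------------------------------------------------------------------------


class TestSeriesValidation:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            make_series([[1.0, np.nan, 2.0]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            MultiChannelSeries(np.zeros((2, 5)), ["a", "a"])

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            make_series([[1.0]])

    def test_label_lookup(self):
        s = make_series(np.zeros((2, 5)), ["a", "b"])
        assert s.index("b") == 1
        with pytest.raises(KeyError):
            s.index("c")


class TestEmbeddingSpec:
    @pytest.mark.parametrize("kwargs", [dict(k_target=0), dict(l_source=0), dict(delay=0)])
    def test_rejects_nonpositive(self, kwargs):
        with pytest.raises(ValueError):
            EmbeddingSpec(**kwargs)

    def test_span(self):
        assert EmbeddingSpec(2, 3, 2).span == 6


# ---------------------------------------------------------------------------
# discretize
# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_constant_equal_width_all_zero(self):
        s = make_series([[3.0] * 50])
        assert np.all(discretize(s, 4, "equal_width") == 0)

    def test_single_bin_always_zero(self, rng):
        s = make_series(rng.normal(size=(3, 100)))
        assert np.all(discretize(s, 1, "quantile") == 0)

    def test_quantile_near_uniform_occupancy(self, rng):
        # empirical quantile oracle: 4 quantile bins of 100k normals
        # each hold 0.25 +/- 0.01 of the mass
        s = make_series(rng.normal(size=(1, 100_000)))
        sym = discretize(s, 4, "quantile")[0]
        freqs = np.bincount(sym, minlength=4) / sym.size
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_constant_quantile_raises(self):
        s = make_series([[1.0] * 50], labels=["flat"])
        with pytest.raises(DegenerateBinsError, match="flat"):
            discretize(s, 4, "quantile")

    def test_unknown_scheme(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            discretize(make_series(rng.normal(size=(1, 20))), 2, "magic")

    @given(
        n_bins=st.integers(min_value=1, max_value=8),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=25, deadline=None)
    def test_symbols_below_n_bins(self, n_bins, seed):
        data = np.random.default_rng(seed).normal(size=(2, 64))
        s = MultiChannelSeries(data, ["a", "b"])
        for scheme in ("equal_width", "quantile"):
            sym = discretize(s, n_bins, scheme)
            assert sym.min() >= 0 and sym.max() < n_bins


# ---------------------------------------------------------------------------
# embed
# ---------------------------------------------------------------------------


class TestEmbed:
    def test_hand_enumerated_rows(self):
        s = make_series([[1, 2, 3, 4, 5]], labels=["x"])
        s2 = MultiChannelSeries(
            np.vstack([s.values[0], s.values[0] + 10]), ["x", "y"]
        )
        emb = embed(s2, EmbeddingSpec(1, 1, 1), {"x": "target", "y": "source"})
        assert emb.n_rows == 4
        assert emb.target_present[0] == 2
        assert emb.target_past[0, 0] == 1
        assert emb.source_past["y"][0, 0] == 11

    def test_row_count_k2(self, rng):
        T = 57
        s = make_series(rng.normal(size=(1, T)))
        emb = embed(s, EmbeddingSpec(k_target=2), {"p0": "target"})
        assert emb.n_rows == T - 2

    def test_delay3_first_present_index(self):
        s = make_series([list(range(10))])
        emb = embed(s, EmbeddingSpec(1, 1, 3), {"p0": "target"})
        # hand enumeration: present starts at sample 3 (0-based)
        assert emb.first_present_index == 3
        assert emb.target_present[0] == 3
        assert emb.target_past[0, 0] == 0

    def test_too_short_raises(self):
        s = make_series([[1.0, 2.0, 3.0]])
        with pytest.raises(SeriesTooShortError):
            embed(s, EmbeddingSpec(2, 2, 2), {"p0": "target"})

    def test_requires_exactly_one_target(self, rng):
        s = make_series(rng.normal(size=(2, 30)))
        with pytest.raises(ValueError, match="target"):
            embed(s, EmbeddingSpec(), {"p0": "source", "p1": "source"})


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------


class TestTransferEntropy:
    def test_independent_coins_near_zero(self, rng):
        x = rng.integers(0, 2, 20_000).astype(float)
        y = rng.integers(0, 2, 20_000).astype(float)
        s = make_series(np.vstack([x, y]), ["X", "Y"])
        te = transfer_entropy("X", "Y", s, estimator="plugin", n_bins=2,
                              scheme="equal_width")
        assert te.te <= 0.01

    def test_copy_channel_one_bit(self, rng):
        x = rng.integers(0, 2, 20_000).astype(float)
        y = np.roll(x, 1)
        y[0] = 0.0
        s = make_series(np.vstack([x, y]), ["X", "Y"])
        te = transfer_entropy("X", "Y", s, estimator="plugin", n_bins=2,
                              scheme="equal_width")
        assert te.te == pytest.approx(1.0, abs=0.02)
        # asymmetry: the copy carries nothing back
        rev = transfer_entropy("Y", "X", s, estimator="plugin", n_bins=2,
                               scheme="equal_width")
        assert rev.te <= 0.05

    def test_te_equals_h2_minus_h1(self, rng):
        s = make_series(rng.normal(size=(2, 3000)))
        te = transfer_entropy("p0", "p1", s)
        assert te.te == pytest.approx(te.h2 - te.h1)
        assert te.te_clamped >= 0.0

    def test_gaussian_matches_ols_oracle(self, rng):
        # independent OLS oracle for the Gaussian variance-ratio formula
        n = 4000
        x = np.zeros(n)
        y = np.zeros(n)
        e = rng.normal(size=(2, n))
        for t in range(1, n):
            x[t] = 0.6 * x[t - 1] + e[0, t]
            y[t] = 0.5 * y[t - 1] + 0.4 * x[t - 1] + e[1, t]
        s = make_series(np.vstack([x, y]), ["X", "Y"])
        te = transfer_entropy("X", "Y", s, estimator="gaussian")

        # oracle: explicit lstsq on the same embedding
        yp, ypast, xpast = y[1:], y[:-1], x[:-1]
        ones = np.ones_like(yp)
        for cols, name in ((np.column_stack([ones, ypast]), "r"),
                           (np.column_stack([ones, ypast, xpast]), "f")):
            beta, *_ = np.linalg.lstsq(cols, yp, rcond=None)
            resid = yp - cols @ beta
            if name == "r":
                var_r = resid @ resid / yp.size
            else:
                var_f = resid @ resid / yp.size
        oracle = 0.5 * math.log2(var_r / var_f)
        assert te.te == pytest.approx(oracle, abs=1e-6)

    def test_source_equals_target_rejected(self, rng):
        s = make_series(rng.normal(size=(2, 100)))
        with pytest.raises(ValueError):
            transfer_entropy("p0", "p0", s)

    def test_plugin_needs_two_bins(self, rng):
        s = make_series(rng.normal(size=(2, 100)))
        with pytest.raises(ValueError):
            transfer_entropy("p0", "p1", s, n_bins=1)

    def test_gaussian_too_short_raises(self, rng):
        s = make_series(rng.normal(size=(2, 20)))
        with pytest.raises(SeriesTooShortError):
            transfer_entropy("p0", "p1", s, estimator="gaussian")

    def test_plugin_dimensionality_warning(self, rng):
        s = make_series(rng.normal(size=(2, 40)))
        with pytest.warns(UserWarning, match="joint space"):
            transfer_entropy("p0", "p1", s, spec=EmbeddingSpec(3, 3, 1),
                             n_bins=4)


class TestConditionalTransferEntropy:
    def test_empty_condition_reduces_to_te(self, rng):
        s = make_series(rng.normal(size=(3, 2000)))
        a = transfer_entropy("p0", "p1", s)
        b = conditional_transfer_entropy("p0", "p1", (), s)
        assert a.te == b.te and a.h1 == b.h1 and a.h2 == b.h2

    def test_markov_chain_screening(self, binary_copy_chain):
        # Z = X two steps back; conditioning on the relay Y removes it.
        spec = EmbeddingSpec(k_target=1, l_source=2, delay=1)
        te = transfer_entropy("X", "Z", binary_copy_chain, spec,
                              n_bins=2, scheme="equal_width")
        cte = conditional_transfer_entropy("X", "Z", ("Y",), binary_copy_chain,
                                           spec, n_bins=2, scheme="equal_width")
        assert te.te >= 0.5
        assert cte.te <= 0.02

    def test_xor_synergy(self, xor_series):
        te = transfer_entropy("X1", "Y", xor_series, n_bins=2,
                              scheme="equal_width")
        cte = conditional_transfer_entropy("X1", "Y", ("X2",), xor_series,
                                           n_bins=2, scheme="equal_width")
        assert te.te <= 0.02
        assert cte.te == pytest.approx(1.0, abs=0.02)

    def test_condition_set_membership_checks(self, rng):
        s = make_series(rng.normal(size=(3, 200)))
        with pytest.raises(ValueError):
            conditional_transfer_entropy("p0", "p1", ("p0",), s)
        with pytest.raises(ValueError):
            conditional_transfer_entropy("p0", "p1", ("p1",), s)


# ---------------------------------------------------------------------------
# surrogate testing
# ---------------------------------------------------------------------------


def _te_stat(source, target, condition_set, series, spec):
    return conditional_transfer_entropy(
        source, target, condition_set, series, spec,
        estimator="plugin", n_bins=2, scheme="equal_width",
    ).te


class TestSurrogateTest:
    def test_p_floor_on_copy_channel(self, rng):
        x = rng.integers(0, 2, 4000).astype(float)
        y = np.roll(x, 1)
        y[0] = 0.0
        s = make_series(np.vstack([x, y]), ["X", "Y"])
        res = surrogate_test(_te_stat, "X", "Y", (), s, n_perm=99, rng_seed=1)
        assert res.p_value == pytest.approx(0.01)
        assert res.significant

    def test_determinism(self, rng):
        s = make_series(rng.normal(size=(2, 500)))
        a = surrogate_test(_te_stat, "p0", "p1", (), s, n_perm=29, rng_seed=42)
        b = surrogate_test(_te_stat, "p0", "p1", (), s, n_perm=29, rng_seed=42)
        assert a.observed == b.observed
        assert a.p_value == b.p_value
        assert np.array_equal(a.surrogate_values, b.surrogate_values)

    def test_nperm_minimum(self, rng):
        s = make_series(rng.normal(size=(2, 500)))
        with pytest.raises(ValueError, match="19"):
            surrogate_test(_te_stat, "p0", "p1", (), s, n_perm=10)

    def test_type_one_error_rate(self):
        # independence => rejections at the nominal alpha level
        reps, hits = 200, 0
        for r in range(reps):
            rg = np.random.default_rng(1000 + r)
            s = make_series(rg.integers(0, 2, size=(2, 300)).astype(float))
            res = surrogate_test(_te_stat, "p0", "p1", (), s,
                                 n_perm=19, alpha=0.05, rng_seed=r)
            hits += res.significant
        assert hits / reps == pytest.approx(0.05, abs=0.04)

    def test_p_value_invariant_enforced(self):
        from mtenet.estimators import SurrogateResult

        with pytest.raises(ValueError):
            SurrogateResult(1.0, np.zeros(9), p_value=0.0, n_perm=9,
                            alpha=0.05, significant=True)
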