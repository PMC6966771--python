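import math

import numpy as np
import pytest

from mtenet.estimators import EmbeddingSpec, conditional_transfer_entropy
from mtenet.inference import (
    DirectedNetwork,
    InferenceParams,
    fit_mvar,
    infer_bvte_network,
    infer_gca_network,
    infer_mte_network,
    infer_network,
    select_order_aic,
)

from conftest import make_series


def simulate_var(coeffs, n, seed, noise_sd=1.0):
    """Simulate a VAR(p) given coefficient matrices [p x nproc x nproc]
    with entry (i, j) the effect of i's lag on j."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, nproc, _ = coeffs.shape
    rng = np.random.default_rng(seed)
    x = np.zeros((nproc, n + 100))
    eps = rng.normal(0, noise_sd, size=(nproc, n + 100))
    for t in range(p, n + 100):
        acc = eps[:, t].copy()
        for k in range(p):
            acc += coeffs[k].T @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, 100:]


VAR1_CHAIN = np.array([[[0.5, 0.6, 0.0], [0.0, 0.5, 0.6], [0.0, 0.0, 0.5]]])


class TestFitMvar:
    def test_parameter_recovery(self):
        data = simulate_var(VAR1_CHAIN, 5000, seed=0)
        s = make_series(data, ["X", "Y", "Z"])
        model = fit_mvar(s, 1)
        # standard error of an AR coefficient ~ 1/sqrt(n); allow 3 SE
        assert np.allclose(model.coefficients[0], VAR1_CHAIN[0], atol=3 / np.sqrt(5000) * 3)
        assert model.order == 1

    def test_white_noise_small_coefficients(self, rng):
        s = make_series(rng.normal(size=(3, 5000)))
        model = fit_mvar(s, 1)
        assert np.max(np.abs(model.coefficients)) <= 0.1

    def test_residual_covariance_psd(self, rng):
        s = make_series(rng.normal(size=(2, 400)))
        model = fit_mvar(s, 2)
        eigvals = np.linalg.eigvalsh(model.residual_covariance)
        assert np.all(eigvals >= -1e-10)

    def test_infeasible_order_raises(self, rng):
        s = make_series(rng.normal(size=(2, 30)))
        with pytest.raises(Exception):
            fit_mvar(s, 30)

    def test_singular_regressors_raise(self):
        # duplicated channel -> rank-deficient lag matrix
        row = np.random.default_rng(0).normal(size=500)
        s = make_series(np.vstack([row, row]), ["a", "b"])
        with pytest.raises(np.linalg.LinAlgError):
            fit_mvar(s, 1)


class TestSelectOrderAic:
    def test_var2_order_recovery(self):
        coeffs = np.array([
            [[0.4, 0.3], [0.0, 0.4]],
            [[-0.3, 0.0], [0.25, -0.3]],
        ])
        hits = 0
        for seed in range(50):
            data = simulate_var(coeffs, 2000, seed=seed)
            s = make_series(data, ["a", "b"])
            hits += select_order_aic(s, 6) == 2
        assert hits >= 40  # >= 80% of runs

    def test_single_candidate(self, rng):
        s = make_series(rng.normal(size=(2, 300)))
        assert select_order_aic(s, 1) == 1

    def test_white_noise_selects_one(self, rng):
        s = make_series(rng.normal(size=(3, 2000)))
        assert select_order_aic(s, 4) == 1


class TestGcaNetwork:
    def test_linear_chain_recovery(self):
        data = simulate_var(VAR1_CHAIN, 2000, seed=3)
        s = make_series(data, ["X", "Y", "Z"])
        net = infer_gca_network(s, InferenceParams(alpha=0.01))
        truth = (VAR1_CHAIN[0] > 0).astype(int)
        np.fill_diagonal(truth, 0)
        assert np.array_equal(net.binary, truth)

    def test_weights_nonnegative_zero_diagonal(self, rng):
        s = make_series(rng.normal(size=(4, 600)))
        net = infer_gca_network(s, InferenceParams())
        assert np.all(net.weights >= 0)
        assert np.all(np.diag(net.weights) == 0)

    def test_gaussian_te_identity(self):
        # Gaussian TE equals the Granger log-variance-ratio / (2 ln 2)
        data = simulate_var(VAR1_CHAIN, 3000, seed=5)
        s = make_series(data, ["X", "Y", "Z"])
        params = InferenceParams(estimator="gaussian", max_order=1)
        net = infer_gca_network(s, params)
        for src, tgt, conds in (
            ("X", "Y", ("Z",)),
            ("Y", "Z", ("X",)),
            ("Z", "X", ("Y",)),
        ):
            te = conditional_transfer_entropy(
                src, tgt, conds, s, EmbeddingSpec(1, 1, 1), "gaussian"
            )
            gc = net.weights[s.index(src), s.index(tgt)]
            assert te.te == pytest.approx(gc / (2 * math.log(2)), abs=1e-6)

    def test_single_process_rejected(self, rng):
        s = make_series(rng.normal(size=(1, 300)))
        with pytest.raises(ValueError):
            infer_gca_network(s, InferenceParams())


class TestBvteNetwork:
    def test_chain_flags_spurious_cascade(self, binary_copy_chain):
        params = InferenceParams(
            embedding=EmbeddingSpec(1, 2, 1), n_bins=2, scheme="equal_width",
            n_perm=49, alpha=0.05, seed=11,
        )
        sub = make_series(
            binary_copy_chain.values[:, :2000], list(binary_copy_chain.labels)
        )
        net = infer_bvte_network(sub, params)
        i, j, k = (sub.index(c) for c in "XYZ")
        assert net.binary[i, j] == 1       # X -> Y
        assert net.binary[j, k] == 1       # Y -> Z
        assert net.binary[i, k] == 1       # spurious cascade edge

    def test_false_edge_rate_near_alpha(self):
        hits, pairs = 0, 0
        for seed in range(50):
            rg = np.random.default_rng(2000 + seed)
            s = make_series(rg.normal(size=(3, 400)))
            net = infer_bvte_network(
                s, InferenceParams(n_perm=39, alpha=0.05, seed=seed)
            )
            hits += int(net.binary.sum())
            pairs += 6
        assert hits / pairs == pytest.approx(0.05, abs=0.04)

    def test_single_process_rejected(self, rng):
        s = make_series(rng.normal(size=(1, 300)))
        with pytest.raises(ValueError):
            infer_bvte_network(s, InferenceParams())


class TestMteNetwork:
    def test_chain_prunes_cascade(self, binary_copy_chain):
        params = InferenceParams(
            embedding=EmbeddingSpec(1, 2, 1), n_bins=2, scheme="equal_width",
            n_perm=49, alpha=0.05, seed=13,
        )
        sub = make_series(
            binary_copy_chain.values[:, :4000], list(binary_copy_chain.labels)
        )
        net = infer_mte_network(sub, params)
        i, j, k = (sub.index(c) for c in "XYZ")
        assert net.binary[i, j] == 1
        assert net.binary[j, k] == 1
        assert net.binary[i, k] == 0       # pruned by conditioning on Y

    def test_xor_synergy_recovered(self, xor_series):
        params = InferenceParams(
            n_bins=2, scheme="equal_width", n_perm=49, alpha=0.05, seed=17
        )
        net = infer_mte_network(xor_series, params)
        i1, i2, iy = (xor_series.index(c) for c in ("X1", "X2", "Y"))
        assert net.binary[i1, iy] == 1 and net.binary[i2, iy] == 1
        assert net.weights[i1, iy] >= 0.9
        assert net.weights[i2, iy] >= 0.9

    def test_null_networks_mostly_empty(self):
        empty = 0
        for seed in range(50):
            rg = np.random.default_rng(3000 + seed)
            s = make_series(rg.normal(size=(5, 512)))
            net = infer_mte_network(
                s, InferenceParams(n_perm=199, alpha=0.01, seed=seed)
            )
            empty += int(net.binary.sum() == 0)
        assert empty >= 45  # >= 90% of 50 seeded runs

    def test_fewer_chain_false_positives_than_bvte(self):
        # on lag-1 copy chains MTE never exceeds BVTE's false-positive count
        from conftest import noisy_binary_chain

        worse = 0
        for seed in range(20):
            rg = np.random.default_rng(4000 + seed)
            s = noisy_binary_chain(rg, 1500)
            truth = np.zeros((3, 3), dtype=int)
            truth[0, 1] = truth[1, 2] = 1
            params = InferenceParams(
                embedding=EmbeddingSpec(1, 2, 1), n_bins=2,
                scheme="equal_width", n_perm=39, seed=seed,
            )
            fp_b = int((infer_bvte_network(s, params).binary & (1 - truth)).sum())
            fp_m = int((infer_mte_network(s, params).binary & (1 - truth)).sum())
            worse += int(fp_m > fp_b)
        assert worse == 0


class TestDeterminism:
    @pytest.mark.parametrize("method", ["gca", "bvte", "mte"])
    def test_same_seed_same_network(self, method):
        rg = np.random.default_rng(55)
        s = make_series(rg.normal(size=(3, 400)))
        params = InferenceParams(n_perm=29, seed=99)
        a = infer_network(s, method, params)
        b = infer_network(s, method, params)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.binary, b.binary)

    def test_unknown_method(self, rng):
        s = make_series(rng.normal(size=(2, 200)))
        with pytest.raises(ValueError, match="unknown method"):
            infer_network(s, "pdc", InferenceParams())


class TestDirectedNetworkInvariants:
    def test_nonzero_diagonal_rejected(self):
        w = np.ones((2, 2))
        with pytest.raises(ValueError, match="diagonal"):
            DirectedNetwork(w, np.zeros((2, 2)), ["a", "b"], "gca")

    def test_te_edge_needs_positive_weight(self):
        w = np.zeros((2, 2))
        b = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError, match="positive"):
            DirectedNetwork(w, b, ["a", "b"], "mte")
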