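"""Whole-network inference by three methods.

``infer_bvte_network``
    Bivariate transfer entropy between every ordered pair, thresholded by
    circular-shift surrogate tests.

``infer_mte_network``
    Multivariate transfer entropy: per target, greedily select the set of
    relevant sources (forward selection with a maximum-statistic surrogate
    gate, a one-shot pair-lookahead that rescues purely synergistic parent
    pairs, and iterative backward pruning), then weight each surviving
    source by its conditional TE given the remaining selected set.

``infer_gca_network``
    Conditional Granger causality from a full multivariate autoregressive
    (MVAR) model with AIC order selection; the edge statistic is the
    log-variance ratio of nested per-equation OLS fits with an F-test.

All three return a :class:`DirectedNetwork` with the convention
row = source, column = target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .estimators import (
    EmbeddingSpec,
    MultiChannelSeries,
    SeriesTooShortError,
    discretize,
)
from .util import seed_sequence

__all__ = [
    "DirectedNetwork",
    "MvarModel",
    "InferenceParams",
    "infer_bvte_network",
    "infer_mte_network",
    "fit_mvar",
    "select_order_aic",
    "infer_gca_network",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DirectedNetwork:
    """Square weighted + binary adjacency; entry (i, j) is the i -> j edge."""

    weights: np.ndarray
    binary: np.ndarray
    labels: List[str]
    method: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.binary = np.asarray(self.binary, dtype=int)
        n = len(self.labels)
        if self.weights.shape != (n, n) or self.binary.shape != (n, n):
            raise ValueError("weights and binary must be square n x n")
        if np.any(np.diag(self.weights) != 0) or np.any(np.diag(self.binary) != 0):
            raise ValueError("diagonals must be zero")
        if self.method in ("bvte", "mte") and np.any(
            (self.binary == 1) & (self.weights <= 0)
        ):
            raise ValueError("significant TE edges must have positive weight")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class MvarModel:
    """MVAR(p) fit: per-lag coefficient matrices and residual covariance.

    ``coefficients[k][i, j]`` is the effect of process i at lag k+1 on the
    present of process j.
    """

    order: int
    coefficients: np.ndarray            # (order, n, n)
    residual_covariance: np.ndarray     # (n, n)
    aic: float
    intercept: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        S = self.residual_covariance
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("residual covariance must be symmetric")


@dataclass
class InferenceParams:
    """Shared knobs for the three network methods."""

    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    estimator: str = "plugin"
    n_bins: int = 3
    scheme: str = "quantile"
    n_perm: int = 99
    alpha: float = 0.05
    max_order: int = 5
    order: Optional[int] = None         # fixed GCA order; None = AIC selection
    seed: int = 0
    max_sources: Optional[int] = None   # per-target cap; None = n_processes - 1
    pair_lookahead: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")


# ---------------------------------------------------------------------------
# fast TE engine (index-based, shared by BVTE and MTE)
# ---------------------------------------------------------------------------


class _TEEngine:
    """Conditional-TE evaluation on pre-discretized (or raw) data.

    Works on process indices and supports circular shifts of individual
    source rows, so surrogate loops avoid re-discretizing.  Shifting a row
    and then embedding is equivalent to embedding the shifted process,
    which is the surrogate scheme of :func:`mtenet.estimators.surrogate_test`.
    """

    def __init__(self, series: MultiChannelSeries, params: InferenceParams):
        self.spec = params.embedding
        self.estimator = params.estimator
        self.n_bins = params.n_bins
        self.T = series.n_samples
        if params.estimator == "plugin":
            self.data = discretize(series, params.n_bins, params.scheme).astype(
                np.int64
            )
        else:
            self.data = series.values
        self.span = self.spec.span
        if self.T <= self.span:
            raise SeriesTooShortError(
                f"{self.T} samples too short for embedding span {self.span}"
            )

    def _row(self, idx: int, shift: int) -> np.ndarray:
        row = self.data[idx]
        return np.roll(row, shift) if shift else row

    def _past(self, row: np.ndarray, n_lags: int) -> List[np.ndarray]:
        d, span, T = self.spec.delay, self.span, self.T
        return [row[span - (a + 1) * d : T - (a + 1) * d] for a in range(n_lags)]

    def cte(
        self,
        sources: Tuple[int, ...],
        target: int,
        conditions: Tuple[int, ...] = (),
        shifts: Optional[Dict[int, int]] = None,
    ) -> float:
        """CTE(sources -> target | conditions) in bits, clamped at zero."""
        shifts = shifts or {}
        k, l = self.spec.k_target, self.spec.l_source
        trow = self.data[target]
        pres = trow[self.span :]
        tpast = self._past(trow, k)
        cpast: List[np.ndarray] = []
        for c in conditions:
            cpast.extend(self._past(self._row(c, shifts.get(c, 0)), l))
        spast: List[np.ndarray] = []
        for s in sources:
            spast.extend(self._past(self._row(s, shifts.get(s, 0)), l))
        if self.estimator == "plugin":
            h2 = _H(self, [pres] + tpast + cpast) - _H(self, tpast + cpast)
            h1 = _H(self, [pres] + tpast + cpast + spast) - _H(
                self, tpast + cpast + spast
            )
        else:
            v_r = _resid_var(pres, tpast + cpast)
            v_f = _resid_var(pres, tpast + cpast + spast)
            tiny = 1e-300
            h2 = 0.5 * math.log2(max(v_r, tiny))
            h1 = 0.5 * math.log2(max(v_f, tiny))
        return max(h2 - h1, 0.0)


def _H(engine: _TEEngine, columns: List[np.ndarray]) -> float:
    if not columns:
        return 0.0
    m = columns[0].shape[0]
    b = engine.n_bins
    code = np.zeros(m, dtype=np.int64)
    mult = 1
    for col in columns:
        code += col * mult
        mult *= b
        if mult > (1 << 50):  # fall back for huge joint alphabets
            stacked = np.column_stack(columns)
            _, counts = np.unique(stacked, axis=0, return_counts=True)
            p = counts / m
            return float(-(p * np.log2(p)).sum())
    counts = np.bincount(code)
    counts = counts[counts > 0]
    p = counts / m
    return float(-(p * np.log2(p)).sum())


def _resid_var(y: np.ndarray, regressors: List[np.ndarray]) -> float:
    X = np.column_stack([np.ones_like(y)] + regressors)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r) / y.shape[0]


def _offsets(rng: np.random.Generator, T: int, size: int) -> np.ndarray:
    return rng.integers(T // 8, (7 * T) // 8 + 1, size=size)


def _single_test(
    engine: _TEEngine,
    source: int,
    target: int,
    conditions: Tuple[int, ...],
    n_perm: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """(observed CTE, surrogate p-value) for one directed statistic."""
    obs = engine.cte((source,), target, conditions)
    exceed = 0
    for _ in range(n_perm):
        off = int(_offsets(rng, engine.T, 1)[0])
        if engine.cte((source,), target, conditions, {source: off}) >= obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return obs, p


# ---------------------------------------------------------------------------
# BVTE
# ---------------------------------------------------------------------------


def infer_bvte_network(
    series: MultiChannelSeries, params: InferenceParams
) -> DirectedNetwork:
    """All-pairs bivariate TE network with per-pair surrogate thresholds."""
    n = series.n_processes
    if n < 2:
        raise ValueError("need at least two processes to form pairs")
    engine = _TEEngine(series, params)
    weights = np.zeros((n, n))
    binary = np.zeros((n, n), dtype=int)
    for j in range(n):  # target
        for i in range(n):  # source
            if i == j:
                continue
            rng = np.random.default_rng(
                seed_sequence(params.seed, "bvte", j, i)
            )
            try:
                obs, p = _single_test(engine, i, j, (), params.n_perm, rng)
            except Exception as exc:  # attach pair identity
                raise type(exc)(
                    f"pair {series.labels[i]} -> {series.labels[j]}: {exc}"
                ) from exc
            weights[i, j] = obs
            binary[i, j] = int(p <= params.alpha and obs > 0)
    return DirectedNetwork(weights, binary, list(series.labels), "bvte")


# ---------------------------------------------------------------------------
# MTE (greedy relevant-source selection)
# ---------------------------------------------------------------------------


def _max_stat_forward(
    engine: _TEEngine,
    candidates: List[int],
    target: int,
    selected: Tuple[int, ...],
    n_perm: int,
    rng: np.random.Generator,
) -> Tuple[int, float, float]:
    """Best single candidate and its maximum-statistic surrogate p-value.

    The observed statistic is the maximum CTE over candidates; each
    surrogate draw shifts the candidate being evaluated and again takes the
    maximum, controlling the per-step selection error at alpha.
    """
    obs = np.array([engine.cte((c,), target, selected) for c in candidates])
    best = int(np.argmax(obs))
    exceed = 0
    for _ in range(n_perm):
        m = -np.inf
        for c in candidates:
            off = int(_offsets(rng, engine.T, 1)[0])
            v = engine.cte((c,), target, selected, {c: off})
            if v > m:
                m = v
        if m >= obs[best]:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return candidates[best], float(obs[best]), p


def _pair_lookahead(
    engine: _TEEngine,
    candidates: List[int],
    target: int,
    selected: Tuple[int, ...],
    n_perm: int,
    rng: np.random.Generator,
) -> Tuple[Optional[Tuple[int, int]], float]:
    """Joint test of the best candidate pair (synergy rescue).

    A purely synergistic parent pair (e.g. an XOR target) carries no
    information individually, so single-candidate forward selection stalls;
    the joint CTE of the pair exposes it.  Maximum-statistic over pairs,
    shifting both members independently.
    """
    pairs = list(combinations(candidates, 2))
    if not pairs:
        return None, 1.0
    obs = np.array([engine.cte(p, target, selected) for p in pairs])
    best = int(np.argmax(obs))
    exceed = 0
    for _ in range(n_perm):
        m = -np.inf
        for p_ in pairs:
            offs = _offsets(rng, engine.T, 2)
            v = engine.cte(
                p_, target, selected, {p_[0]: int(offs[0]), p_[1]: int(offs[1])}
            )
            if v > m:
                m = v
        if m >= obs[best]:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pairs[best], p


def infer_mte_network(
    series: MultiChannelSeries, params: InferenceParams
) -> DirectedNetwork:
    """Greedy multivariate-TE network.

    Per target: (i) forward selection adds the candidate with maximal CTE
    given the already-selected sources when the maximum-statistic surrogate
    test passes at ``alpha``; (ii) if the first forward gate fails, a
    one-shot pair lookahead can admit a synergistic pair; (iii) backward
    pruning iteratively re-tests every selected source conditioned on the
    rest and drops the weakest non-significant one; (iv) surviving source X
    gets weight CTE(X -> target | selected \\ X).
    """
    n = series.n_processes
    if n < 2:
        raise ValueError("need at least two processes")
    engine = _TEEngine(series, params)
    max_sources = params.max_sources or (n - 1)
    weights = np.zeros((n, n))
    binary = np.zeros((n, n), dtype=int)
    for j in range(n):
        selected: List[int] = []
        candidates = [i for i in range(n) if i != j]
        lookahead_used = False
        step = 0
        while candidates and len(selected) < max_sources:
            rng = np.random.default_rng(
                seed_sequence(params.seed, "mte-fwd", j, step)
            )
            best, obs, p = _max_stat_forward(
                engine, candidates, j, tuple(selected), params.n_perm, rng
            )
            if p <= params.alpha and obs > 0:
                selected.append(best)
                candidates.remove(best)
            elif (
                params.pair_lookahead
                and not lookahead_used
                and len(candidates) >= 2
                and len(selected) + 2 <= max_sources
            ):
                lookahead_used = True
                rng2 = np.random.default_rng(
                    seed_sequence(params.seed, "mte-pair", j, step)
                )
                pair, p2 = _pair_lookahead(
                    engine, candidates, j, tuple(selected), params.n_perm, rng2
                )
                # second-stage test: spend half the per-target alpha budget
                if pair is not None and p2 <= params.alpha / 2:
                    for c in pair:
                        selected.append(c)
                        candidates.remove(c)
                else:
                    break
            else:
                break
            step += 1
        # backward pruning: drop weakest non-significant source, re-test
        round_ = 0
        while selected:
            worst = None
            worst_p = -1.0
            for s in selected:
                rest = tuple(x for x in selected if x != s)
                rng = np.random.default_rng(
                    seed_sequence(params.seed, "mte-bwd", j, round_, s)
                )
                _, p = _single_test(engine, s, j, rest, params.n_perm, rng)
                if p > params.alpha and p > worst_p:
                    worst, worst_p = s, p
            if worst is None:
                break
            selected.remove(worst)
            round_ += 1
        for s in selected:
            rest = tuple(x for x in selected if x != s)
            w = engine.cte((s,), j, rest)
            if w > 0:
                weights[s, j] = w
                binary[s, j] = 1
    return DirectedNetwork(weights, binary, list(series.labels), "mte")


# ---------------------------------------------------------------------------
# MVAR / GCA
# ---------------------------------------------------------------------------


def _lagged_design(values: np.ndarray, order: int, start: int) -> Tuple[np.ndarray, np.ndarray]:
    """Design matrix of lags 1..order for all processes, plus targets.

    Columns are ordered process-major: process 0 lags 1..p, process 1 lags
    1..p, ...  ``start`` is the first predicted sample index (>= order).
    """
    n, T = values.shape
    rows = T - start
    X = np.empty((rows, n * order))
    for i in range(n):
        for k in range(order):
            X[:, i * order + k] = values[i, start - (k + 1) : T - (k + 1)]
    Y = values[:, start:].T  # (rows, n)
    return X, Y


def fit_mvar(
    series: MultiChannelSeries, order: int, *, first_sample: Optional[int] = None
) -> MvarModel:
    """Fit an MVAR(order) model by per-equation ordinary least squares.

    AIC follows ``n_eff * log det(residual_covariance) + 2 * p * n**2``.
    """
    n, T = series.n_processes, series.n_samples
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= order * n + 1:
        raise SeriesTooShortError(
            f"{T} samples cannot support MVAR order {order} with {n} processes"
        )
    start = first_sample if first_sample is not None else order
    if start < order:
        raise ValueError("first_sample must be >= order")
    X, Y = _lagged_design(series.values, order, start)
    n_eff = X.shape[0]
    Xc = np.column_stack([np.ones(n_eff), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient regressor matrix; MVAR fit is singular"
        )
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)  # (1 + n*order, n)
    resid = Y - Xc @ beta
    sigma = (resid.T @ resid) / n_eff
    sigma = (sigma + sigma.T) / 2
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        logdet = -np.inf
    aic = n_eff * logdet + 2 * order * n * n
    coeffs = np.empty((order, n, n))
    for i in range(n):
        for k in range(order):
            coeffs[k, i, :] = beta[1 + i * order + k, :]
    return MvarModel(
        order=order,
        coefficients=coeffs,
        residual_covariance=sigma,
        aic=float(aic),
        intercept=beta[0],
    )


def select_order_aic(series: MultiChannelSeries, max_order: int) -> int:
    """Arg-min of AIC over orders 1..max_order (ties go to the smaller).

    All candidate orders are scored on the common sample starting at
    ``max_order`` so the AICs are comparable.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    best_order, best_aic = 1, np.inf
    for p in range(1, max_order + 1):
        model = fit_mvar(series, p, first_sample=max_order)
        if model.aic < best_aic - 1e-12:
            best_order, best_aic = p, model.aic
    return best_order


def infer_gca_network(
    series: MultiChannelSeries, params: InferenceParams
) -> DirectedNetwork:
    """Conditional Granger-causality network from nested MVAR fits.

    Edge weight (i, j) is ``log(var_restricted / var_full)`` (natural log)
    where the restricted model for equation j omits i's lags; the binary
    edge is an F-test on the nested models at ``params.alpha``.
    """
    n, T = series.n_processes, series.n_samples
    if n < 2:
        raise ValueError("need at least two processes")
    order = (
        params.order
        if params.order is not None
        else select_order_aic(series, params.max_order)
    )
    X, Y = _lagged_design(series.values, order, order)
    n_eff = X.shape[0]
    ones = np.ones((n_eff, 1))
    Xc = np.hstack([ones, X])
    k_full = Xc.shape[1]
    df_denom = n_eff - k_full
    if df_denom <= 0:
        raise SeriesTooShortError("too few samples for the F-test denominator")
    # Nested fits via normal equations: one Gram matrix serves the full
    # model and every restricted model (submatrix solves), so the n*(n-1)
    # restricted regressions cost almost nothing beyond the full fit.
    G = Xc.T @ Xc
    B = Xc.T @ Y                    # (k_full, n)
    yty = np.einsum("ij,ij->j", Y, Y)

    def _rss(keep: np.ndarray) -> np.ndarray:
        Gi = G[np.ix_(keep, keep)]
        Bi = B[keep, :]
        try:
            beta = np.linalg.solve(Gi, Bi)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(Gi, Bi, rcond=None)
        return np.maximum(yty - np.einsum("kj,kj->j", Bi, beta), 1e-300)

    rss_full = _rss(np.arange(k_full))
    weights = np.zeros((n, n))
    binary = np.zeros((n, n), dtype=int)
    for i in range(n):
        keep = np.array(
            [0]
            + [1 + c * order + k for c in range(n) if c != i for k in range(order)]
        )
        rss_r = _rss(keep)
        for j in range(n):
            if i == j:
                continue
            weights[i, j] = max(math.log(rss_r[j] / rss_full[j]), 0.0)
            F = ((rss_r[j] - rss_full[j]) / order) / (rss_full[j] / df_denom)
            pval = float(stats.f.sf(max(F, 0.0), order, df_denom))
            binary[i, j] = int(pval <= params.alpha)
    return DirectedNetwork(weights, binary, list(series.labels), "gca")


METHODS = {
    "bvte": infer_bvte_network,
    "mte": infer_mte_network,
    "gca": infer_gca_network,
}


def infer_network(
    series: MultiChannelSeries, method: str, params: InferenceParams
) -> DirectedNetwork:
    """Dispatch to one of the three inference methods by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(series, params)
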