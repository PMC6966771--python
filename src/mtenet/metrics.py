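"""Scoring of estimated networks against ground truth.

Confusion counts over ordered off-diagonal node pairs, sensitivity /
specificity percentages, the normalized adjacency linkage bias between the
noise-free and noisy weight estimates, the edges-recovered agreement count,
and mean +/- sd aggregation with paired t-tests across shared run indices.

Undefined ratios (zero denominators) are returned as ``nan`` markers and
excluded from aggregation rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "BenchmarkRecord",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "adjacency_bias",
    "edges_recovered",
    "aggregate_and_compare",
]

METRIC_COLUMNS = ("bias", "edges_recovered", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class BenchmarkRecord:
    """One (topology, coupling, snr, run, method) benchmark outcome."""

    topology: str
    coupling: str
    snr_db: float
    run: int
    method: str
    bias: float
    edges_recovered: int
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if np.isfinite(self.bias) and self.bias < 0:
            raise ValueError("bias must be >= 0")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")


def _as_binary(mat) -> np.ndarray:
    arr = np.asarray(getattr(mat, "binary", getattr(mat, "adjacency", mat)))
    return (arr != 0).astype(int)


def confusion_counts(estimated, truth) -> ConfusionCounts:
    """TP/TN/FP/FN over all ordered off-diagonal pairs.

    Accepts binary matrices or objects exposing ``binary`` / ``adjacency``.
    """
    est = _as_binary(estimated)
    tru = _as_binary(truth)
    if est.shape != tru.shape or est.shape[0] != est.shape[1]:
        raise ValueError(
            f"shape mismatch: estimated {est.shape} vs truth {tru.shape}"
        )
    est_labels = getattr(estimated, "labels", None)
    tru_labels = getattr(truth, "labels", None)
    if est_labels is not None and tru_labels is not None and list(est_labels) != list(
        tru_labels
    ):
        raise ValueError("node labels differ between estimate and truth")
    off = ~np.eye(est.shape[0], dtype=bool)
    e, t = est[off], tru[off]
    tp = int(np.sum((e == 1) & (t == 1)))
    tn = int(np.sum((e == 0) & (t == 0)))
    fp = int(np.sum((e == 1) & (t == 0)))
    fn = int(np.sum((e == 0) & (t == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(counts: ConfusionCounts) -> float:
    """100 * TP / (TP + FN); nan when no true edges exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return float("nan")
    return 100.0 * counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """100 * TN / (TN + FP); nan when no true non-edges exist."""
    denom = counts.tn + counts.fp
    if denom == 0:
        return float("nan")
    return 100.0 * counts.tn / denom


def adjacency_bias(y_c: np.ndarray, y_b: np.ndarray) -> float:
    """Frobenius-norm attenuation of the noisy estimate.

    ``||y_c - y_b|| / ||y_c||`` where ``y_c`` is the noise-free weight
    matrix and ``y_b`` its noisy counterpart; nan when ``||y_c|| = 0``.
    """
    y_c = np.asarray(y_c, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if y_c.shape != y_b.shape:
        raise ValueError("matrices must share a shape")
    denom = float(np.linalg.norm(y_c))
    if denom == 0.0:
        return float("nan")
    return float(np.linalg.norm(y_c - y_b)) / denom


def edges_recovered(estimated, truth) -> int:
    """Ordered off-diagonal pairs whose presence/absence matches truth."""
    c = confusion_counts(estimated, truth)
    return c.tp + c.tn


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        # degenerate pairing: identical vectors are non-significant (p = 1)
        return 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def aggregate_and_compare(
    records: Sequence[BenchmarkRecord], alpha: float = 0.05
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries shaped like a per-cell "mean +/- sd" table plus tests.

    Returns ``(summary, comparisons)``: the summary has one row per
    (topology, coupling, snr_db, method) with mean and sample sd of every
    metric; comparisons hold two-sided paired t-tests across shared run
    indices for every method pair and metric.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame([r.__dict__ for r in records])
    keys = ["topology", "coupling", "snr_db", "method"]
    summary = (
        df.groupby(keys)[list(METRIC_COLUMNS)]
        .agg(["mean", lambda s: s.std(ddof=1)])
        .reset_index()
    )
    summary.columns = keys + [
        f"{m}_{stat}" for m in METRIC_COLUMNS for stat in ("mean", "sd")
    ]
    rows = []
    for (topo, coup, snr), cell in df.groupby(["topology", "coupling", "snr_db"]):
        methods = sorted(cell["method"].unique())
        for ai in range(len(methods)):
            for bi in range(ai + 1, len(methods)):
                ma, mb = methods[ai], methods[bi]
                da = cell[cell["method"] == ma].set_index("run")
                db = cell[cell["method"] == mb].set_index("run")
                common = da.index.intersection(db.index)
                if len(common) == 0:
                    raise ValueError(
                        f"methods {ma} and {mb} share no run indices"
                    )
                for metric in METRIC_COLUMNS:
                    a = da.loc[common, metric].to_numpy(dtype=float)
                    b = db.loc[common, metric].to_numpy(dtype=float)
                    ok = np.isfinite(a) & np.isfinite(b)
                    if ok.sum() < 2:
                        p = float("nan")
                    else:
                        p = _paired_p(a[ok], b[ok])
                    rows.append(
                        {
                            "topology": topo,
                            "coupling": coup,
                            "snr_db": snr,
                            "metric": metric,
                            "method_a": ma,
                            "method_b": mb,
                            "mean_diff": float(np.nanmean(a - b)),
                            "p_value": p,
                            "significant": bool(np.isfinite(p) and p <= alpha),
                        }
                    )
    return summary, pd.DataFrame(rows)
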