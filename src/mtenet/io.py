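"""Text round-trips for series, networks, events and benchmark tables.

Series files: optional ``#``-prefixed metadata lines, then a header line of
tab-separated process labels, then one row of samples per process (row i
belongs to label i).  Networks: commented header (method, alpha, seed,
orientation row=source) followed by a labeled tab matrix.  A compressed
binary container (``.npz``) is also supported for series.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .estimators import MultiChannelSeries
from .inference import DirectedNetwork

__all__ = [
    "ParseError",
    "read_series",
    "write_series",
    "read_network",
    "write_network",
    "write_edge_list",
    "read_events",
    "write_events",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def write_series(series: MultiChannelSeries, path) -> Path:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            values=series.values,
            labels=np.array(series.labels),
            sample_rate=np.array(
                -1.0 if series.sample_rate is None else series.sample_rate
            ),
        )
        return path
    with open(path, "w") as fh:
        if series.sample_rate is not None:
            fh.write(f"# sample_rate={series.sample_rate:g}\n")
        fh.write("\t".join(series.labels) + "\n")
        for row in series.values:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    return path


def read_series(path) -> MultiChannelSeries:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            sr = float(z["sample_rate"])
            return MultiChannelSeries(
                z["values"],
                [str(x) for x in z["labels"]],
                None if sr < 0 else sr,
            )
    sample_rate: Optional[float] = None
    labels: Optional[List[str]] = None
    rows: List[np.ndarray] = []
    width: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "sample_rate=" in line:
                    try:
                        sample_rate = float(line.split("sample_rate=")[1])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: bad sample_rate"
                        ) from None
                continue
            if labels is None:
                labels = line.split("\t")
                continue
            try:
                row = np.array([float(v) for v in line.split("\t")])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value in data row"
                ) from None
            if width is None:
                width = row.size
            elif row.size != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({row.size} values, "
                    f"expected {width})"
                )
            rows.append(row)
    if labels is None or not rows:
        raise ParseError(f"{path}: no header or data rows found")
    if len(rows) != len(labels):
        raise ParseError(
            f"{path}: {len(rows)} data rows for {len(labels)} labels"
        )
    return MultiChannelSeries(np.vstack(rows), labels, sample_rate)


def write_network(
    network: DirectedNetwork,
    path,
    alpha: Optional[float] = None,
    seed: Optional[int] = None,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# method={network.method}\n")
        if alpha is not None:
            fh.write(f"# alpha={alpha:g}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# orientation=row=source\n")
        fh.write("label\t" + "\t".join(network.labels) + "\n")
        for lab, wrow, brow in zip(network.labels, network.weights, network.binary):
            cells = [f"{w:.12g}|{b}" for w, b in zip(wrow, brow)]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
    return path


def read_network(path) -> DirectedNetwork:
    path = Path(path)
    method = "unknown"
    labels: Optional[List[str]] = None
    weights: List[List[float]] = []
    binary: List[List[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("# method="):
                    method = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if labels is None:
                labels = parts[1:]
                continue
            try:
                w_row, b_row = [], []
                for cell in parts[1:]:
                    w, b = cell.split("|")
                    w_row.append(float(w))
                    b_row.append(int(b))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed cell") from None
            if labels and len(w_row) != len(labels):
                raise ParseError(f"{path}:{lineno}: ragged row")
            weights.append(w_row)
            binary.append(b_row)
    if labels is None or len(weights) != len(labels):
        raise ParseError(f"{path}: incomplete network matrix")
    return DirectedNetwork(np.array(weights), np.array(binary), labels, method)


def write_edge_list(network: DirectedNetwork, path) -> Path:
    """Tab-separated (source, target, weight, significant) rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsignificant\n")
        n = network.n_nodes
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                fh.write(
                    f"{network.labels[i]}\t{network.labels[j]}\t"
                    f"{network.weights[i, j]:.12g}\t{int(network.binary[i, j])}\n"
                )
    return path


def write_events(events: Sequence[Tuple[float, str]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_ms\tlabel\n")
        for t, lab in events:
            fh.write(f"{t:.6g}\t{lab}\n")
    return path


def read_events(path) -> List[Tuple[float, str]]:
    path = Path(path)
    events: List[Tuple[float, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("time_ms"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                events.append((float(parts[0]), parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad event time") from None
    return events
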