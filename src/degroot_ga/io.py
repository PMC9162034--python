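"""CSV readers and writers for adjacency matrices, weight matrices, and panels.

All files are plain CSV.  Square matrices may carry one optional header row of
agent labels; opinion panels are T rows by N agent columns of integers on the
ordinal scale.  Adjacency files produced by social-network tools often omit
self-links; these are added automatically with a logged warning, since the
model always includes them.
"""

from __future__ import annotations

import csv
import logging
from typing import Optional

import numpy as np

from .network import AdjacencyMatrix, WeightMatrix
from .scale import relabel_ordinal

__all__ = [
    "read_adjacency",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_opinion_panel",
    "write_opinion_panel",
]

logger = logging.getLogger(__name__)


def _read_csv_matrix(path) -> tuple[np.ndarray, Optional[tuple[str, ...]]]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    labels: Optional[tuple[str, ...]] = None
    try:
        [float(c) for c in rows[0]]
    except ValueError:
        labels = tuple(c.strip() for c in rows[0])
        rows = rows[1:]
    data = np.array([[float(c) for c in row] for row in rows])
    return data, labels


def read_adjacency(path, add_self_links: bool = True) -> AdjacencyMatrix:
    """Read a square 0/1 CSV (optional label header) as an adjacency matrix."""
    data, labels = _read_csv_matrix(path)
    a = data.astype(np.int64)
    if add_self_links and np.any(np.diag(a) == 0):
        logger.warning("%s: adding missing self-links (a_ii = 1)", path)
        np.fill_diagonal(a, 1)
    return AdjacencyMatrix(a, labels)


def read_weight_matrix(path, adjacency: Optional[AdjacencyMatrix] = None) -> WeightMatrix:
    """Read a square CSV of weights; structural zeros follow ``adjacency`` if given."""
    data, _ = _read_csv_matrix(path)
    if adjacency is not None:
        return WeightMatrix.from_adjacency(data, adjacency)
    return WeightMatrix(data)


def write_weight_matrix(path, W: WeightMatrix, labels: Optional[tuple[str, ...]] = None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if labels is not None:
            writer.writerow(labels)
        writer.writerows([f"{v:.12g}" for v in row] for row in W.entries)


def read_opinion_panel(path, relabel: bool = True) -> np.ndarray:
    """Read a T x N integer panel CSV; shifts arbitrary integer labels to 1..n."""
    data, _ = _read_csv_matrix(path)
    if np.any(data != np.round(data)):
        raise ValueError(f"{path}: opinion panel must contain integers")
    panel = data.astype(np.int64)
    return relabel_ordinal(panel) if relabel else panel


def write_opinion_panel(path, panel: np.ndarray) -> None:
    np.savetxt(path, np.asarray(panel, dtype=np.int64), fmt="%d", delimiter=",")
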