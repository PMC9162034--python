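"""Network and weight-matrix types and the deterministic DeGroot update.

The DeGroot model updates the opinion vector X(t) on a social network as
X(t+1) = W X(t), where W is a row-stochastic influence matrix: w_ij is the
proportion of agent i's updating influence attributed to agent j.  The binary
adjacency matrix A (symmetric, with self-links a_ii = 1 so agents weigh their
own current opinion) constrains W through structural zeros: w_ij = 0 wherever
a_ij = 0.

Agents are indexed 0-based internally; CSV files may carry a header row of
agent labels (see :mod:`degroot_ga.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "ROW_SUM_TOL",
    "ConstraintError",
    "DimensionError",
    "AdjacencyMatrix",
    "WeightMatrix",
    "Violation",
    "validate_weight_matrix",
    "degroot_step",
    "degroot_trajectory",
]

#: Tolerance on |row sum - 1| when validating weight matrices.  Generators
#: renormalise exactly before output; the tolerance only absorbs float drift.
ROW_SUM_TOL = 1e-9


class ConstraintError(ValueError):
    """A matrix violates a model constraint (row sums, range, structure)."""


class DimensionError(ValueError):
    """Shapes of the supplied objects do not match."""


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric binary N x N adjacency structure with self-links on the diagonal."""

    entries: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.entries)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError(f"adjacency matrix must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ConstraintError("adjacency entries must be exactly 0 or 1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ConstraintError("adjacency matrix must be symmetric")
        if not np.all(np.diag(a) == 1):
            raise ConstraintError("adjacency matrix must have self-links (a_ii = 1)")
        if self.labels is not None and len(self.labels) != a.shape[0]:
            raise DimensionError("number of labels must match number of agents")
        object.__setattr__(self, "entries", a)
        self.entries.setflags(write=False)

    @property
    def n_agents(self) -> int:
        return self.entries.shape[0]


class Violation(NamedTuple):
    """One violated weight-matrix invariant, located by row (and column)."""

    constraint: str  # "row_sum" | "range" | "structural_zero" | "fixed_value"
    row: int
    col: Optional[int]
    detail: str


@dataclass
class WeightMatrix:
    """Row-stochastic influence matrix; the genetic algorithm's chromosome.

    ``fixed_mask`` marks entries pinned either by structure (a_ij = 0 forces
    w_ij = 0) or by the user; ``fixed_values`` holds the pinned values (zero at
    unpinned positions).  Rows are the genes of the chromosome.
    """

    entries: np.ndarray
    fixed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fixed_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.array(self.entries, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionError(f"weight matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros((n, n), dtype=bool)
        else:
            self.fixed_mask = np.array(self.fixed_mask, dtype=bool)
        if self.fixed_values is None:
            self.fixed_values = np.zeros((n, n), dtype=float)
        else:
            self.fixed_values = np.array(self.fixed_values, dtype=float)
        if self.fixed_mask.shape != w.shape or self.fixed_values.shape != w.shape:
            raise DimensionError("fixed_mask/fixed_values must match the entry shape")
        self.entries = w

    @property
    def n_agents(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_adjacency(
        cls,
        entries: np.ndarray,
        adjacency: AdjacencyMatrix,
        fixed: Optional[dict[tuple[int, int], float]] = None,
    ) -> "WeightMatrix":
        """Build a WeightMatrix whose structural zeros follow ``adjacency``.

        ``fixed`` optionally pins additional (row, col) entries to known values.
        """
        a = adjacency.entries
        mask = a == 0
        values = np.zeros_like(a, dtype=float)
        if fixed:
            for (i, j), v in fixed.items():
                if a[i, j] == 0 and v != 0.0:
                    raise ConstraintError(
                        f"cannot fix w[{i},{j}]={v}: no link in the adjacency matrix"
                    )
                if not 0.0 <= v <= 1.0:
                    raise ConstraintError(f"fixed value w[{i},{j}]={v} outside [0, 1]")
                mask[i, j] = True
                values[i, j] = v
        return cls(entries=np.asarray(entries, dtype=float), fixed_mask=mask, fixed_values=values)

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.entries.copy(), self.fixed_mask.copy(), self.fixed_values.copy())


def validate_weight_matrix(
    W: WeightMatrix, A: Optional[AdjacencyMatrix] = None
) -> list[Violation]:
    """Report every violated weight-matrix invariant; empty list iff valid.

    Checks row sums (tolerance ``ROW_SUM_TOL``), the [0, 1] range, structural
    zeros against ``A`` (when given), and exact agreement at fixed positions.
    """
    w = W.entries
    n = w.shape[0]
    if A is not None and A.entries.shape != w.shape:
        raise DimensionError("adjacency and weight matrix shapes differ")
    report: list[Violation] = []
    sums = w.sum(axis=1)
    for i in np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]:
        report.append(Violation("row_sum", int(i), None, f"row sums to {sums[i]:.12g}"))
    bad = np.argwhere((w < 0.0) | (w > 1.0))
    for i, j in bad:
        report.append(Violation("range", int(i), int(j), f"w={w[i, j]:.12g} outside [0, 1]"))
    if A is not None:
        for i, j in np.argwhere((A.entries == 0) & (w != 0.0)):
            report.append(
                Violation("structural_zero", int(i), int(j), f"w={w[i, j]:.12g} but a_ij=0")
            )
    for i, j in np.argwhere(W.fixed_mask & (w != W.fixed_values)):
        report.append(
            Violation(
                "fixed_value",
                int(i),
                int(j),
                f"w={w[i, j]:.12g} != fixed {W.fixed_values[i, j]:.12g}",
            )
        )
    return report


def _weight_array(W) -> np.ndarray:
    return W.entries if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)


def degroot_step(W, x) -> np.ndarray:
    """One DeGroot update X(t+1) = W X(t).

    Because each row of W is a set of convex weights, every output entry lies
    between min(x) and max(x), hence within [0, 1] for opinion vectors.
    """
    w = _weight_array(W)
    xv = np.asarray(x, dtype=float)
    if xv.ndim != 1 or xv.shape[0] != w.shape[1]:
        raise DimensionError(
            f"opinion vector length {xv.shape} does not match weight matrix {w.shape}"
        )
    if isinstance(W, WeightMatrix):
        report = validate_weight_matrix(W)
        if report:
            raise ConstraintError(f"invalid weight matrix: {report[0]}")
    return w @ xv


def degroot_trajectory(W, x0, T: int) -> np.ndarray:
    """Iterate the DeGroot update, returning the (T, N) panel (X(0), ..., X(T-1)).

    Row 0 is ``x0`` itself; T = 1 returns only the initial opinions.
    """
    if int(T) != T or T < 1:
        raise ValueError(f"T must be an integer >= 1, got {T!r}")
    w = _weight_array(W)
    x = np.asarray(x0, dtype=float)
    out = np.empty((int(T), x.shape[0]), dtype=float)
    out[0] = x
    for t in range(1, int(T)):
        out[t] = w @ out[t - 1]
    return out
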