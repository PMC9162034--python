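"""Calibration-study harness: factorial grid, per-run records, and summaries.

The study crosses network size, mean degree, time steps, scale precision,
population size, and the three hyperparameter preset groups with the
stagnation-threshold level, running the genetic algorithm on freshly generated
synthetic data for each replicate of each feasible design cell.  Cells whose
mean degree is infeasible for the network size (d >= N) are excluded.
Performance is measured by whether and when (in thousand-generation blocks) a
perfect solution was found, by elapsed time, and by parameter-recovery RMSE
over the non-structurally-zero weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ga import run
from .hyperparameters import HyperParameters
from .network import AdjacencyMatrix, ConstraintError, DimensionError, WeightMatrix
from .scale import OrdinalScale
from .synthetic import GeneratorSpec, generate_dataset

__all__ = [
    "StudyDesign",
    "DesignCell",
    "RunRecord",
    "recovery_rmse",
    "run_cell",
    "run_study",
    "summarize",
]

logger = logging.getLogger(__name__)

_CELL_COLUMNS = (
    "cell_id",
    "n_agents",
    "mean_degree",
    "time_steps",
    "bins",
    "chromosomes",
    "probsigma",
    "minmax",
    "multfactor",
    "iter_level",
)


def recovery_rmse(W_true, W_hat, A: AdjacencyMatrix) -> float:
    """Root-mean-square weight-recovery error over the P linked positions.

    RMSE = sqrt( sum_{a_ij=1} (w_ij - what_ij)^2 / P ), with self-links
    included in P.  Both matrices must respect A's structural zeros.
    """
    wt = W_true.entries if isinstance(W_true, WeightMatrix) else np.asarray(W_true, float)
    wh = W_hat.entries if isinstance(W_hat, WeightMatrix) else np.asarray(W_hat, float)
    a = A.entries
    if wt.shape != a.shape or wh.shape != a.shape:
        raise DimensionError("weight and adjacency shapes differ")
    zeros = a == 0
    if np.any(wt[zeros] != 0) or np.any(wh[zeros] != 0):
        raise ConstraintError("a weight matrix violates the structural zeros of A")
    mask = a == 1
    diff = wt[mask] - wh[mask]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class DesignCell:
    """One feasible combination of the study factors."""

    cell_id: int
    n_agents: int
    mean_degree: int
    time_steps: int
    bins: int
    chromosomes: int
    probsigma: str
    minmax: str
    multfactor: str
    iter_level: int

    def hyperparameters(self, max_iter: int) -> HyperParameters:
        return HyperParameters.from_levels(
            probsigma=self.probsigma,
            minmax=self.minmax,
            multfactor=self.multfactor,
            iter_level=self.iter_level,
            chromosomes=self.chromosomes,
            max_iter=max_iter,
        )


@dataclass(frozen=True)
class StudyDesign:
    """The full factorial grid with replication, subsampling, and seeding.

    Defaults reproduce the calibration study's factor levels with 10
    replicates per cell.  ``subsample`` keeps a seeded uniform fraction of the
    feasible cells (subsampling is by cell, preserving within-cell replicate
    structure); ``max_iter`` caps each run.
    """

    network_sizes: tuple[int, ...] = (4, 20, 50)
    mean_degrees: tuple[int, ...] = (2, 5, 9)
    time_steps: tuple[int, ...] = (2, 3, 6)
    scale_bins: tuple[int, ...] = (5, 7, 10, 20, 30)
    chromosomes: tuple[int, ...] = (5, 21, 51, 99)
    probsigma: tuple[str, ...] = ("low", "medium", "high")
    minmax: tuple[str, ...] = ("minimal", "moderate", "extreme")
    multfactor: tuple[str, ...] = ("slow", "moderate", "rapid")
    iter_levels: tuple[int, ...] = (200, 1000, 5000)
    replicates: int = 10
    subsample: float = 1.0
    max_iter: int = 100_000
    base_seed: int = 0

    def feasible_cells(self) -> list[DesignCell]:
        """All cells with d < N, in grid order, numbered before subsampling."""
        cells = []
        cell_id = 0
        for N, d, T, n, k, ps, mm, mf, lvl in itertools.product(
            self.network_sizes,
            self.mean_degrees,
            self.time_steps,
            self.scale_bins,
            self.chromosomes,
            self.probsigma,
            self.minmax,
            self.multfactor,
            self.iter_levels,
        ):
            if d >= N:
                logger.debug("skipping infeasible cell N=%d, d=%d", N, d)
                cell_id += 1
                continue
            cells.append(DesignCell(cell_id, N, d, T, n, k, ps, mm, mf, lvl))
            cell_id += 1
        return cells

    def sampled_cells(self) -> list[DesignCell]:
        """The seeded uniform subsample of feasible cells actually run."""
        cells = self.feasible_cells()
        if self.subsample >= 1.0:
            return cells
        rng = np.random.default_rng(np.random.SeedSequence([self.base_seed, 0xC311]))
        count = max(1, int(round(self.subsample * len(cells))))
        idx = np.sort(rng.choice(len(cells), size=count, replace=False))
        return [cells[i] for i in idx]


@dataclass(frozen=True)
class RunRecord:
    """Design-cell values plus the measured outcomes of one replicate."""

    cell: DesignCell
    replicate: int
    seed: int
    solved: bool
    generations: int
    blocks_to_solution: Optional[int]  # thousand-generation increments; None if unsolved
    elapsed_seconds: float
    final_objective: float
    rmse: float

    def as_row(self) -> dict:
        row = {c: getattr(self.cell, c) for c in _CELL_COLUMNS}
        row.update(
            replicate=self.replicate,
            seed=self.seed,
            solved=self.solved,
            generations=self.generations,
            blocks_to_solution=self.blocks_to_solution,
            elapsed_seconds=self.elapsed_seconds,
            final_objective=self.final_objective,
            rmse=self.rmse,
        )
        return row


def _derive_seed(base_seed: int, cell_id: int, replicate: int, stream: int) -> int:
    ss = np.random.SeedSequence([base_seed, cell_id, replicate, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    cell: DesignCell,
    replicates: int,
    base_seed: int,
    max_iter: int = 100_000,
) -> list[RunRecord]:
    """Run one design cell: fresh network, weights, and panel per replicate.

    Seeds derive deterministically from (base_seed, cell_id, replicate); a
    failed replicate is recorded as unsolved with NaN outcomes rather than
    aborting the cell.
    """
    records = []
    hp = cell.hyperparameters(max_iter)
    scale = OrdinalScale(cell.bins)
    for rep in range(replicates):
        data_seed = _derive_seed(base_seed, cell.cell_id, rep, 0)
        ga_seed = _derive_seed(base_seed, cell.cell_id, rep, 1)
        try:
            data = generate_dataset(
                GeneratorSpec(
                    n_agents=cell.n_agents,
                    mean_degree=cell.mean_degree,
                    time_steps=cell.time_steps,
                    bins=cell.bins,
                    seed=data_seed,
                )
            )
            result = run(data.adjacency, data.observed, scale, hp, seed=ga_seed)
            rmse = recovery_rmse(data.true_weights, result.best_weights, data.adjacency)
            records.append(
                RunRecord(
                    cell=cell,
                    replicate=rep,
                    seed=ga_seed,
                    solved=result.solved,
                    generations=result.generations_run,
                    blocks_to_solution=(
                        (result.generations_run + 999) // 1000 if result.solved else None
                    ),
                    elapsed_seconds=float(sum(result.thousand_block_times)),
                    final_objective=result.best_fitness.total,
                    rmse=rmse,
                )
            )
        except Exception:  # pragma: no cover - defensive; surfaced in the table
            logger.exception("replicate %d of cell %d failed", rep, cell.cell_id)
            records.append(
                RunRecord(cell, rep, ga_seed, False, 0, None, float("nan"), float("nan"), float("nan"))
            )
    return records


def run_study(design: StudyDesign, out: Optional[str | Path] = None) -> pd.DataFrame:
    """Run the (sub)sampled study and return one row per run.

    When ``out`` is given, results are appended to the CSV after each cell and
    cells already present in an existing file are skipped, making long studies
    resumable.
    """
    done: set[int] = set()
    frames: list[pd.DataFrame] = []
    out_path = Path(out) if out is not None else None
    if out_path is not None and out_path.exists():
        prior = pd.read_csv(out_path)
        if len(prior):
            done = set(prior["cell_id"].astype(int))
            frames.append(prior)
    for cell in design.sampled_cells():
        if cell.cell_id in done:
            continue
        records = run_cell(cell, design.replicates, design.base_seed, design.max_iter)
        frame = pd.DataFrame([r.as_row() for r in records])
        frames.append(frame)
        if out_path is not None:
            header = not out_path.exists()
            frame.to_csv(out_path, mode="a", header=header, index=False)
    if not frames:
        return pd.DataFrame(columns=list(_CELL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def summarize(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate a results table into the study's headline summaries.

    Returns a dict of tidy DataFrames: ``overall`` (proportion solved within
    the first 1000-generation block; proportion unsolved at the cap), RMSE
    distribution summaries grouped by stagnation-threshold level, ProbSigma
    level, number of time steps, and chromosome count, and generations/time
    distributions by chromosome count.
    """
    if results is None or len(results) == 0:
        raise ValueError("results table is empty")
    df = results.copy()
    df["solved"] = df["solved"].astype(bool)
    solved_first_block = (df["solved"] & (df["blocks_to_solution"] <= 1)).mean()
    overall = pd.DataFrame(
        {
            "statistic": ["prop_solved_first_1000", "prop_unsolved_at_cap", "n_runs"],
            "value": [float(solved_first_block), float((~df["solved"]).mean()), float(len(df))],
        }
    )

    def rmse_by(key: str) -> pd.DataFrame:
        g = df.groupby(key)["rmse"]
        out = g.agg(["count", "mean", "median", "std"]).reset_index()
        return out

    effort = (
        df.groupby("chromosomes")[["generations", "elapsed_seconds"]]
        .agg(["mean", "median"])
        .reset_index()
    )
    effort.columns = ["_".join(c).rstrip("_") for c in effort.columns]
    return {
        "overall": overall,
        "rmse_by_iter_level": rmse_by("iter_level"),
        "rmse_by_probsigma": rmse_by("probsigma"),
        "rmse_by_time_steps": rmse_by("time_steps"),
        "rmse_by_chromosomes": rmse_by("chromosomes"),
        "effort_by_chromosomes": effort,
    }


def write_summary(summaries: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write the summary tables to one tidy CSV with a ``table`` column."""
    parts = []
    for name, frame in summaries.items():
        f = frame.copy()
        f.insert(0, "table", name)
        parts.append(f)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
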