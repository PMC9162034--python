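"""The adaptive genetic algorithm for fitting DeGroot weight matrices.

A chromosome is a candidate weight matrix W; a gene is one of its rows.  Each
generation applies, in order: selection with elitism (including a multi-donor
gene swap into the elite), random pairing and blending, crossover, mutation,
pairwise parent/offspring survival (with single-donor gene swaps), a
stagnation update, chromosome reintroduction, and control-parameter
adaptation.  The run stops when the elite objective is at or below ``min_dev``
— checked only every 1000 generations — or at ``max_iter`` generations.

The elite chromosome is exempt from the disruptive operators, and gene swaps
are kept only when they strictly improve the receiving chromosome's total
objective, so the elite objective is non-increasing across generations.

Reproducibility: one numpy Generator is seeded per run and consumed in a
fixed order each generation — pairing permutation; blending coins (per pair x
row) then one beta per firing row; crossover coins then permutation keys for
the firing rows; mutation coins then position uniforms and noise for the
firing rows.  The firing sets themselves are drawn from the same stream, so
runs with the same seed and inputs are bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .hyperparameters import ControlParameters, HyperParameters
from .network import (
    AdjacencyMatrix,
    ConstraintError,
    DimensionError,
    WeightMatrix,
)
from .objective import FitnessValue
from .scale import OrdinalScale

__all__ = [
    "Chromosome",
    "GAResult",
    "initialize_population",
    "select_elite",
    "gene_swap",
    "blend_pair",
    "crossover",
    "mutate",
    "survive",
    "adapt_controls",
    "reintroduce_chromosome",
    "run",
]

logger = logging.getLogger(__name__)


@dataclass
class Chromosome:
    """A candidate weight matrix with its cached fitness (None when stale)."""

    weights: WeightMatrix
    fitness: Optional[FitnessValue] = None

    def copy(self) -> "Chromosome":
        return Chromosome(self.weights.copy(), self.fitness)


@dataclass(frozen=True)
class GAResult:
    """Outcome of one run: best solution, effort spent, and per-generation history."""

    best_weights: WeightMatrix
    best_fitness: FitnessValue
    generations_run: int
    solved: bool
    thousand_block_times: tuple[float, ...]
    elite_trace: np.ndarray = field(repr=False)  # elite total per generation
    control_trace: np.ndarray = field(repr=False)  # (G, 4): p_b, p_c, p_m, sigma


# ---------------------------------------------------------------------------
# helpers bridging Chromosome objects and the batched kernels


def _structure_of(w: WeightMatrix) -> _engine.Structure:
    return _engine.Structure(w.fixed_mask, w.fixed_values)


def _wrap(entries: np.ndarray, template: WeightMatrix, fit: Optional[FitnessValue] = None) -> Chromosome:
    return Chromosome(
        WeightMatrix(entries, template.fixed_mask.copy(), template.fixed_values.copy()),
        fit,
    )


def _ensure_fitness(
    population: Sequence[Chromosome], evaluator: _engine.Evaluator
) -> None:
    stale = [c for c in population if c.fitness is None]
    if stale:
        W = np.stack([c.weights.entries for c in stale])
        totals, per_gene = evaluator.evaluate(W)
        for c, t, pg in zip(stale, totals, per_gene):
            c.fitness = FitnessValue(float(t), pg)


# ---------------------------------------------------------------------------
# public operators


def initialize_population(
    A: AdjacencyMatrix,
    fixed: Optional[dict[tuple[int, int], float]],
    k: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """k-1 random row-stochastic chromosomes plus one identity matrix.

    Free weights are drawn Unif(0,1) and each row rescaled so the free mass
    equals 1 minus the row's fixed mass; the identity chromosome is appended
    last.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"population size must be an odd integer >= 3, got {k}")
    st = _engine.Structure.from_adjacency(A, fixed)
    template = WeightMatrix(st.fixed_values.copy(), st.fixed_mask, st.fixed_values)
    randoms = st.random_matrices(k - 1, rng)
    chroms = [_wrap(randoms[i].copy(), template) for i in range(k - 1)]
    chroms.append(_wrap(st.identity_matrix(), template))
    return chroms


def select_elite(
    population: Sequence[Chromosome],
    observed_panel: np.ndarray,
    scale: OrdinalScale,
) -> tuple[Chromosome, list[Chromosome]]:
    """Pick the fittest chromosome (ties to the lowest index) and gene-swap with the rest.

    Returns the (possibly improved) elite and the (possibly modified) even-
    sized remainder of the population.
    """
    if not population:
        raise ValueError("population is empty")
    population = list(population)
    evaluator = _engine.Evaluator(_ordinal_panel(observed_panel, scale), scale)
    _ensure_fitness(population, evaluator)
    totals = [c.fitness.total for c in population]
    e = int(np.argmin(totals))  # argmin ties -> lowest index
    rest = [population[i] for i in range(len(population)) if i != e]
    elite, rest_out, _ = gene_swap(population[e], rest, observed_panel, scale)
    return elite, rest_out


def gene_swap(
    best: Chromosome,
    donors: Sequence[Chromosome],
    observed_panel: np.ndarray,
    scale: OrdinalScale,
) -> tuple[Chromosome, list[Chromosome], bool]:
    """Swap strictly fitter donor genes into ``best``, all at once or not at all.

    Each gene position may draw from a different donor (the one with the
    lowest gene fitness).  The modified best is re-evaluated; on strict
    improvement of its total the swaps stick for best and the affected donors,
    otherwise everything reverts.
    """
    donors = [d.copy() for d in donors]
    evaluator = _engine.Evaluator(_ordinal_panel(observed_panel, scale), scale)
    _ensure_fitness([best, *donors], evaluator)
    if not donors:
        return best.copy(), donors, False
    W_don = np.stack([d.weights.entries for d in donors])
    pg_don = np.stack([d.fitness.per_gene for d in donors])
    w_new, t_new, pg_new, donor_updates, accepted = _engine.gene_swap_multi(
        best.weights.entries.copy(),
        best.fitness.total,
        best.fitness.per_gene,
        W_don,
        pg_don,
        evaluator,
    )
    if not accepted:
        return best.copy(), donors, False
    best_out = _wrap(w_new, best.weights, FitnessValue(t_new, pg_new))
    for d_idx, new_w in donor_updates:
        donors[d_idx] = _wrap(new_w, donors[d_idx].weights)
    _ensure_fitness(donors, evaluator)
    return best_out, donors, True


def blend_pair(
    B: Chromosome, C: Chromosome, p_b: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Blend each gene of a random pair with probability p_b.

    A firing row i draws one beta ~ Unif(0,1) and replaces both rows by
    beta*B_i + (1-beta)*C_i and (1-beta)*B_i + beta*C_i.
    """
    if not np.array_equal(B.weights.fixed_mask, C.weights.fixed_mask) or not np.array_equal(
        B.weights.fixed_values, C.weights.fixed_values
    ):
        raise ConstraintError("blended chromosomes must share fixed structure")
    W = np.stack([B.weights.entries, C.weights.entries])
    _engine.blend_kernel(W, np.array([0]), np.array([1]), p_b, rng)
    return _wrap(W[0], B.weights), _wrap(W[1], C.weights)


def crossover(chrom: Chromosome, p_c: float, rng: np.random.Generator) -> Chromosome:
    """Reshuffle the non-fixed weights within each gene with probability p_c."""
    st = _structure_of(chrom.weights)
    W = chrom.weights.entries[None].copy()
    _engine.crossover_kernel(W, p_c, rng, st)
    return _wrap(W[0], chrom.weights)


def mutate(
    chrom: Chromosome, p_m: float, sigma: float, rng: np.random.Generator
) -> Chromosome:
    """Perturb one non-fixed weight per firing gene with Normal(0, sigma^2) noise."""
    st = _structure_of(chrom.weights)
    W = chrom.weights.entries[None].copy()
    _engine.mutate_kernel(W, p_m, sigma, rng, st)
    return _wrap(W[0], chrom.weights)


def survive(
    parents: Sequence[Chromosome],
    offspring: Sequence[Chromosome],
    observed_panel: np.ndarray,
    scale: OrdinalScale,
) -> list[Chromosome]:
    """Positional parent/offspring pairs; the fitter of each pair survives.

    Ties go to the parent.  Within each pair the fitter chromosome attempts a
    gene swap with the other as sole donor before surviving.
    """
    if len(parents) != len(offspring):
        raise DimensionError("parents and offspring lists must have equal length")
    evaluator = _engine.Evaluator(_ordinal_panel(observed_panel, scale), scale)
    parents = list(parents)
    offspring = list(offspring)
    _ensure_fitness(parents + offspring, evaluator)
    Wp = np.stack([c.weights.entries for c in parents])
    Wo = np.stack([c.weights.entries for c in offspring])
    tp = np.array([c.fitness.total for c in parents])
    to = np.array([c.fitness.total for c in offspring])
    pgp = np.stack([c.fitness.per_gene for c in parents])
    pgo = np.stack([c.fitness.per_gene for c in offspring])
    Wb, tb, pgb = _engine.survive_kernel(Wp, tp, pgp, Wo, to, pgo, evaluator)
    return [
        _wrap(Wb[i], parents[i].weights, FitnessValue(float(tb[i]), pgb[i]))
        for i in range(len(parents))
    ]


def adapt_controls(
    controls: ControlParameters, hp: HyperParameters, stagnation: int
) -> ControlParameters:
    """Multiplicative control-parameter adaptation (see HyperParameters.adapt_controls)."""
    return hp.adapt_controls(controls, stagnation)


def reintroduce_chromosome(
    population: Sequence[Chromosome],
    elite: Chromosome,
    mode: str,
) -> list[Chromosome]:
    """Replace the worst chromosome with an elite clone or an identity matrix.

    Fitness values must be current; worst-fitness ties break to the highest
    index.  ``population`` is the non-elite population.
    """
    if not population:
        raise ValueError("population is empty")
    if mode not in ("elite", "identity"):
        raise ValueError("mode must be 'elite' or 'identity'")
    population = [c.copy() for c in population]
    totals = np.array([c.fitness.total for c in population])
    worst = len(totals) - 1 - int(np.argmax(totals[::-1]))  # ties -> highest index
    if mode == "elite":
        population[worst] = elite.copy()
    else:
        st = _structure_of(elite.weights)
        population[worst] = _wrap(st.identity_matrix(), elite.weights)
    return population


def _ordinal_panel(observed_panel: np.ndarray, scale: OrdinalScale) -> np.ndarray:
    """Accept either an ordinal (integer) or forward-transformed panel."""
    arr = np.asarray(observed_panel)
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    from .scale import back_transform

    return back_transform(arr, scale)


# ---------------------------------------------------------------------------
# the full run


def run(
    A: AdjacencyMatrix,
    Y: np.ndarray,
    scale: OrdinalScale,
    hp: HyperParameters,
    seed: int,
    fixed: Optional[dict[tuple[int, int], float]] = None,
    log_every: int = 0,
) -> GAResult:
    """Fit a weight matrix to an observed ordinal panel.

    Parameters
    ----------
    A : adjacency matrix defining the structural zeros.
    Y : (T, N) panel of ordinal opinions in 1..n.
    scale : the n-point ordinal scale.
    hp : hyperparameters (population size, operator schedule, stopping rules).
    seed : seed for the single RNG stream driving the whole run.
    fixed : optional user-fixed weights as {(row, col): value}.
    log_every : log the elite objective every this many generations (0 = off).
    """
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[1] != A.n_agents:
        raise DimensionError(f"opinion panel shape {Y.shape} does not match N={A.n_agents}")
    if np.any(Y < 1) or np.any(Y > scale.n_bins):
        raise ValueError(f"ordinal opinions must lie in 1..{scale.n_bins}")

    rng = np.random.default_rng(seed)
    st = _engine.Structure.from_adjacency(A, fixed)
    evaluator = _engine.Evaluator(Y, scale)
    template = WeightMatrix(st.fixed_values.copy(), st.fixed_mask, st.fixed_values)

    k = hp.chromosomes
    n = A.n_agents
    D = k - 1  # non-elite count, even
    half = D // 2

    # population arrays; identity chromosome enters last, matching the
    # documented initialisation order
    W = np.concatenate([st.random_matrices(D, rng), st.identity_matrix()[None]])
    totals, per_gene = evaluator.evaluate(W)
    identity_entries = st.identity_matrix()
    id_total, id_pg = (x[0] for x in evaluator.evaluate(identity_entries[None]))

    controls = hp.initial_controls
    best_total = float(totals.min())
    stagnation = 0
    elite_trace = np.empty(hp.max_iter, dtype=float)
    control_trace = np.empty((hp.max_iter, 4), dtype=float)
    block_times: list[float] = []
    block_start = time.perf_counter()
    gen = 0

    for gen in range(1, hp.max_iter + 1):
        # selection with elitism + multi-donor gene swap into the elite
        e = int(np.argmin(totals))
        don_idx = np.concatenate([np.arange(e), np.arange(e + 1, k)])
        w_e, t_e, pg_e, donor_updates, _ = _engine.gene_swap_multi(
            W[e].copy(), float(totals[e]), per_gene[e], W[don_idx], per_gene[don_idx], evaluator
        )
        if donor_updates:
            upd = np.stack([w for _, w in donor_updates])
            ut, upg = evaluator.evaluate(upd)
            for (d, w_new), t_new, pg_new in zip(donor_updates, ut, upg):
                gi = don_idx[d]
                W[gi] = w_new
                totals[gi] = t_new
                per_gene[gi] = pg_new

        Wp = W[don_idx]  # parents (post gene-swap)
        tp = totals[don_idx].copy()
        pgp = per_gene[don_idx].copy()

        # offspring: blending on random pairs, then crossover, then mutation
        off = Wp.copy()
        perm = rng.permutation(D)
        ia, ib = perm[:half], perm[half:]
        _engine.blend_kernel(off, ia, ib, controls.p_b, rng)
        _engine.crossover_kernel(off, controls.p_c, rng, st)
        _engine.mutate_kernel(off, controls.p_m, controls.sigma, rng, st)
        to, pgo = evaluator.evaluate(off)

        # pairwise survival vs the pre-operator parents
        Ws, ts, pgs = _engine.survive_kernel(Wp, tp, pgp, off, to, pgo, evaluator)

        # next generation: elite in slot 0, survivors after it
        W = np.concatenate([w_e[None], Ws])
        totals = np.concatenate([[t_e], ts])
        per_gene = np.concatenate([pg_e[None], pgs])

        new_best = float(totals.min())
        if best_total - new_best > hp.min_improve:
            best_total = new_best
            stagnation = 0
        else:
            best_total = min(best_total, new_best)
            stagnation += 1

        if stagnation > 0 and stagnation % hp.iterr == 0:
            rest = totals[1:]
            worst = 1 + (D - 1 - int(np.argmax(rest[::-1])))  # ties -> highest index
            if hp.reintroduce == "elite":
                e_now = int(np.argmin(totals))
                W[worst] = W[e_now]
                totals[worst] = totals[e_now]
                per_gene[worst] = per_gene[e_now]
            else:
                W[worst] = identity_entries
                totals[worst] = id_total
                per_gene[worst] = id_pg

        controls = hp.adapt_controls(controls, stagnation)
        elite_trace[gen - 1] = best_total
        control_trace[gen - 1] = (controls.p_b, controls.p_c, controls.p_m, controls.sigma)

        if log_every and gen % log_every == 0:
            logger.info(
                "generation %d: elite objective %.6g, controls p_b=%.3g p_c=%.3g p_m=%.3g sigma=%.3g",
                gen, best_total, controls.p_b, controls.p_c, controls.p_m, controls.sigma,
            )

        if gen % 1000 == 0:
            now = time.perf_counter()
            block_times.append(now - block_start)
            block_start = now
            if best_total <= hp.min_dev:
                break

    if gen % 1000 != 0:  # run ended at a cap off the block grid
        block_times.append(time.perf_counter() - block_start)

    e = int(np.argmin(totals))
    best = WeightMatrix(W[e].copy(), st.fixed_mask.copy(), st.fixed_values.copy())
    fit = FitnessValue(float(totals[e]), per_gene[e].copy())
    return GAResult(
        best_weights=best,
        best_fitness=fit,
        generations_run=gen,
        solved=bool(fit.total <= hp.min_dev),
        thousand_block_times=tuple(block_times),
        elite_trace=elite_trace[:gen].copy(),
        control_trace=control_trace[:gen].copy(),
    )
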