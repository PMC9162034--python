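"""Batched numpy kernels behind the genetic operators.

The population is held as one (k, N, N) array and every operator acts on all
chromosomes at once; the public single-chromosome operators in
:mod:`degroot_ga.ga` wrap these same kernels at batch size 1, so there is a
single implementation of each operator.

Free (non-fixed) positions of each row are addressed through a padded slot
layout precomputed in :class:`Structure`: row i has m_i free slots, slot s of
row i points at column ``slot_cols[i, s]``, and slots s >= m_i are padding.
Crossover permutes the free values of a firing row via an argsort of uniform
keys (padding keys sort last); mutation addresses its target weight by slot
index.

Randomness: each kernel first draws its operator coins for every
(chromosome, row) pair, then draws the remaining quantities (betas, keys,
positions, noise) only for the rows that fired, in row-major order of the
firing set.  Given a seed, both the firing set and all subsequent draws are
fully determined, so runs are bit-reproducible.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .network import AdjacencyMatrix, ConstraintError

_FULL_BUDGET_TOL = 1e-12


class Structure:
    """Shared constraint structure of a population of weight matrices."""

    def __init__(self, fixed_mask: np.ndarray, fixed_values: np.ndarray):
        self.fixed_mask = np.asarray(fixed_mask, dtype=bool)
        self.fixed_values = np.asarray(fixed_values, dtype=float)
        n = self.fixed_mask.shape[0]
        self.n_agents = n
        self.free_mask = ~self.fixed_mask
        self.w_fixed = self.fixed_values.sum(axis=1)  # per-row sum of fixed values
        self.budget = 1.0 - self.w_fixed  # mass available to free positions
        if np.any(self.budget < -_FULL_BUDGET_TOL):
            raise ConstraintError("fixed values in a row exceed the unit row sum")
        self.m = self.free_mask.sum(axis=1).astype(np.int64)  # free slots per row
        fully_fixed = self.m == 0
        if np.any(fully_fixed & (np.abs(self.budget) > 1e-9)):
            i = int(np.nonzero(fully_fixed & (np.abs(self.budget) > 1e-9))[0][0])
            raise ConstraintError(f"row {i} is fully fixed but its values do not sum to 1")
        self.M = int(self.m.max()) if n else 0
        self.slot_cols = np.zeros((n, self.M), dtype=np.int64)
        self.slot_valid = np.zeros((n, self.M), dtype=bool)
        for i in range(n):
            cols = np.nonzero(self.free_mask[i])[0]
            self.slot_cols[i, : cols.size] = cols
            self.slot_valid[i, : cols.size] = True

    @classmethod
    def from_adjacency(
        cls,
        adjacency: AdjacencyMatrix,
        fixed: Optional[dict[tuple[int, int], float]] = None,
    ) -> "Structure":
        a = adjacency.entries
        mask = a == 0
        values = np.zeros(a.shape, dtype=float)
        if fixed:
            for (i, j), v in fixed.items():
                if a[i, j] == 0 and v != 0.0:
                    raise ConstraintError(
                        f"cannot fix w[{i},{j}]={v}: no link in the adjacency matrix"
                    )
                mask[i, j] = True
                values[i, j] = v
        return cls(mask, values)

    # -- row-subset gather/scatter -------------------------------------------------

    def gather_rows(
        self, W: np.ndarray, bi: np.ndarray, ri: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Free values of rows (bi, ri) as a padded (f, M) block.

        Returns (values, cols, valid); padding positions hold arbitrary
        gathered values and must be ignored via ``valid``.
        """
        cols = self.slot_cols[ri]
        valid = self.slot_valid[ri]
        vals = W[bi[:, None], ri[:, None], cols]
        return vals, cols, valid

    def scatter_rows(
        self,
        W: np.ndarray,
        bi: np.ndarray,
        ri: np.ndarray,
        vals: np.ndarray,
        cols: np.ndarray,
        valid: np.ndarray,
    ) -> None:
        """Write padded free values back into W, skipping padding slots."""
        f0, f1 = np.nonzero(valid)
        W[bi[f0], ri[f0], cols[f0, f1]] = vals[f0, f1]

    # -- canonical chromosomes -----------------------------------------------------

    def identity_matrix(self) -> np.ndarray:
        """The identity-like chromosome: fixed values held, free mass on the diagonal.

        With no user-fixed values this is the exact identity matrix.  If a
        row's diagonal is itself fixed, the free budget is spread evenly over
        the row's free positions instead.
        """
        n = self.n_agents
        W = self.fixed_values.copy()
        for i in range(n):
            if self.m[i] == 0:
                continue
            if self.free_mask[i, i]:
                W[i, i] = self.budget[i]
            else:
                W[i, self.free_mask[i]] = self.budget[i] / self.m[i]
        return W

    def random_matrices(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``count`` matrices: free entries Unif(0,1), rows rescaled to budget."""
        B = np.tile(self.fixed_values, (count, 1, 1))
        u = rng.random((count, self.n_agents, self.M)) * self.slot_valid
        sums = u.sum(axis=2, keepdims=True)
        np.maximum(sums, 1e-300, out=sums)
        P = u * (self.budget[None, :, None] / sums)
        bi = np.repeat(np.arange(count), self.n_agents)
        ri = np.tile(np.arange(self.n_agents), count)
        self.scatter_rows(
            B, bi, ri, P.reshape(-1, self.M), self.slot_cols[ri], self.slot_valid[ri]
        )
        return B


class Evaluator:
    """Batch objective evaluation against one observed ordinal panel."""

    def __init__(self, observed_ordinal: np.ndarray, scale):
        from .scale import forward_transform

        Y = np.asarray(observed_ordinal)
        if Y.ndim != 2:
            raise ValueError("observed panel must be a (T, N) array")
        self.scale = scale
        self.n = scale.n_bins
        self.Y = Y.astype(np.int64)
        self.Yf = self.Y.astype(float)
        self.X = forward_transform(self.Y, scale)  # (T, N) bin centres
        self.T, self.n_agents = self.X.shape

    def evaluate(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Totals (B,) and per-gene values (B, N) for a (B, N, N) weight batch."""
        B = W.shape[0]
        xhat = np.empty((B, self.T, self.n_agents), dtype=float)
        xhat[:, 0] = self.X[0]
        for t in range(1, self.T):
            np.matmul(W, xhat[:, t - 1][..., None], out=xhat[:, t][..., None])
        bins_hat = np.clip(np.ceil(xhat * self.n), 1.0, float(self.n))
        dev = np.abs(bins_hat - self.Yf[None]) * np.abs(xhat - self.X[None])
        per_gene = dev.sum(axis=1)
        return per_gene.sum(axis=1), per_gene


# -- operator kernels (all act in place on (B, N, N) batches) -----------------------


def blend_kernel(
    W: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    p_b: float,
    rng: np.random.Generator,
) -> None:
    """Row-wise convex blending of the chromosome pairs (W[ia[p]], W[ib[p]]).

    Each row of each pair fires independently with probability p_b; a firing
    row draws one beta ~ Unif(0,1) and both rows are replaced by the convex
    combinations beta*B + (1-beta)*C and (1-beta)*B + beta*C.  Fixed values
    are identical across the population and therefore preserved.
    """
    n = W.shape[1]
    fire = rng.random((ia.size, n)) < p_b
    pi, ri = np.nonzero(fire)
    if pi.size == 0:
        return
    beta = rng.random(pi.size)[:, None]
    rb = W[ia[pi], ri]
    rc = W[ib[pi], ri]
    W[ia[pi], ri] = beta * rb + (1.0 - beta) * rc
    W[ib[pi], ri] = (1.0 - beta) * rb + beta * rc


def crossover_kernel(
    W: np.ndarray,
    p_c: float,
    rng: np.random.Generator,
    st: Structure,
) -> None:
    """Reshuffle free values within each row firing with probability p_c.

    A firing row draws M uniform keys; sorting the keys of its valid slots
    induces a uniform random permutation of its free values.  Rows with
    fewer than two free positions are skipped.
    """
    fire = (rng.random((W.shape[0], st.n_agents)) < p_c) & (st.m[None, :] > 1)
    bi, ri = np.nonzero(fire)
    if bi.size == 0:
        return
    vals, cols, valid = st.gather_rows(W, bi, ri)
    keys = rng.random((bi.size, st.M))
    keys[~valid] = 2.0  # padding sorts last
    perm = np.argsort(keys, axis=1, kind="stable")
    new_vals = np.take_along_axis(vals, perm, axis=1)
    st.scatter_rows(W, bi, ri, new_vals, cols, valid)


def mutate_kernel(
    W: np.ndarray,
    p_m: float,
    sigma: float,
    rng: np.random.Generator,
    st: Structure,
) -> None:
    """Perturb one free weight per firing row and renormalise, in place.

    Each row fires independently with probability p_m; the target free weight
    is chosen uniformly and receives noise eps ~ Normal(0, sigma^2), giving
    w* = w + eps.  Then: w* < 0 is clamped to 0; w* above the row's free
    budget r is clamped to r with the other free weights zeroed; if the
    selected weight already held the full budget the excess r - w* is spread
    evenly over the other free positions; otherwise the other free weights
    are rescaled by (r - w*) over their previous sum to restore the unit row
    sum.  Rows with fewer than two free positions are skipped.
    """
    fire = (rng.random((W.shape[0], st.n_agents)) < p_m) & (st.m[None, :] > 1)
    bi, ri = np.nonzero(fire)
    f = bi.size
    if f == 0:
        return
    m = st.m[ri]
    pos = np.minimum((rng.random(f) * m).astype(np.int64), m - 1)
    eps = rng.normal(0.0, sigma, f)
    vals, cols, valid = st.gather_rows(W, bi, ri)
    rows = np.arange(f)
    w_sel = vals[rows, pos]
    r = st.budget[ri]
    w_star = np.clip(w_sel + eps, 0.0, r)
    # previous sum of the other free weights; dividing by it (rather than by
    # r - w_sel) restores the unit row sum exactly even under float drift
    others = (vals * valid).sum(axis=1) - w_sel
    full = others <= _FULL_BUDGET_TOL  # selected weight held the whole budget
    scale = np.where(full, 0.0, (r - w_star) / np.where(full, 1.0, others))
    share = np.where(full, (r - w_star) / np.maximum(m - 1, 1), 0.0)
    new_vals = np.where(full[:, None], share[:, None], vals * scale[:, None])
    np.clip(new_vals, 0.0, r[:, None], out=new_vals)  # shave ulp-level overshoot
    new_vals[rows, pos] = w_star
    st.scatter_rows(W, bi, ri, new_vals, cols, valid)


def gene_swap_multi(
    w_best: np.ndarray,
    total_best: float,
    pg_best: np.ndarray,
    W_don: np.ndarray,
    pg_don: np.ndarray,
    evaluator: Evaluator,
):
    """Swap every strictly fitter donor gene into the best chromosome at once.

    For each gene position the donor with the lowest gene fitness (ties to
    the lowest donor index) contributes its row if strictly fitter than the
    best chromosome's gene.  All swaps are applied simultaneously and kept —
    for the best chromosome and the affected donors — only if the
    re-evaluated total strictly improves.

    Returns (w_best, total_best, pg_best, donor_updates, accepted) where
    ``donor_updates`` lists (donor_index, new_weights) for donors that gave
    away a gene; the caller re-evaluates their fitness.
    """
    n = pg_best.shape[0]
    j = pg_don.argmin(axis=0)  # ties -> lowest donor index
    g_min = pg_don[j, np.arange(n)]
    swap = g_min < pg_best
    if not swap.any():
        return w_best, total_best, pg_best, [], False
    cand = w_best.copy()
    cand[swap] = W_don[j[swap], swap]
    ct, cpg = evaluator.evaluate(cand[None])
    if not ct[0] < total_best:
        return w_best, total_best, pg_best, [], False
    donor_updates = []
    for d in np.unique(j[swap]):
        rows = swap & (j == d)
        new_w = W_don[d].copy()
        new_w[rows] = w_best[rows]
        donor_updates.append((int(d), new_w))
    return cand, float(ct[0]), cpg[0], donor_updates, True


def survive_kernel(
    Wp: np.ndarray,
    tp: np.ndarray,
    pgp: np.ndarray,
    Wo: np.ndarray,
    to: np.ndarray,
    pgo: np.ndarray,
    evaluator: Evaluator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise parent/offspring survival with single-donor gene swapping.

    Within each positional pair the fitter chromosome (ties to the parent)
    plays best and the other sole donor; swaps are kept per pair only when
    the re-evaluated total strictly improves.  ``Wp`` is consumed (survivors
    are built into it); callers needing the parents must pass a copy.
    """
    off_better = to < tp
    pgd = np.where(off_better[:, None], pgp, pgo)
    tb = np.where(off_better, to, tp)
    pgb = np.where(off_better[:, None], pgo, pgp)
    swap = pgd < pgb  # (D, N)
    di, ri = np.nonzero(swap)
    # donor rows must be read before survivors overwrite the parent array
    donor_rows = np.where(off_better[di][:, None], Wp[di, ri], Wo[di, ri])
    survivors = Wp
    survivors[off_better] = Wo[off_better]
    if di.size:
        idx = np.unique(di)
        cand = survivors[idx].copy()
        local = np.searchsorted(idx, di)
        cand[local, ri] = donor_rows
        ct, cpg = evaluator.evaluate(cand)
        accept = ct < tb[idx]
        acc = idx[accept]
        survivors[acc] = cand[accept]
        tb[acc] = ct[accept]
        pgb[acc] = cpg[accept]
    return survivors, tb, pgb
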