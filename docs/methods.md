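# Methods

## Model

The DeGroot model describes deterministic opinion diffusion on a social
network of `N` agents.  Opinions live on the unit interval; at each time step
every agent replaces its opinion with a convex combination of its network
contacts' current opinions:

    X(t+1) = W X(t),        w_ij >= 0,  sum_j w_ij = 1,

where `w_ij` is the share of agent `i`'s updating influence attributed to
agent `j`.  A symmetric binary adjacency matrix `A` with self-links
(`a_ii = 1`, so agents weigh their own opinion) constrains `W` through
structural zeros: `w_ij = 0` wherever `a_ij = 0`.  The estimation target is
`W`; the data are panels of opinions observed at `T` consecutive time points.

## Ordinal observation

Survey opinions arrive on an `n`-point ordinal scale.  The package assumes
the ordinal categories have interval properties and maps them onto `[0, 1]`
by dividing the interval into `n` equal-width bins.  The forward
transformation sends ordinal `y` to the bin centre `(y - 0.5)/n`; the back
transformation sends continuous `x` to `ceil(n x)` (with `x = 0` mapped to
bin 1).  Bin boundaries belong to the lower bin, as forced by the ceiling.
Continuous values within `1e-12` below zero are clamped to 0 before binning,
because long chains of convex combinations can round a hair below zero.

## Objective

A candidate `W` is scored against the forward-transformed observed panel by
free-running the model from the observed initial opinions
(`Xhat(0) = X(0)`, `Xhat(t+1) = W Xhat(t)`) and accumulating

    f = sum_i sum_t B(xhat_i(t), x_i(t)) |xhat_i(t) - x_i(t)|,

where `B` counts how many bins apart prediction and observation land.  The
factor `B` makes deviation free while the prediction stays in the observed
bin, so `f = 0` exactly when the fit is perfect *on the ordinal scale*.  The
per-agent summand is the fitness of one row (gene) of `W`; it depends on the
other rows only through the predicted trajectory.  `f` is discontinuous and
non-convex with large plateaus, which motivates a genetic algorithm over
gradient methods.

Note a consequence of seeding predictions with observed bin centres: the
*generating* weight matrix of a synthetic dataset is only approximately a
perfect solution, because it propagates bin centres rather than the latent
initial opinions.  Perfect solutions on the ordinal scale nevertheless exist
in abundance (and need not resemble the generating matrix, especially for
coarse scales and short panels) — this surplus of spurious perfect solutions
is the central phenomenon the calibration study quantifies.

## Genetic algorithm

A chromosome is a candidate `W`; a gene is a row.  Each generation applies:

1. **Selection with elitism.** The lowest-objective chromosome (ties to the
   lowest population index) is exempted from the disruptive operators.
2. **Gene swapping into the elite.** For each gene position, the donor with
   the strictly lowest gene fitness (each position may use a different
   donor; donor ties to the lowest index) offers its row.  All such swaps
   are applied at once and kept — for elite and donors — only if the elite's
   re-evaluated total strictly improves; otherwise everything reverts.
3. **Blending.** The remaining even population is paired uniformly at
   random.  Each gene of a pair blends with probability `p_b`, replacing
   both rows with convex combinations `beta*B + (1-beta)*C` and
   `(1-beta)*B + beta*C`, one `beta ~ Unif(0,1)` per firing row.
4. **Crossover.** Each gene reshuffles its non-fixed weights uniformly at
   random with probability `p_c`.
5. **Mutation.** Each gene, with probability `p_m`, adds
   `eps ~ Normal(0, sigma^2)` to one uniformly chosen non-fixed weight `w`,
   giving `w* = w + eps`, then restores the row sum: `w* < 0` is clamped to
   0; `w*` above the row's free budget `r = 1 - w_fixed` is clamped to `r`
   with the other free weights zeroed; if `w` held the whole budget the
   excess `r - w*` is spread evenly over the other free positions; otherwise
   the other free weights are rescaled by `(r - w*)` over their previous
   sum.  The divisor is the *actual* previous sum rather than `r - w`
   because the former restores the unit row sum exactly under accumulated
   float drift; rescaled values are additionally clipped into `[0, r]` to
   absorb one-ulp rounding overshoot.  Rows with fewer than two free
   positions are skipped.  Mutation is the only operator that can reach
   boundary rows ("edge cases"), which matters below.
6. **Survival.** Parent `j` (pre-operator) meets offspring `j`; the fitter
   (ties to the parent) attempts a gene swap with the other as sole donor
   and survives.  Survivors plus the elite form the next generation.

**Adaptation.**  A single stagnation counter tracks consecutive generations
in which the elite objective failed to improve by more than `min_improve`
(reset on improvement).  When the counter is a positive multiple of a
control's `iter*` threshold, that control is multiplied by its factor and
clamped: `p_b` grows toward `maxb` (exploitation via blending), while `p_c`,
`p_m` and `sigma` shrink toward their minima (away from exploration).  On
multiples of `iterr` the worst non-elite chromosome (ties to the highest
index) is replaced by an elite clone or an identity matrix.  The run stops
when the elite objective is at or below `min_dev` — checked only every 1000
generations — or at `max_iter` generations; elapsed time is recorded per
1000-generation block on a monotonic clock.

**Initial population.**  `chromosomes - 1` random matrices (free weights
`Unif(0,1)`, rows rescaled to the free budget) plus one identity matrix.
The population size must be odd so that the post-selection remainder pairs
evenly.

**Reproducibility.**  One numpy `Generator` is seeded per run and consumed
in a fixed order per generation (pairing permutation; blending coins, then
one beta per firing row; crossover coins, then keys per firing row; mutation
coins, then positions and noise per firing row).  All ties break
deterministically, so identical seeds give bit-identical results.  The hot
loop operates on the whole population as one `(k, N, N)` array; the public
single-chromosome operators wrap the same kernels, so there is one
implementation of each operator.

### Hyperparameters

Defaults are the recommended starting values: 21 chromosomes; initial
controls `p_b = p_c = p_m = 0.1`, `sigma = 0.5` (the "medium" preset);
bounds `maxb = 0.5`, `minc = minm = mins = 0.01` ("moderate"); factors
`factorb = 5`, `factorc = factorm = factors = 0.2` ("moderate"); all
stagnation thresholds 200 generations; `max_iter = 100000`;
`min_improve = min_dev = 0`; elite reintroduction.  The three preset
families each ship three named levels (low/medium/high initial controls,
minimal/moderate/extreme bounds, slow/moderate/rapid factors).  `sigma` and
its schedule deserve the most care: large `sigma` with a late threshold
forces a prolonged search of the simplex boundary, which harms parameter
recovery when the truth is interior.

## Synthetic data generator

Each dataset draws: a connected Erdős–Rényi network with edge probability
`p = d/(N-1)` (so the expected degree equals the target mean degree `d`;
disconnected draws are rejected, which also enforces minimum degree 1, with
a 10,000-draw budget); self-weights `w_ii ~ Beta(kappa*mu, kappa*(1-mu))`
with mean `mu = 0.5` and concentration `kappa = 4` (i.e. Beta(2,2)); the
remaining row mass spread over neighbours as rescaled `Unif(0,1)` draws;
initial opinions `Unif(0,1)`; `T` DeGroot steps; and ordinal observation of
every latent opinion on an `n`-point scale.  All free weights come from
continuous interior distributions, so the ground truth almost surely
contains no boundary rows — the generator is deliberately biased against
edge-case solutions.  Isolated rows (possible only with user-supplied
adjacency, not under rejection sampling) get `w_ii = 1`.

What the generator does *not* emulate: measurement error beyond
discretisation, missing agents or waves, directed or weighted ties, and
drifting influence over time.  Passing recovery tests therefore demonstrate
identifiability under clean, exactly-DeGroot data, not robustness to the
messiness of field panels.

## Calibration study harness

The study design crosses network size {4, 20, 50}, mean degree {2, 5, 9},
time steps {2, 3, 6}, scale bins {5, 7, 10, 20, 30}, population size
{5, 21, 51, 99}, the three preset families (3 levels each), and the shared
stagnation threshold {200, 1000, 5000}; cells with `d >= N` are infeasible
and excluded.  Each replicate of each cell draws a fresh dataset and runs
the algorithm, recording whether and when (in 1000-generation blocks) a
perfect solution appeared, the elapsed time, the final objective, and the
recovery RMSE

    RMSE_rec = sqrt( sum_{a_ij = 1} (w_ij - what_ij)^2 / P ),

with `P` the number of linked (non-structurally-zero) positions, self-links
included.  Seeds derive deterministically from `(base_seed, cell, replicate)`
via `SeedSequence`, so the full results table is a pure function of the
design (timings excepted).  Subsampling operates on whole cells to preserve
the within-cell replicate structure, and studies writing to CSV are
resumable (finished cells are skipped).

`summarize` reports the proportion of runs solving within the first
1000-generation block, the proportion unsolved at the cap, RMSE
distributions by stagnation level, initial-control level, time steps and
population size, and effort (generations, seconds) by population size.

## Problem sizes used by the test suite

The shipped tests exercise the full factorial machinery at reduced scale,
as the package's own default verification workload: the directional RMSE
comparisons use 110 matched-seed pairs per contrast on 4-agent networks at
a 1000-generation cap; the study-aggregate check uses a seeded uniform
subsample of ~300 cells at one replicate and a 1000-generation cap for the
first-block proportion, and a ~40-cell subsample at the full
100,000-generation cap for the failure proportion.  The full 10-replicate
factorial (≈340,000 runs) is reproducible through `StudyDesign()` defaults
but is a cluster-scale computation, not part of the test suite.

## Known limitations

- Where the operator definitions leave micro-choices open (which donor
  contributes when several are equally fit, tie-breaks in selection and
  replacement, whether pairs are re-drawn each generation), this
  implementation fixes them deterministically as documented above.  Such
  choices shift the absolute solving-speed aggregates of a study while
  preserving the directional comparisons between design cells.
- Binning uses the ceiling of `n x` in double precision; a prediction
  sitting within one ulp of a bin boundary can land on either side.  This
  only matters for ties that are measure-zero under the generator.
- The harness runs serially; cells are independent, so users can shard a
  large design across processes by splitting the grid and concatenating the
  CSVs.
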