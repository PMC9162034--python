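"""Fitness function linking a candidate weight matrix to observed ordinal opinions.

Given an observed panel of opinions (forward-transformed to bin centres), a
candidate weight matrix W is scored by free-running the DeGroot model from the
observed initial opinions and accumulating, over agents i and times t,

    f = sum_i sum_t B(xhat_i(t), x_i(t)) * |xhat_i(t) - x_i(t)|,

where B counts the bin deviation on the ordinal scale.  Continuous deviation is
penalised only when the prediction lands in the wrong bin (the product form),
so f = 0 exactly when the predicted trajectory matches the observations on the
ordinal scale.  The same sum restricted to one agent scores a single gene
(row of W) and drives the gene-swapping operator; a gene's fitness depends on
the other genes only through the predicted trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DimensionError, _weight_array
from .scale import OrdinalScale, _bins_unchecked

__all__ = ["FitnessValue", "predict", "chromosome_fitness", "gene_fitness"]


@dataclass(frozen=True)
class FitnessValue:
    """Chromosome-level objective value and its per-agent (per-gene) breakdown."""

    total: float
    per_gene: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_gene", np.asarray(self.per_gene, dtype=float))


def predict(W, observed_panel: np.ndarray) -> np.ndarray:
    """Free-run the DeGroot model from the observed initial opinions.

    Returns the predicted (T, N) trajectory with row 0 equal to the observed
    X(0) and row t+1 = W @ row t.  ``observed_panel`` is the forward-transformed
    ordinal panel.
    """
    w = _weight_array(W)
    panel = np.asarray(observed_panel, dtype=float)
    if panel.ndim != 2 or panel.shape[1] != w.shape[0]:
        raise DimensionError(
            f"observed panel shape {panel.shape} does not match weight matrix {w.shape}"
        )
    out = np.empty_like(panel)
    out[0] = panel[0]
    for t in range(1, panel.shape[0]):
        out[t] = w @ out[t - 1]
    return out


def _panel_terms(
    predicted: np.ndarray, observed: np.ndarray, scale: OrdinalScale
) -> np.ndarray:
    """(T, N) array of the objective's summands B * |xhat - x|."""
    n = scale.n_bins
    b_hat = _bins_unchecked(predicted, n)
    b_obs = _bins_unchecked(observed, n)
    return np.abs(b_hat - b_obs) * np.abs(predicted - observed)


def chromosome_fitness(
    W, observed_panel: np.ndarray, scale: OrdinalScale
) -> FitnessValue:
    """Evaluate the objective for one chromosome.

    ``total`` is the double sum over agents and times; ``per_gene[i]`` is agent
    i's contribution (the gene-level objective), so total == per_gene.sum()
    exactly.  The t = 0 terms vanish because the prediction is seeded with the
    observed initial opinions.
    """
    predicted = predict(W, observed_panel)
    terms = _panel_terms(predicted, np.asarray(observed_panel, dtype=float), scale)
    per_gene = terms.sum(axis=0)
    return FitnessValue(total=float(per_gene.sum()), per_gene=per_gene)


def gene_fitness(
    predicted: np.ndarray,
    observed_panel: np.ndarray,
    scale: OrdinalScale,
    agent: int,
) -> float:
    """Agent ``agent``'s summand of the objective, against a full predicted trajectory.

    The trajectory must come from the gene's own chromosome: a gene's fitness
    depends on the genes of the agents who influence it.
    """
    predicted = np.asarray(predicted, dtype=float)
    n_agents = predicted.shape[1]
    if not 0 <= agent < n_agents:
        raise IndexError(f"agent index {agent} out of range 0..{n_agents - 1}")
    terms = _panel_terms(predicted, np.asarray(observed_panel, dtype=float), scale)
    return float(terms[:, agent].sum())
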