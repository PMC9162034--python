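"""User-facing hyperparameters and the evolving control parameters.

The four control parameters — the operator probabilities p_b (blending),
p_c (crossover), p_m (mutation) and the mutation noise scale sigma — evolve
during a run: whenever the elite objective has stagnated for a multiple of the
corresponding iter* threshold, each is multiplied by its factor and clamped at
its bound.  Blending grows toward maxb (exploitation); crossover, mutation and
sigma shrink toward their minima (away from exploration).

The 22 hyperparameters are grouped into three named preset families used in
the calibration study — ProbSigma (initial control values), MinMax (bounds)
and MultFactor (adaptation factors) — each with three levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Union

__all__ = [
    "ControlParameters",
    "HyperParameters",
    "PROBSIGMA_LEVELS",
    "MINMAX_LEVELS",
    "MULTFACTOR_LEVELS",
    "load_config",
]

#: Initial control-parameter values (probb, probc, probm, sigma) by level.
PROBSIGMA_LEVELS: dict[str, dict[str, float]] = {
    "low": {"probb": 0.01, "probc": 0.05, "probm": 0.05, "sigma": 0.2},
    "medium": {"probb": 0.1, "probc": 0.1, "probm": 0.1, "sigma": 0.5},
    "high": {"probb": 0.2, "probc": 0.2, "probm": 0.2, "sigma": 1.0},
}

#: Control-parameter bounds (maxb, minc, minm, mins) by level of restriction.
MINMAX_LEVELS: dict[str, dict[str, float]] = {
    "minimal": {"maxb": 1.0, "minc": 0.0, "minm": 0.0, "mins": 0.0},
    "moderate": {"maxb": 0.5, "minc": 0.01, "minm": 0.01, "mins": 0.01},
    "extreme": {"maxb": 0.2, "minc": 0.05, "minm": 0.05, "mins": 0.05},
}

#: Multiplicative adaptation factors (factorb, factorc, factorm, factors) by speed.
MULTFACTOR_LEVELS: dict[str, dict[str, float]] = {
    "slow": {"factorb": 2.0, "factorc": 0.5, "factorm": 0.5, "factors": 0.5},
    "moderate": {"factorb": 5.0, "factorc": 0.2, "factorm": 0.2, "factors": 0.2},
    "rapid": {"factorb": 10.0, "factorc": 0.1, "factorm": 0.1, "factors": 0.1},
}

_ITER_FIELDS = ("iterb", "iterc", "iterm", "iters", "iterr")


@dataclass(frozen=True)
class ControlParameters:
    """Current operator intensities (p_b, p_c, p_m, sigma)."""

    p_b: float
    p_c: float
    p_m: float
    sigma: float


@dataclass(frozen=True)
class HyperParameters:
    """All user-facing settings governing one run of the genetic algorithm.

    Field names match the flat configuration-file keys.  Defaults are the
    recommended starting values: 21 chromosomes, medium initial control
    values, moderate bounds, moderate adaptation factors, all stagnation
    thresholds at 200 generations, a 100 000-generation cap, and elite
    reintroduction.
    """

    chromosomes: int = 21
    probb: float = 0.1
    factorb: float = 5.0
    maxb: float = 0.5
    iterb: int = 200
    probc: float = 0.1
    factorc: float = 0.2
    minc: float = 0.01
    iterc: int = 200
    probm: float = 0.1
    factorm: float = 0.2
    minm: float = 0.01
    iterm: int = 200
    sigma: float = 0.5
    factors: float = 0.2
    mins: float = 0.01
    iters: int = 200
    max_iter: int = 100_000
    min_improve: float = 0.0
    min_dev: float = 0.0
    reintroduce: str = "elite"
    iterr: int = 200

    def __post_init__(self) -> None:
        if self.chromosomes < 3 or self.chromosomes % 2 == 0:
            raise ValueError(f"chromosomes must be an odd integer >= 3, got {self.chromosomes}")
        for name in ("probb", "probc", "probm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.factorb < 1.0:
            raise ValueError("factorb must be >= 1 (blending probability grows)")
        for name in ("factorc", "factorm", "factors"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1] (these controls shrink), got {v}")
        if not self.probb <= self.maxb <= 1.0:
            raise ValueError("require probb <= maxb <= 1")
        if not 0.0 <= self.minc <= self.probc:
            raise ValueError("require 0 <= minc <= probc")
        if not 0.0 <= self.minm <= self.probm:
            raise ValueError("require 0 <= minm <= probm")
        if not 0.0 <= self.mins <= self.sigma:
            raise ValueError("require 0 <= mins <= sigma")
        for name in _ITER_FIELDS:
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.min_improve < 0 or self.min_dev < 0:
            raise ValueError("min_improve and min_dev must be nonnegative")
        if self.reintroduce not in ("elite", "identity"):
            raise ValueError("reintroduce must be 'elite' or 'identity'")

    @classmethod
    def from_levels(
        cls,
        probsigma: str = "medium",
        minmax: str = "moderate",
        multfactor: str = "moderate",
        iter_level: int = 200,
        **overrides,
    ) -> "HyperParameters":
        """Build hyperparameters from the named preset levels.

        ``iter_level`` sets all five stagnation thresholds to the same value,
        as in the calibration study.  Remaining fields can be overridden by
        keyword.
        """
        values: dict = {}
        try:
            values.update(PROBSIGMA_LEVELS[probsigma.lower()])
            values.update(MINMAX_LEVELS[minmax.lower()])
            values.update(MULTFACTOR_LEVELS[multfactor.lower()])
        except KeyError as exc:
            raise ValueError(f"unknown preset level: {exc.args[0]!r}") from None
        values.update({name: int(iter_level) for name in _ITER_FIELDS})
        values.update(overrides)
        return cls(**values)

    def replace(self, **changes) -> "HyperParameters":
        return replace(self, **changes)

    @property
    def initial_controls(self) -> ControlParameters:
        return ControlParameters(self.probb, self.probc, self.probm, self.sigma)

    def adapt_controls(self, controls: ControlParameters, stagnation: int) -> ControlParameters:
        """Multiplicatively adjust and clamp each control whose threshold fires.

        A control adjusts when ``stagnation`` is a positive multiple of its
        iter* threshold, allowing repeated adjustment during long stagnation.
        """
        if stagnation <= 0:
            return controls
        p_b, p_c, p_m, sigma = controls.p_b, controls.p_c, controls.p_m, controls.sigma
        if stagnation % self.iterb == 0:
            p_b = min(self.factorb * p_b, self.maxb)
        if stagnation % self.iterc == 0:
            p_c = max(self.factorc * p_c, self.minc)
        if stagnation % self.iterm == 0:
            p_m = max(self.factorm * p_m, self.minm)
        if stagnation % self.iters == 0:
            sigma = max(self.factors * sigma, self.mins)
        return ControlParameters(p_b, p_c, p_m, sigma)


def load_config(source: Union[str, Path, dict]) -> HyperParameters:
    """Load hyperparameters from a flat JSON file or dict.

    Keys are the flat hyperparameter field names; the optional keys ``probsigma``,
    ``minmax``, ``multfactor`` and ``iter_level`` expand to their preset
    values first, with explicit fields overriding them.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("hyperparameter config must be a JSON object")
    preset_kw = {
        key: data.pop(key)
        for key in ("probsigma", "minmax", "multfactor", "iter_level")
        if key in data
    }
    known = {f.name for f in fields(HyperParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown hyperparameter keys: {sorted(unknown)}")
    if preset_kw:
        return HyperParameters.from_levels(**preset_kw, **data)
    return HyperParameters(**data)
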