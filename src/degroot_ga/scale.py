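"""Bidirectional mapping between n-point ordinal opinions and continuous [0, 1] opinions.

Opinion diffusion is modelled on the continuous unit interval, but survey
instruments record opinions on an n-point ordinal (Likert-type) scale.  The
interval [0, 1] is divided into n equal-width bins; ordinal value y covers the
sub-interval ((y-1)/n, y/n], with bin 1 additionally including 0.  The forward
transformation sends an ordinal opinion to the centre of its bin; the back
transformation sends a continuous opinion to the index of the bin containing it
(via the ceiling function).  Bin boundaries therefore belong to the *lower*
bin: back_transform(0.6, n=5) == 3.

The bin-deviation measure B counts how many bins apart two continuous opinions
land after back transformation; it is the discrete factor in the fitting
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrdinalScale",
    "forward_transform",
    "back_transform",
    "bin_deviation",
    "relabel_ordinal",
]

# DeGroot products can round a hair below 0 at machine precision; clamp that.
_NEG_DRIFT_TOL = 1e-12


@dataclass(frozen=True)
class OrdinalScale:
    """An n-point equal-width ordinal scale on [0, 1]."""

    n_bins: int

    def __post_init__(self) -> None:
        if int(self.n_bins) != self.n_bins or self.n_bins < 1:
            raise ValueError(f"n_bins must be a positive integer, got {self.n_bins!r}")
        object.__setattr__(self, "n_bins", int(self.n_bins))


def forward_transform(y, scale: OrdinalScale):
    """Map ordinal opinion(s) y in 1..n to the centre (y - 0.5)/n of bin y.

    Accepts scalars or arrays; returns the matching float shape.
    """
    n = scale.n_bins
    arr = np.asarray(y)
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError(f"ordinal opinions must be numeric, got dtype {arr.dtype}")
    if np.any(arr != np.round(arr)):
        raise ValueError("ordinal opinions must be integers")
    if np.any(arr < 1) or np.any(arr > n):
        raise ValueError(f"ordinal opinions must lie in 1..{n}")
    out = (arr - 0.5) / n
    return float(out) if np.isscalar(y) else out


def back_transform(x, scale: OrdinalScale):
    """Map continuous opinion(s) x in [0, 1] to ordinal bin ceil(n*x), with 0 -> 1."""
    n = scale.n_bins
    arr = np.asarray(x, dtype=float)
    if np.any(arr < -_NEG_DRIFT_TOL) or np.any(arr > 1.0 + _NEG_DRIFT_TOL):
        raise ValueError("continuous opinions must lie in [0, 1]")
    out = _bins_unchecked(arr, n)
    return int(out) if np.isscalar(x) else out


def _bins_unchecked(x: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ceiling binning without range validation (hot path).

    ceil(n*x) with the x <= 0 edge case mapped to bin 1 and floating drift
    above 1 clipped back to bin n.
    """
    return np.clip(np.ceil(np.asarray(x, dtype=float) * n), 1, n).astype(np.int64)


def bin_deviation(x_hat, x, scale: OrdinalScale):
    """Absolute deviation, in bins, between two continuous opinions.

    B(x_hat, x) = |back_transform(x_hat) - back_transform(x)|; symmetric and
    bounded by n - 1.
    """
    b1 = back_transform(x_hat, scale)
    b2 = back_transform(x, scale)
    out = np.abs(np.asarray(b1) - np.asarray(b2))
    return int(out) if np.isscalar(x_hat) and np.isscalar(x) else out


def relabel_ordinal(panel):
    """Shift an ordinal panel on an arbitrary integer scale (e.g. -2..2) to 1..n.

    Panels already starting at 1 are returned unchanged.
    """
    arr = np.asarray(panel)
    if np.any(arr != np.round(arr)):
        raise ValueError("ordinal panel must contain integers")
    lo = arr.min()
    return (arr - lo + 1).astype(np.int64)
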