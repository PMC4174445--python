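"""Approach-to-equilibrium labeling kinetics.

After a thiolated-nucleotide pulse, labeled transcript abundance rises
toward a plateau.  Assuming first-order decay and zeroth-order synthesis,
the labeled pool of a transcript follows

    Y(t) = Y_eq * (1 - exp(-alpha * (t - t_d)))    for t > t_d,

where ``alpha = alpha_rna + alpha_growth`` is the total removal rate
(degradation plus dilution by cell division), ``Y_eq`` is the equilibrium
labeled abundance and ``t_d`` is the delay between label addition and first
detectability of labeled molecules.  Half-life refers to degradation only:
``ln(2) / alpha_rna``.

All rates are per minute; times are minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the saturating-exponential labeling curve."""

    alpha_total: float
    y_eq: float
    t_d: float = 2.0
    alpha_growth: float = LN2 / 100.0

    def __post_init__(self) -> None:
        if self.alpha_total <= 0:
            raise ValueError("alpha_total must be positive")
        if self.y_eq < 0:
            raise ValueError("y_eq must be non-negative")
        if self.t_d < 0:
            raise ValueError("t_d must be non-negative")

    @property
    def alpha_rna(self) -> float:
        return self.alpha_total - self.alpha_growth

    @property
    def half_life(self) -> float:
        return half_life(self.alpha_total, self.alpha_growth)


def model_y(t, alpha_total: float, y_eq: float, t_d: float = 2.0):
    """Expected labeled abundance at time(s) ``t`` minutes after label addition.

    Returns 0 for ``t <= t_d`` (labeled molecules are undetectable before the
    delay elapses).  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t_d
    out = np.where(dt > 0, y_eq * -np.expm1(-alpha_total * np.clip(dt, 0.0, None)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def alpha_growth_from_doubling(doubling_time: float) -> float:
    """Growth (dilution) rate constant ln(2)/doubling-time, per minute.

    For the canonical 100-min budding-yeast culture this is 0.0069 min^-1.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    return LN2 / doubling_time


def half_life(alpha_total: float, alpha_growth: float) -> float:
    """Degradation half-life ln(2)/(alpha_total - alpha_growth), minutes.

    Returns NaN (the explicit "undefined" marker) when the fitted total rate
    does not exceed the growth rate, i.e. when no degradation signal remains
    after subtracting dilution.  Never returns a negative number.
    """
    alpha_rna = alpha_total - alpha_growth
    if not np.isfinite(alpha_rna) or alpha_rna <= 0:
        return float("nan")
    return LN2 / alpha_rna
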