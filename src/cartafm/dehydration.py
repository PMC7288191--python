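"""Power-law model of specimen dehydration.

Cartilage specimens dry between excision and AFM measurement; their mass
follows a power law in time,

    m(t) = m0 * (1 + t)**b,      t in hours, b < 0,

with ``b`` close to -0.141414... for hyaline cartilage under typical room
conditions (20 degC, ~56 % humidity).  Measurements stabilise once roughly
30 % of the liquid is lost, which the model places at t = 12 h.

This module evaluates the model, fits it to (t, m) observations by linear
least squares in log space, and inverts it for the time at which a given
mass fraction is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "B_DEFAULT",
    "DehydrationSeries",
    "DehydrationFit",
    "predict_mass",
    "fit_power_law",
    "time_to_mass_fraction",
]

#: Default drying exponent: the repeating decimal -0.141414... = -14/99.
B_DEFAULT = -14.0 / 99.0


@dataclass(frozen=True, eq=False)
class DehydrationSeries:
    """Observed specimen mass over drying time.

    Parameters
    ----------
    t : array-like
        Times in hours, non-negative and strictly increasing.
    m : array-like
        Masses, positive, in the same (arbitrary) unit as ``m0``.
    """

    t: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        m = np.asarray(self.m, dtype=float)
        if t.ndim != 1 or m.shape != t.shape:
            raise ValueError("t and m must be 1-D arrays of equal length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "m", m)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class DehydrationFit:
    """Fitted parameters of the drying law and the mass-space residual."""

    m0: float
    b: float
    rss: float

    def predict(self, t):
        return predict_mass(t, self.m0, self.b)


def predict_mass(t, m0: float, b: float = B_DEFAULT):
    """Mass at time ``t`` (hours) under m = m0 * (1 + t)**b.

    Accepts a scalar or array ``t``; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if m0 <= 0:
        raise ValueError("initial mass must be positive")
    out = m0 * np.power(1.0 + t, b)
    return float(out) if out.ndim == 0 else out


def fit_power_law(series: DehydrationSeries) -> DehydrationFit:
    """Least-squares fit of log m = log m0 + b * log(1 + t).

    The fit is linear in log space, hence deterministic and exact on
    noiseless model data.  ``rss`` is the residual sum of squares in mass
    space (not log space), so it is comparable to measurement noise.
    """
    if len(series) < 3:
        raise ValueError("at least 3 observations are required")
    x = np.log1p(series.t)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, np.log(series.m), rcond=None)
    m0 = float(np.exp(coef[0]))
    b = float(coef[1])
    rss = float(np.sum((series.m - predict_mass(series.t, m0, b)) ** 2))
    return DehydrationFit(m0=m0, b=b, rss=rss)


def time_to_mass_fraction(fraction: float, b: float = B_DEFAULT) -> float:
    """Time (hours) at which m/m0 reaches ``fraction``; inverse of the model.

    t = fraction**(1/b) - 1, valid for 0 < fraction < 1 and b < 0.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if b >= 0:
        raise ValueError("drying exponent b must be negative")
    return float(fraction ** (1.0 / b) - 1.0)
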