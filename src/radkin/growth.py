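"""Unirradiated tumor growth: growth-rate decay law and Gompertz closed forms.

The specific growth rate decays because the vasculature grows slower than
the tumor by the retardation factor theta:

    d(lambda)/dt = -(1 - theta) * lambda(0) * lambda

so lambda(t) = lambda(0) * exp(-(1 - theta) * lambda(0) * t), and the
volume follows the Gompertzian closed form

    V(t) = V0 * exp[ (1/(1-theta)) * (1 - exp(-(1-theta) * lambda(0) * t)) ]

with the exponential limit V0 * exp(lambda(0) * t) at theta = 1.
lambda(0) = ln 2 / Td(0) where Td(0) is the initial volume doubling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthParams", "growth_rate_at", "gompertz_volume", "doubling_time", "LN2"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of vascular-limited Gompertz-type growth.

    Parameters
    ----------
    v0 : float
        Initial tumor volume, cm^3 (> 0).
    td0 : float
        Initial volume doubling time Td(0), days (> 0).  The initial
        growth rate is lambda(0) = ln 2 / td0.
    theta : float
        Vascular growth retardation factor, 0 < theta <= 1.  theta = 1
        gives pure exponential growth (no saturation).
    """

    v0: float
    td0: float
    theta: float

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if self.td0 <= 0:
            raise ValueError(f"td0 must be > 0, got {self.td0}")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")

    @property
    def lam0(self) -> float:
        """Initial specific growth rate lambda(0) = ln 2 / Td(0), 1/day."""
        return LN2 / self.td0

    @property
    def decay_rate(self) -> float:
        """Decay rate of lambda(t): (1 - theta) * lambda(0), 1/day."""
        return (1.0 - self.theta) * self.lam0

    def to_dict(self) -> dict:
        return {"v0_cm3": self.v0, "td0_days": self.td0, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        return cls(v0=float(d["v0_cm3"]), td0=float(d["td0_days"]), theta=float(d["theta"]))


def growth_rate_at(t, gp: GrowthParams):
    """Specific growth rate lambda(t), 1/day, at time(s) ``t`` >= 0 days.

    Accepts a scalar or array; vectorized via numpy.
    """
    t = np.asarray(t, dtype=float)
    out = gp.lam0 * np.exp(-gp.decay_rate * t)
    return out.item() if out.ndim == 0 else out


def log_growth_integral(t, lam0: float, decay_rate: float):
    """Integral of lambda(s) = lam0 * exp(-decay_rate * s) over [0, t].

    Used by the closed-form volume expressions; handles decay_rate -> 0.
    """
    t = np.asarray(t, dtype=float)
    if decay_rate == 0.0:
        out = lam0 * t
    else:
        out = lam0 / decay_rate * (-np.expm1(-decay_rate * t))
    return out.item() if out.ndim == 0 else out


def gompertz_volume(t, gp: GrowthParams):
    """Unirradiated volume V(t), cm^3, at time(s) ``t`` >= 0 days.

    Strictly increasing from V(0) = v0 toward the asymptote
    v0 * exp(1/(1-theta)) (theta < 1); pure exponential for theta = 1.
    """
    t = np.asarray(t, dtype=float)
    out = gp.v0 * np.exp(log_growth_integral(t, gp.lam0, gp.decay_rate))
    return out.item() if out.ndim == 0 else out


def doubling_time(lam: float) -> float:
    """Volume doubling time ln 2 / lambda, days, for a growth rate lam > 0."""
    if lam <= 0:
        raise ValueError(f"growth rate must be > 0, got {lam}")
    return LN2 / lam
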