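"""Linear-quadratic dose response and delayed-death probabilities.

Dose dependence is carried entirely by the lethality exponent

    chi(D) = alpha * D * (1 + D / (alpha/beta)),

the negative log of the LQ clonogenic survival fraction.  During the
active radiation-effect window the probability that a cell divides at
the end of a cycle is ``p = 1 - (T*/(3 T_m)) * chi`` and cells transit
to the non-dividing compartment at rate ``g = chi / (3 T_m)``, so that
``p + q = 1`` with ``q = (T*/(3 T_m)) * chi`` and ``g * 3 T_m = chi``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "RadiobiologyConstants",
    "lethality_exponent",
    "division_probability",
    "death_rate",
    "lq_survival",
]


@dataclass(frozen=True)
class RadiobiologyConstants:
    """Radiosensitivity and timing constants of the delayed-death model.

    Parameters
    ----------
    alpha : float
        Linear radiosensitivity coefficient, 1/Gy.  Must be >= 0.
    alpha_beta : float
        LQ alpha/beta ratio, Gy (the dose at which linear and quadratic
        killing contribute equally).  Must be > 0.  The quadratic
        coefficient beta is never independent: beta = alpha / alpha_beta.
    t_star : float
        Characteristic (cell-cycle) time T*, days.  Default 1.
    t_m : float
        Colony-counting / observation time T_m, days.  Default 10.
    """

    alpha: float
    alpha_beta: float = 10.0
    t_star: float = 1.0
    t_m: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.t_star <= 0:
            raise ValueError(f"t_star must be > 0, got {self.t_star}")
        if self.t_m <= 0:
            raise ValueError(f"t_m must be > 0, got {self.t_m}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_beta": self.alpha_beta,
            "t_star": self.t_star,
            "t_m": self.t_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadiobiologyConstants":
        return cls(
            alpha=float(d["alpha"]),
            alpha_beta=float(d.get("alpha_beta", 10.0)),
            t_star=float(d.get("t_star", 1.0)),
            t_m=float(d.get("t_m", 10.0)),
        )


def lethality_exponent(dose: float, consts: RadiobiologyConstants) -> float:
    """Return chi(D) = alpha * D * (1 + D / (alpha/beta)).

    chi(0) = 0 and chi is strictly increasing in dose for alpha > 0.

    Raises
    ------
    ValueError
        If ``dose`` is negative.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return consts.alpha * dose * (1.0 + dose / consts.alpha_beta)


def division_probability(dose: float, consts: RadiobiologyConstants) -> float:
    """Probability p(D) that a cell divides at the end of a cycle.

    p = 1 - (T*/(3 T_m)) * chi(D), clamped to [0, 1].  p(0) = 1.  A
    warning is emitted when the unclamped value falls below zero (large
    alpha * D excursions during fitting can push chi above 3 T_m / T*).
    """
    chi = lethality_exponent(dose, consts)
    p = 1.0 - consts.t_star / (3.0 * consts.t_m) * chi
    if p < 0.0:
        warnings.warn(
            f"division probability clamped: unclamped p = {p:.4g} "
            f"(dose = {dose} Gy, chi = {chi:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return min(p, 1.0)


def death_rate(dose: float, consts: RadiobiologyConstants) -> float:
    """Transition rate g(D) = chi(D) / (3 T_m) from dividing to non-dividing, 1/day."""
    return lethality_exponent(dose, consts) / (3.0 * consts.t_m)


def lq_survival(dose: float, consts: RadiobiologyConstants) -> float:
    """Clonogenic survival fraction S(D) = exp(-chi(D)) in (0, 1]."""
    return math.exp(-lethality_exponent(dose, consts))
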