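"""Three-phase piecewise simulation of the two-compartment radiation response.

The observable (e.g. contrast-enhanced MRI volume) is V_total = V_T + V_ND
where V_T is the dividing-cell volume and V_ND the non-dividing-cell volume.

Phase 1, t < t_R (pre-irradiation):
    dV_T/dt = lambda(t) V_T,   V_ND = 0,   lambda decays per the growth law.
Phase 2, t_R <= t < t_R + tau_rad (active radiation-effect window):
    lambda frozen at lambda_R;
    dV_T/dt  = (lambda_R p - g) V_T
    dV_ND/dt = g V_T - eta_cl V_ND
Phase 3, t >= t_R + tau_rad:
    dV_T/dt = lambda(t) V_T with lambda resuming exponential decay from
    lambda_R;  dV_ND/dt = -eta_cl V_ND.

All three states are continuous at the phase boundaries.  A dose of zero
means no radiation effect at all: the trajectory is the plain Gompertz
closed form (p = 1, g = 0 and no growth-rate freeze).

The constant-coefficient phases admit exact closed forms, which are the
default engine; `integrate_numeric` re-solves the same piecewise ODEs with
a stiff implicit integrator as an independent cross-check.

A comparator, `simulate_standard_model`, implements the conventional
instantaneous-kill response: at t_R a fraction S(D) = exp(-chi) of V_T
survives and the complement jumps into V_ND, with no effect window and no
growth-rate freeze.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .growth import LN2, GrowthParams, log_growth_integral
from .radiobiology import (
    RadiobiologyConstants,
    death_rate,
    division_probability,
    lq_survival,
)

__all__ = [
    "TreatmentSpec",
    "CaseConfig",
    "Trajectory",
    "simulate",
    "simulate_standard_model",
    "integrate_numeric",
    "phase2_closed_form",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """Single-fraction treatment schedule.

    Parameters
    ----------
    dose : float
        Prescribed (mean) dose, Gy, >= 0.
    t_r : float
        Irradiation day counted from the start of the series, >= 0.
    tau_rad : float
        Active radiation-effect time, days (> 0; the usual range is
        3 to 10 days and values outside it trigger a warning).
    t_cl : float
        Cell clearance time, days (> 0; may be ``inf`` for no clearance).
        The clearance rate is eta_cl = ln 2 / t_cl.
    """

    dose: float
    t_r: float
    tau_rad: float = 8.0
    t_cl: float = 10.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.t_r < 0:
            raise ValueError(f"t_r must be >= 0, got {self.t_r}")
        if self.tau_rad <= 0:
            raise ValueError(f"tau_rad must be > 0, got {self.tau_rad}")
        if self.t_cl <= 0:
            raise ValueError(f"t_cl must be > 0, got {self.t_cl}")
        if not 3.0 <= self.tau_rad <= 10.0:
            import warnings

            warnings.warn(
                f"tau_rad = {self.tau_rad} days is outside the usual 3-10 day range",
                UserWarning,
                stacklevel=2,
            )

    @property
    def eta_cl(self) -> float:
        """Clearance rate ln 2 / t_cl, 1/day (0 for t_cl = inf)."""
        return 0.0 if math.isinf(self.t_cl) else LN2 / self.t_cl

    def to_dict(self) -> dict:
        return {
            "dose_gy": self.dose,
            "t_r_days": self.t_r,
            "tau_rad_days": self.tau_rad,
            "t_cl_days": self.t_cl,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentSpec":
        return cls(
            dose=float(d["dose_gy"]),
            t_r=float(d["t_r_days"]),
            tau_rad=float(d.get("tau_rad_days", 8.0)),
            t_cl=float(d["t_cl_days"]),
        )


@dataclass(frozen=True)
class CaseConfig:
    """Everything needed to simulate one tumor.

    ``td_at_treatment`` optionally overrides the growth rate at the
    instant of irradiation: when set, lambda_R = ln 2 / td_at_treatment
    replaces the value the growth law would give at t_R (used when the
    doubling time at treatment is known independently of the decay-law
    extrapolation from baseline).  ``inf`` is allowed and means
    lambda_R = 0.
    """

    label: str
    growth: GrowthParams
    radio: RadiobiologyConstants
    treatment: TreatmentSpec
    td_at_treatment: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.td_at_treatment is not None and self.td_at_treatment <= 0:
            raise ValueError(
                f"td_at_treatment must be > 0, got {self.td_at_treatment}"
            )

    def lambda_r(self) -> float:
        """Growth rate in force at the irradiation instant, 1/day."""
        if self.td_at_treatment is not None:
            return 0.0 if math.isinf(self.td_at_treatment) else LN2 / self.td_at_treatment
        return self.growth.lam0 * math.exp(-self.growth.decay_rate * self.treatment.t_r)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "growth": self.growth.to_dict(),
            "radio": self.radio.to_dict(),
            "treatment": self.treatment.to_dict(),
        }
        if self.td_at_treatment is not None:
            d["td_at_treatment_days"] = self.td_at_treatment
        if self.metadata:
            d["metadata"] = self.metadata
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        for key in ("label", "growth", "radio", "treatment"):
            if key not in d:
                raise ValueError(f"case config missing required key {key!r}")
        override = d.get("td_at_treatment_days")
        return cls(
            label=str(d["label"]),
            growth=GrowthParams.from_dict(d["growth"]),
            radio=RadiobiologyConstants.from_dict(d["radio"]),
            treatment=TreatmentSpec.from_dict(d["treatment"]),
            td_at_treatment=float(override) if override is not None else None,
            metadata=dict(d.get("metadata", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CaseConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Trajectory:
    """Simulated time series of the compartment volumes and growth rate."""

    times: np.ndarray
    v_t: np.ndarray
    v_nd: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "v_t", "v_nd", "lam"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if any(getattr(self, k).size != n for k in ("v_t", "v_nd", "lam")):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.v_t < 0) or np.any(self.v_nd < 0):
            raise ValueError("volumes must be nonnegative")

    @property
    def v_total(self) -> np.ndarray:
        return self.v_t + self.v_nd

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_days": self.times,
                "v_t_cm3": self.v_t,
                "v_nd_cm3": self.v_nd,
                "lambda_per_day": self.lam,
                "v_total_cm3": self.v_total,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def phase2_closed_form(
    v_t_at_tr: float,
    lam_r: float,
    p: float,
    g: float,
    eta: float,
    dt,
):
    """Exact solution of the constant-coefficient effect-window ODEs.

    With a = lam_r * p - g:

        v_t(dt)  = v_t_at_tr * exp(a dt)
        v_nd(dt) = g * v_t_at_tr * (exp(a dt) - exp(-eta dt)) / (a + eta)

    and the removable-singularity limit g * v_t_at_tr * dt * exp(-eta dt)
    when a + eta is numerically zero.  ``dt`` may be a scalar or array.
    """
    dt = np.asarray(dt, dtype=float)
    a = lam_r * p - g
    v_t = v_t_at_tr * np.exp(a * dt)
    denom = a + eta
    if abs(denom) < 1e-12 * max(abs(a), eta, 1e-30):
        v_nd = g * v_t_at_tr * dt * np.exp(-eta * dt)
    else:
        v_nd = g * v_t_at_tr * (np.exp(a * dt) - np.exp(-eta * dt)) / denom
    if dt.ndim == 0:
        return float(v_t), float(v_nd)
    return v_t, v_nd


def _effect_coefficients(config: CaseConfig):
    """(lambda_R, p, g, eta_cl) in force during the effect window."""
    lam_r = config.lambda_r()
    p = division_probability(config.treatment.dose, config.radio)
    g = death_rate(config.treatment.dose, config.radio)
    return lam_r, p, g, config.treatment.eta_cl


def _closed_form_components(config: CaseConfig, times: np.ndarray):
    """Vectorized closed-form (v_t, v_nd, lam) on an arbitrary grid."""
    gp = config.growth
    tr = config.treatment
    lam0, k = gp.lam0, gp.decay_rate

    if tr.dose == 0.0:
        # no radiation effect: plain Gompertz throughout
        expo = log_growth_integral(times, lam0, k)
        v_t = gp.v0 * np.exp(expo)
        return v_t, np.zeros_like(v_t), lam0 * np.exp(-k * times)

    t_r = tr.t_r
    t_end_eff = t_r + tr.tau_rad
    lam_r, p, g, eta = _effect_coefficients(config)
    a = lam_r * p - g

    v_t = np.empty_like(times)
    v_nd = np.zeros_like(times)
    lam = np.empty_like(times)

    pre = times < t_r
    mid = (times >= t_r) & (times < t_end_eff)
    post = times >= t_end_eff

    # phase 1: Gompertz growth from v0
    v_t[pre] = gp.v0 * np.exp(log_growth_integral(times[pre], lam0, k))
    lam[pre] = lam0 * np.exp(-k * times[pre])

    v_t_tr = gp.v0 * math.exp(log_growth_integral(t_r, lam0, k))

    # phase 2: frozen growth rate, constant-coefficient kill dynamics
    if np.any(mid):
        vt2, vnd2 = phase2_closed_form(v_t_tr, lam_r, p, g, eta, times[mid] - t_r)
        v_t[mid] = vt2
        v_nd[mid] = vnd2
    lam[mid] = lam_r

    # phase 3: growth-rate decay resumes from lambda_R; V_ND clears
    if np.any(post):
        vt_e, vnd_e = phase2_closed_form(v_t_tr, lam_r, p, g, eta, tr.tau_rad)
        s = times[post] - t_end_eff
        v_t[post] = vt_e * np.exp(log_growth_integral(s, lam_r, k))
        v_nd[post] = vnd_e * np.exp(-eta * s)
        lam[post] = lam_r * np.exp(-k * s)

    return v_t, v_nd, lam


def _validate_times(config: CaseConfig, times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if config.treatment.dose > 0 and config.treatment.t_r > times[-1]:
        raise ValueError(
            f"irradiation day t_r = {config.treatment.t_r} lies outside "
            f"the simulated span [0, {times[-1]}]"
        )
    return times


def simulate(config: CaseConfig, times) -> Trajectory:
    """Closed-form piecewise simulation of the proposed model (default engine)."""
    times = _validate_times(config, times)
    v_t, v_nd, lam = _closed_form_components(config, times)
    return Trajectory(times=times, v_t=v_t, v_nd=v_nd, lam=lam)


def simulate_standard_model(config: CaseConfig, times) -> Trajectory:
    """Instantaneous-kill comparator.

    At t_R the dividing volume jumps to S(D) V_T(t-) and the complement
    (1 - S) V_T(t-) appears in V_ND, which then clears at eta_cl; the
    growth-rate decay is never frozen.  V_total is conserved across the
    jump.  Values at exactly t_R are post-jump (right-continuous).
    """
    times = _validate_times(config, times)
    gp = config.growth
    tr = config.treatment
    lam0, k = gp.lam0, gp.decay_rate

    expo = log_growth_integral(times, lam0, k)
    v_unirr = gp.v0 * np.exp(expo)
    lam = lam0 * np.exp(-k * times)

    if tr.dose == 0.0:
        return Trajectory(times=times, v_t=v_unirr, v_nd=np.zeros_like(v_unirr), lam=lam)

    s_frac = lq_survival(tr.dose, config.radio)
    v_t_tr = gp.v0 * math.exp(log_growth_integral(tr.t_r, lam0, k))
    eta = tr.eta_cl

    post = times >= tr.t_r
    v_t = np.where(post, s_frac * v_unirr, v_unirr)
    v_nd = np.where(
        post, (1.0 - s_frac) * v_t_tr * np.exp(-eta * np.maximum(times - tr.t_r, 0.0)), 0.0
    )
    return Trajectory(times=times, v_t=v_t, v_nd=v_nd, lam=lam)


def integrate_numeric(
    config: CaseConfig,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-16,
    method: str = "LSODA",
) -> Trajectory:
    """Stiff-integrator cross-check of `simulate`.

    Solves the piecewise ODE system phase by phase (exact event handling:
    the integration is restarted at t_R and t_R + tau_rad) and evaluates
    the solution on the requested grid.  Same contract as `simulate`; the
    two engines agree to solver tolerance.
    """
    times = _validate_times(config, times)
    gp = config.growth
    tr = config.treatment
    lam0, k = gp.lam0, gp.decay_rate

    def solve_segment(rhs, t0, t1, y0, t_eval):
        """Integrate rhs over [t0, t1]; return (states at t_eval, state at t1)."""
        t_eval = np.asarray(t_eval, dtype=float)
        if t1 <= t0:
            return np.empty((len(y0), 0)), np.asarray(y0, dtype=float)
        appended = not (t_eval.size and t_eval[-1] == t1)
        eval_full = np.append(t_eval, t1) if appended else t_eval
        sol = solve_ivp(
            rhs, (t0, t1), y0, method=method, rtol=rtol, atol=atol, t_eval=eval_full
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed on [{t0}, {t1}] for case "
                f"{config.label!r}: {sol.message}"
            )
        y_end = sol.y[:, -1].copy()
        ys = sol.y[:, : t_eval.size] if appended else sol.y
        return ys, y_end

    def growth_rhs(t, y):
        v_t, v_nd, lam = y
        return [lam * v_t, -config.treatment.eta_cl * v_nd, -k * lam]

    if tr.dose == 0.0:
        # single phase, no freeze (matches the closed-form convention)
        out = np.empty((3, times.size))
        y = [gp.v0, 0.0, lam0]
        t0 = 0.0
        if times[0] == 0.0:
            out[:, 0] = y
            eval_mask = np.arange(times.size) > 0
        else:
            eval_mask = np.ones(times.size, dtype=bool)
        ys, _ = solve_segment(growth_rhs, t0, times[-1], y, times[eval_mask])
        out[:, eval_mask] = ys
        return Trajectory(times=times, v_t=out[0], v_nd=out[1], lam=out[2])

    lam_r, p, g, eta = _effect_coefficients(config)

    def effect_rhs(t, y):
        v_t, v_nd = y
        return [(lam_r * p - g) * v_t, g * v_t - eta * v_nd]

    def post_rhs(t, y):
        v_t, v_nd, lam = y
        return [lam * v_t, -eta * v_nd, -k * lam]

    t_r, t_e = tr.t_r, tr.t_r + tr.tau_rad
    out = np.empty((3, times.size))
    done = np.zeros(times.size, dtype=bool)

    # phase 1: [0, t_r)
    m1 = times < t_r
    y = np.array([gp.v0, 0.0, lam0])
    idx = np.flatnonzero(m1)
    if idx.size and times[idx[0]] == 0.0:
        out[:, idx[0]] = y
        idx = idx[1:]
    done[m1] = True
    ys, y = solve_segment(growth_rhs, 0.0, t_r, y, times[idx])
    out[:, idx] = ys
    # freeze / override the growth rate at t_R
    y2 = y[:2]

    # phase 2: [t_r, t_e)
    m2 = (times >= t_r) & (times < t_e) & ~done
    idx = np.flatnonzero(m2)
    if idx.size and times[idx[0]] == t_r:
        out[:2, idx[0]] = y2
        out[2, idx[0]] = lam_r
        idx = idx[1:]
    done[m2] = True
    ys, y2 = solve_segment(effect_rhs, t_r, t_e, y2, times[idx])
    out[:2, idx] = ys
    out[2, idx] = lam_r
    y = np.array([y2[0], y2[1], lam_r])

    # phase 3: [t_e, end]
    m3 = ~done
    if np.any(m3):
        seg = times[m3]
        idx = np.flatnonzero(m3)
        if seg[0] == t_e:
            out[:, idx[0]] = y
            seg_eval, idx_eval = seg[1:], idx[1:]
        else:
            seg_eval, idx_eval = seg, idx
        if len(seg_eval):
            ys, _ = solve_segment(post_rhs, t_e, seg[-1], y, seg_eval)
            out[:, idx_eval] = ys

    return Trajectory(times=times, v_t=out[0], v_nd=out[1], lam=out[2])
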