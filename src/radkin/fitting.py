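"""Least-squares parameter estimation and model scoring.

The fit target is the observed total-volume series.  Two residual
conventions coexist and are never conflated:

* the optimizer minimizes the *absolute* residual sum of squares
  sum_i (y_i - yhat_i)^2 (units cm^6);
* model quality is scored by the *relative* mean square of differences
  MSD = (1/N) sum_n ((yhat_n - Y_n)/Y_n)^2 (dimensionless), and
  AIC = N ln(MSD) + 2k.

The optimizer is bounded simulated annealing with geometric cooling and
Gaussian proposals reflected at the bounds; the seed is a required
argument and the result is deterministic given it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .simulator import CaseConfig, GrowthParams, TreatmentSpec, simulate

__all__ = [
    "VolumeSeries",
    "FitSpec",
    "FitResult",
    "ModelScore",
    "REFERENCE_BOUNDS",
    "residual_ss",
    "fit_simulated_annealing",
    "msd",
    "aic",
]

#: Feasible domain used for the reference annealing benchmark:
#: alpha in (0.01, 0.2) 1/Gy, theta in (0, 1), Td(0) in (0.5, 15) days,
#: T_cl in (1, 50) days.
REFERENCE_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 0.2),
    "theta": (0.0, 1.0),
    "td0": (0.5, 15.0),
    "t_cl": (1.0, 50.0),
}

_FITTABLE = ("alpha", "theta", "td0", "t_cl")


@dataclass(frozen=True)
class VolumeSeries:
    """Observed (t_i, y_i) volume pairs with optional uncertainty."""

    times: np.ndarray
    volumes: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=float))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if self.volumes.shape != self.times.shape:
            raise ValueError("times and volumes must have equal length")
        if self.sigma is not None and self.sigma.shape != self.times.shape:
            raise ValueError("sigma must match the series length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be > 0")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        import pandas as pd

        d = {"t_days": self.times, "volume_cm3": self.volumes}
        if self.sigma is not None:
            d["sigma_cm3"] = self.sigma
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VolumeSeries":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("t_days", "volume_cm3"):
            if col not in df.columns:
                raise ValueError(f"series CSV missing required column {col!r}")
        sigma = df["sigma_cm3"].to_numpy() if "sigma_cm3" in df.columns else None
        return cls(
            times=df["t_days"].to_numpy(),
            volumes=df["volume_cm3"].to_numpy(),
            sigma=sigma,
        )


@dataclass(frozen=True)
class FitSpec:
    """Annealing configuration: bounds, iteration budget, seed, fixed params."""

    bounds: Mapping[str, tuple[float, float]]
    steps: int = 100_000
    seed: int = 0
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("bounds must be nonempty")
        for name, (lo, hi) in self.bounds.items():
            if name not in _FITTABLE:
                raise ValueError(f"unknown parameter {name!r}; fittable: {_FITTABLE}")
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name!r}: ({lo}, {hi})")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in _FITTABLE if n in self.bounds and n not in self.fixed)


@dataclass(frozen=True)
class FitResult:
    """Best parameters found, their residual sum of squares, and provenance."""

    best_params: dict
    rss: float
    trace: list
    n_evals: int
    seed: int
    bounds: dict

    def to_dict(self) -> dict:
        return {
            "best_params": self.best_params,
            "rss": self.rss,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "trace_length": len(self.trace),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class ModelScore:
    """(MSD, AIC, N, k) bundle for comparing fitted models."""

    msd: float
    aic: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.msd < 0:
            raise ValueError("msd must be >= 0")


def _apply_params(config: CaseConfig, params: Mapping[str, float]) -> CaseConfig:
    """Return a copy of ``config`` with fittable parameters replaced."""
    unknown = set(params) - set(_FITTABLE)
    if unknown:
        raise ValueError(f"unknown fit parameters: {sorted(unknown)}")
    growth = config.growth
    if "theta" in params or "td0" in params:
        growth = GrowthParams(
            v0=growth.v0,
            td0=float(params.get("td0", growth.td0)),
            theta=float(params.get("theta", growth.theta)),
        )
    radio = config.radio
    if "alpha" in params:
        from .radiobiology import RadiobiologyConstants

        radio = RadiobiologyConstants(
            alpha=float(params["alpha"]),
            alpha_beta=radio.alpha_beta,
            t_star=radio.t_star,
            t_m=radio.t_m,
        )
    treatment = config.treatment
    if "t_cl" in params:
        treatment = TreatmentSpec(
            dose=treatment.dose,
            t_r=treatment.t_r,
            tau_rad=treatment.tau_rad,
            t_cl=float(params["t_cl"]),
        )
    return CaseConfig(
        label=config.label,
        growth=growth,
        radio=radio,
        treatment=treatment,
        td_at_treatment=config.td_at_treatment,
        metadata=config.metadata,
    )


def predict_volumes(
    params: Mapping[str, float], series_times, config_template: CaseConfig
) -> np.ndarray:
    """Model-predicted total volumes at the observation times."""
    config = _apply_params(config_template, params)
    traj = simulate(config, np.asarray(series_times, dtype=float))
    return traj.v_total


def residual_ss(
    params: Mapping[str, float], series: VolumeSeries, config_template: CaseConfig
) -> float:
    """Absolute residual sum of squares sum_i (y_i - yhat_i)^2, cm^6."""
    try:
        yhat = predict_volumes(params, series.times, config_template)
    except Exception as exc:
        raise RuntimeError(f"simulation failed for params {dict(params)}: {exc}") from exc
    return float(np.sum((series.volumes - yhat) ** 2))


def _make_objective(series: VolumeSeries, config_template: CaseConfig, names, fixed):
    """Closure evaluating the rss for a free-parameter vector (fast path).

    Inlines the closed-form piecewise solution with plain scalars so the
    annealer is not paying dataclass-validation costs on every step.
    """
    from .growth import LN2

    t = series.times
    y = series.volumes
    gp = config_template.growth
    rc = config_template.radio
    tr = config_template.treatment
    base = {
        "alpha": rc.alpha,
        "theta": gp.theta,
        "td0": gp.td0,
        "t_cl": tr.t_cl,
    }
    base.update(fixed)
    v0 = gp.v0
    dose = tr.dose
    t_r = tr.t_r
    tau = tr.tau_rad
    ab = rc.alpha_beta
    tstar = rc.t_star
    tm = rc.t_m
    td_override = config_template.td_at_treatment

    pre = t < t_r
    mid = (t >= t_r) & (t < t_r + tau)
    post = t >= t_r + tau
    t_pre = t[pre]
    dt_mid = t[mid] - t_r
    s_post = t[post] - t_r - tau
    yhat = np.empty_like(y)

    def objective(x) -> float:
        p = dict(base)
        for name, val in zip(names, x):
            p[name] = val
        lam0 = LN2 / p["td0"]
        k = (1.0 - p["theta"]) * lam0

        def gomp_expo(tt):
            return lam0 * tt if k == 0.0 else lam0 / k * (-np.expm1(-k * tt))

        if dose == 0.0:
            yhat_all = v0 * np.exp(gomp_expo(t))
            return float(np.sum((y - yhat_all) ** 2))

        chi = p["alpha"] * dose * (1.0 + dose / ab)
        prob = max(0.0, 1.0 - tstar / (3.0 * tm) * chi)
        g = chi / (3.0 * tm)
        eta = 0.0 if math.isinf(p["t_cl"]) else LN2 / p["t_cl"]
        if td_override is not None:
            lam_r = 0.0 if math.isinf(td_override) else LN2 / td_override
        else:
            lam_r = lam0 * math.exp(-k * t_r)
        a = lam_r * prob - g

        yhat[pre] = v0 * np.exp(gomp_expo(t_pre))
        v_t_tr = v0 * math.exp(gomp_expo(t_r))
        denom = a + eta
        degenerate = abs(denom) < 1e-12 * max(abs(a), eta, 1e-30)
        if mid.any():
            e_a = np.exp(a * dt_mid)
            if degenerate:
                vnd = g * v_t_tr * dt_mid * np.exp(-eta * dt_mid)
            else:
                vnd = g * v_t_tr * (e_a - np.exp(-eta * dt_mid)) / denom
            yhat[mid] = v_t_tr * e_a + vnd
        if post.any():
            e_a = math.exp(a * tau)
            if degenerate:
                vnd_e = g * v_t_tr * tau * math.exp(-eta * tau)
            else:
                vnd_e = g * v_t_tr * (e_a - math.exp(-eta * tau)) / denom
            vt_e = v_t_tr * e_a
            expo = lam_r * s_post if k == 0.0 else lam_r / k * (-np.expm1(-k * s_post))
            yhat[post] = vt_e * np.exp(expo) + vnd_e * np.exp(-eta * s_post)
        return float(np.sum((y - yhat) ** 2))

    return objective


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] by reflection at the bounds."""
    width = hi - lo
    if width <= 0:
        return lo
    z = (x - lo) % (2.0 * width)
    if z < 0:
        z += 2.0 * width
    return lo + (z if z <= width else 2.0 * width - z)


def fit_simulated_annealing(
    series: VolumeSeries, spec: FitSpec, config_template: CaseConfig
) -> FitResult:
    """Bounded simulated annealing minimizing the absolute rss.

    Geometric cooling T_j = T0 * c**j with c set so the final temperature
    is 1e-8 * T0 after ``spec.steps`` steps; Gaussian proposals with
    per-parameter scale 5% of the bound width, multiplied by
    (T_j/T0)^(1/4) so the walk contracts as the system cools, reflected
    at the bounds.  T0 is the median objective over 64 seeded uniform
    draws from the bounds, which makes the schedule scale-free and
    reproducible.  The best state ever visited is returned, never a
    worse accepted one.
    """
    names = spec.free_names
    if not names:
        raise ValueError("no free parameters: bounds minus fixed is empty")
    if len(series) < len(names):
        raise ValueError(
            f"under-determined fit: {len(series)} points for {len(names)} free parameters"
        )
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    scale = 0.05 * (hi - lo)
    rng = np.random.default_rng(spec.seed)
    objective = _make_objective(series, config_template, names, dict(spec.fixed))

    n_evals = 0

    def evaluate(x) -> float:
        nonlocal n_evals
        n_evals += 1
        val = objective(x)
        return val if math.isfinite(val) else math.inf

    # temperature scale from the objective landscape, not from one point
    probes = rng.uniform(lo, hi, size=(64, len(names)))
    probe_vals = np.array([evaluate(p) for p in probes])
    finite = probe_vals[np.isfinite(probe_vals)]
    t0 = float(np.median(finite)) if finite.size else 1.0
    t0 = max(t0, 1e-12)
    cool = (1e-8) ** (1.0 / spec.steps)

    x = rng.uniform(lo, hi)
    fx = evaluate(x)
    best_x, best_f = x.copy(), fx
    trace: list = [(0, tuple(x), fx)]  # accepted-state history
    temp = t0
    for j in range(spec.steps):
        contraction = max(temp / t0, 1e-12) ** 0.25
        prop = x + contraction * scale * rng.standard_normal(len(names))
        prop = np.array([_reflect(v, l, h) for v, l, h in zip(prop, lo, hi)])
        fp = evaluate(prop)
        delta = fp - fx
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            x, fx = prop, fp
            trace.append((j + 1, tuple(x), fx))
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        temp *= cool

    best_params = dict(spec.fixed)
    best_params.update(dict(zip(names, best_x)))
    return FitResult(
        best_params={k: float(v) for k, v in best_params.items()},
        rss=float(best_f),
        trace=trace,
        n_evals=n_evals,
        seed=spec.seed,
        bounds={n: tuple(spec.bounds[n]) for n in names},
    )


def msd(observed: VolumeSeries, predicted: Sequence[float]) -> float:
    """Mean square of relative differences (1/N) sum ((yhat - Y)/Y)^2."""
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != observed.volumes.shape:
        raise ValueError("predicted must match the observed series length")
    if np.any(observed.volumes == 0):
        raise ValueError("observed volumes must be nonzero")
    rel = (predicted - observed.volumes) / observed.volumes
    return float(np.mean(rel**2))


def aic(score_msd: float, n: int, k: int = 5) -> float:
    """Akaike information criterion N ln(MSD) + 2k for an MSD-scored fit."""
    if score_msd <= 0:
        raise ValueError(f"msd must be > 0 for AIC, got {score_msd}")
    return n * math.log(score_msd) + 2 * k
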