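"""Clinically oriented trajectory summaries and predictor-screening regression.

R_40 is the response endpoint: the total model volume 40 days after
irradiation divided by the volume at irradiation.  The post-effect
survival metric is the dividing-cell volume ratio across the active
radiation-effect window.  Predictor screening regresses the endpoint on a
candidate variable with a second-order polynomial and reports the overall
F-test p-value (a coefficient-wise t-test alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Trajectory

__all__ = [
    "r40",
    "survival_after_effect",
    "quadratic_regression_pvalue",
    "RegressionPValues",
]


def _log_interp(traj_times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Interpolate a positive series linearly in log-space at time t."""
    if t < traj_times[0] or t > traj_times[-1]:
        raise ValueError(
            f"time {t} outside trajectory span [{traj_times[0]}, {traj_times[-1]}]"
        )
    if np.any(values <= 0):
        # log-linear undefined; fall back to plain linear interpolation
        return float(np.interp(t, traj_times, values))
    return float(np.exp(np.interp(t, traj_times, np.log(values))))


def r40(traj: Trajectory, t_r: float, horizon: float = 40.0) -> float:
    """Volume ratio V_total(t_r + horizon) / V_total(t_r).

    Off-grid times are interpolated linearly in log-volume, matching the
    exponential structure of the model.  Invariant to uniform rescaling
    of all volumes.

    Raises
    ------
    ValueError
        If the trajectory does not cover [t_r, t_r + horizon].
    """
    v_total = traj.v_total
    v_at = _log_interp(traj.times, v_total, t_r)
    v_later = _log_interp(traj.times, v_total, t_r + horizon)
    return v_later / v_at


def survival_after_effect(traj: Trajectory, t_r: float, tau_rad: float) -> float:
    """Dividing-cell ratio V_T(t_r + tau_rad) / V_T(t_r) over the effect window.

    Defined as exactly 1.0 when no radiation effect occurred (V_ND is
    identically zero, i.e. dose 0): with no transition to the
    non-dividing compartment every dividing cell survives.
    """
    if not np.any(traj.v_nd > 0):
        return 1.0
    vt_start = _log_interp(traj.times, traj.v_t, t_r)
    vt_end = _log_interp(traj.times, traj.v_t, t_r + tau_rad)
    return vt_end / vt_start


@dataclass(frozen=True)
class RegressionPValues:
    """P-values from the predictor-screening polynomial regression."""

    quadratic: float
    linear: float


def quadratic_regression_pvalue(
    x, y, test: str = "ftest"
) -> RegressionPValues:
    """Screen predictor ``x`` against response ``y`` with polynomial OLS.

    Fits y = b0 + b1 x + b2 x^2 by ordinary least squares and returns the
    overall F-test p-value of that model against the intercept-only model,
    together with the same quantity for the linear-only fit
    y = b0 + b1 x.

    Parameters
    ----------
    x, y : array-like
        Predictor and response values, >= 4 points, x not all equal.
    test : {"ftest", "ttest"}
        "ftest" (default): overall-regression F-test p-value.
        "ttest": p-value of the highest-order coefficient's t-test.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError(f"need >= 4 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal (rank-deficient design)")
    if test not in ("ftest", "ttest"):
        raise ValueError(f"test must be 'ftest' or 'ttest', got {test!r}")

    # a perfectly constant response has no explainable variance: the F
    # ratio is 0/0; report 1.0 (nothing to explain) without fitting
    if np.ptp(y) == 0:
        return RegressionPValues(quadratic=1.0, linear=1.0)

    design_quad = sm.add_constant(np.column_stack([x, x**2]))
    design_lin = sm.add_constant(x)
    if np.linalg.matrix_rank(design_quad) < design_quad.shape[1]:
        raise ValueError("rank-deficient quadratic design (too few distinct x)")

    fit_quad = sm.OLS(y, design_quad).fit()
    fit_lin = sm.OLS(y, design_lin).fit()

    if test == "ftest":
        p_quad = float(fit_quad.f_pvalue)
        p_lin = float(fit_lin.f_pvalue)
    else:
        p_quad = float(fit_quad.pvalues[-1])
        p_lin = float(fit_lin.pvalues[-1])

    return RegressionPValues(quadratic=p_quad, linear=p_lin)


def case_report(traj: Trajectory, t_r: float, tau_rad: float) -> dict:
    """Per-case summary: R_40, post-window survival, state at treatment."""
    from .growth import LN2

    v_at = _log_interp(traj.times, traj.v_total, t_r)
    lam_at = float(np.interp(t_r, traj.times, traj.lam))
    return {
        "r40": r40(traj, t_r),
        "survival_after_effect": survival_after_effect(traj, t_r, tau_rad),
        "v_at_treatment_cm3": v_at,
        "td_at_treatment_days": LN2 / lam_at if lam_at > 0 else float("inf"),
    }
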