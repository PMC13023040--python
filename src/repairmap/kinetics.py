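"""Kinetic modeling of Cas9 cleavage and double-strand-break repair.

The editing time course is modeled in two stages.  A logistic curve fit to
the observed edited fraction estimates the maximal editable fraction
``f_max`` — the asymptote that accounts for cells that are never
transfected or never cut.  Within that editable fraction a three-state
linear ODE describes the flow from intact target (u) through the cut
intermediate (b) to the indel-bearing product (e)::

    du/dt = -k_cut * u + k_perf * b
    db/dt =  k_cut * u - (k_perf + k_err) * b
    de/dt =  k_err * b,          u(0) = 1, b(0) = e(0) = 0

with first-order rate constants (per hour) for cleavage (``k_cut``),
error-prone repair (``k_err``) and perfect repair (``k_perf``, returning the
cut state to intact).  The observed edited fraction is ``F(t) = f_max * e(t)``
by default: cut-but-unrepaired molecules are assumed not to amplify and so
count toward the unedited pool.  Passing ``observe_broken=True`` instead
scores the cut intermediate as edited, ``F(t) = f_max * (b(t) + e(t))``.

Because the system is linear with constant coefficients it is solved
exactly with a matrix exponential; conservation u+b+e = 1 holds to machine
precision at every time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

DEFAULT_TIME_GRID_H = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0, 60.0, 72.0)

__all__ = [
    "DEFAULT_TIME_GRID_H",
    "TimeCourse",
    "KineticParams",
    "LogisticFit",
    "KineticFit",
    "pattern_trajectories",
    "fit_logistic",
    "simulate_repair_ode",
    "fit_repair_ode",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants (h^-1) and the maximal editable fraction."""

    k_cut: float
    k_err: float
    k_perf: float
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_cut, self.k_err, self.k_perf) < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0 < self.f_max <= 1):
            raise ValueError("f_max must lie in (0, 1]")


@dataclass
class TimeCourse:
    """Editing fractions (and optionally per-pattern counts) over time."""

    times: np.ndarray
    edited_fraction: np.ndarray
    pattern_counts: pd.DataFrame | None = None  # rows: times, cols: patterns
    total_reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.edited_fraction = np.asarray(self.edited_fraction, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.edited_fraction < 0) | (self.edited_fraction > 1)):
            raise ValueError("edited fractions must lie in [0, 1]")


@dataclass
class LogisticFit:
    f_max: float
    rate: float
    midpoint: float
    r_squared: float
    converged: bool
    unreliable: bool = False


@dataclass
class KineticFit:
    params: KineticParams
    r_squared: float
    residuals: np.ndarray
    k_perf_unidentified: bool = False
    warning: str | None = None
    n_starts: int = 0


def pattern_trajectories(timecourse: TimeCourse) -> pd.DataFrame:
    """Per-time pattern proportions; rows with zero edited reads are NaN.

    Each informative row sums to 1 over the patterns present in
    ``pattern_counts``.
    """
    if timecourse.pattern_counts is None:
        raise ValueError("time course carries no pattern counts")
    counts = timecourse.pattern_counts.astype(float)
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    return props


def _logistic(t: np.ndarray, f_max: float, rate: float, t0: float) -> np.ndarray:
    return f_max / (1.0 + np.exp(-rate * (t - t0)))


def fit_logistic(
    times: np.ndarray,
    edited_fraction: np.ndarray,
) -> LogisticFit:
    """Least-squares 3-parameter logistic fit of the editing time course.

    Returns the fitted maximal editable fraction (clipped to (0, 1]),
    growth rate and midpoint.  A flat near-zero signal is flagged
    unreliable; non-convergence raises.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(edited_fraction, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 timepoints for the logistic fit")
    ymax = float(y.max())
    if ymax < 1e-6:
        return LogisticFit(f_max=1e-6, rate=0.0, midpoint=float(np.median(t)),
                           r_squared=0.0, converged=True, unreliable=True)

    def resid(theta: np.ndarray) -> np.ndarray:
        return _logistic(t, *theta) - y

    # Midpoint guess: first time the signal crosses half its maximum.
    above = np.nonzero(y >= 0.5 * ymax)[0]
    t0_guess = float(t[above[0]]) if above.size else float(np.median(t))
    x0 = np.array([min(ymax * 1.05, 1.0), 0.2, t0_guess])
    res = least_squares(
        resid, x0,
        bounds=([1e-9, 1e-6, -np.inf], [1.0, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not res.success:
        raise RuntimeError(f"logistic fit failed: {res.message}")
    f_max, rate, t0 = res.x
    ss_res = float(np.sum(res.fun ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LogisticFit(
        f_max=float(np.clip(f_max, 1e-9, 1.0)), rate=float(rate),
        midpoint=float(t0), r_squared=r2, converged=True,
        unreliable=bool(ymax < 0.01),
    )


def simulate_repair_ode(
    params: KineticParams,
    times: np.ndarray,
) -> pd.DataFrame:
    """Exact trajectories u(t), b(t), e(t) and observed F(t) = f_max*e(t).

    Solved with the matrix exponential of the constant-coefficient
    generator, so u+b+e = 1 exactly (to floating point) at every time.
    """
    t = np.asarray(times, dtype=float)
    kc, ke, kp = params.k_cut, params.k_err, params.k_perf
    gen = np.array([
        [-kc,        kp, 0.0],
        [ kc, -(kp + ke), 0.0],
        [0.0,        ke, 0.0],
    ])
    y0 = np.array([1.0, 0.0, 0.0])
    states = np.empty((t.size, 3))
    for i, ti in enumerate(t):
        states[i] = expm(gen * ti) @ y0
    df = pd.DataFrame(states, columns=["u", "b", "e"], index=pd.Index(t, name="time_h"))
    df["F"] = params.f_max * df["e"]
    return df


def _edited_signal(k: np.ndarray, t: np.ndarray, f_max: float,
                   observe_broken: bool) -> np.ndarray:
    params = KineticParams(k_cut=k[0], k_err=k[1], k_perf=k[2], f_max=f_max)
    traj = simulate_repair_ode(params, t)
    e = traj["e"].to_numpy()
    if observe_broken:
        e = e + traj["b"].to_numpy()
    return f_max * e


# Multi-start grids (h^-1): one decade spacing for the fast rates, and a
# wide low range for perfect repair, which the data constrain only weakly.
_KCUT_STARTS = np.logspace(-3, 0, 3)
_KERR_STARTS = np.logspace(-3, 0, 3)
_KPERF_STARTS = np.logspace(-9, -3, 2)


def fit_repair_ode(
    timecourse: TimeCourse,
    f_max: float | None = None,
    weights: np.ndarray | None = None,
    observe_broken: bool = False,
) -> KineticFit:
    """Least-squares fit of (k_cut, k_err, k_perf) to an editing time course.

    ``f_max`` is fixed from the logistic stage (estimated here if not
    supplied).  The sum of squared differences between observed and modeled
    edited fractions is minimized from a log-spaced multi-start grid with
    non-negativity bounds; optional ``weights`` multiply the residuals
    (e.g. inverse binomial SDs).

    The perfect-repair rate is flagged ``k_perf_unidentified`` when its
    relative standard error from the local curvature exceeds 1 (or the
    curvature is singular) — expected whenever k_perf << k_err.

    .. note::
       When only the indel product e(t) is observed, the model is exactly
       invariant under exchanging k_cut and k_err: e(t) depends on the
       rates only through k_cut + k_err (plus k_perf) and k_cut * k_err.
       The pair is therefore identifiable only up to order, and the fit
       labels the larger rate as k_cut — cleavage outpacing error-prone
       end joining, the regime time-course data consistently show.  With
       ``observe_broken=True`` the intact fraction enters the signal and
       the ordering becomes identifiable from the data themselves.
    """
    t = timecourse.times
    y = timecourse.edited_fraction
    informative = t > 0
    if informative.sum() < 4:
        raise ValueError("need at least 4 informative timepoints")
    if f_max is None:
        f_max = fit_logistic(t, y).f_max
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def resid(logk: np.ndarray) -> np.ndarray:
        # Clip so optimizer excursions cannot overflow the exponential.
        k = np.exp(np.clip(logk, -60.0, 8.0))
        return w * (_edited_signal(k, t, f_max, observe_broken) - y)

    best = None
    n_starts = 0
    for kc0 in _KCUT_STARTS:
        for ke0 in _KERR_STARTS:
            for kp0 in _KPERF_STARTS:
                n_starts += 1
                x0 = np.log([kc0, ke0, kp0])
                try:
                    res = least_squares(resid, x0, method="lm",
                                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                        max_nfev=2000)
                except Exception:
                    continue
                if best is None or res.cost < best.cost - 1e-15:
                    best = res
    if best is None:
        raise RuntimeError("ODE fit failed from every start")
    k = np.exp(np.clip(best.x, -60.0, 8.0))
    if not observe_broken and k[0] < k[1]:
        # e(t) is symmetric under k_cut <-> k_err; label the faster rate
        # as cleavage (see the docstring note).
        k[0], k[1] = k[1], k[0]
    model = _edited_signal(k, t, f_max, observe_broken)
    residuals = y - model
    ss_res = float(np.sum((w * residuals) ** 2))
    ss_tot = float(np.sum((w * (y - y.mean())) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # Curvature-based identifiability check on log-parameters.
    k_perf_unidentified = True
    try:
        J = best.jac
        col_norms = np.linalg.norm(J, axis=0)
        if col_norms[2] <= 1e-6 * max(col_norms.max(), 1e-30):
            # The objective is locally flat in log k_perf.
            k_perf_unidentified = True
        else:
            dof = max(t.size - 3, 1)
            s2 = ss_res / dof
            cov = np.linalg.pinv(J.T @ J) * max(s2, 1e-30)
            rel_se_logkp = float(np.sqrt(max(cov[2, 2], 0.0)))
            # SE on log k_perf > 1 means >e-fold uncertainty.
            k_perf_unidentified = (not np.isfinite(rel_se_logkp)
                                   or rel_se_logkp > 1.0)
    except Exception:
        pass

    warning = None
    if r2 < 0.5:
        warning = "poor fit: noise dominates the time course"
        warnings.warn(warning, stacklevel=2)
    params = KineticParams(k_cut=float(k[0]), k_err=float(k[1]),
                           k_perf=float(k[2]), f_max=float(f_max))
    return KineticFit(params=params, r_squared=r2, residuals=residuals,
                      k_perf_unidentified=k_perf_unidentified,
                      warning=warning, n_starts=n_starts)
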