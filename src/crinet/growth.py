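"""Coupled regulatory interaction (CRI) growth model.

Two sigmoid traits -- here stem height H and stem diameter D -- grow under a
Lotka-Volterra-type system that splits each trait's growth rate into a
self-regulated logistic part and an interactive part driven by the other
trait:

    dH/dt = alpha_H (1 - H/K_H) H + alpha_H beta_HD H D
    dD/dt = alpha_D (1 - D/K_D) D + alpha_D beta_DH D H

``alpha`` is the intrinsic growth rate (1/year), ``K`` the asymptote in trait
units, and the ``beta`` coefficients measure how strongly the co-existing
trait promotes (beta > 0) or inhibits (beta < 0) growth.  The sign pattern of
(beta_HD, beta_DH) defines the interaction strategy: neutral (both zero),
cooperative (at least one positive, none negative) or antagonistic (any
negative).

The module integrates the system with fixed-step RK4, decomposes trajectories
into independent and interactive components, fits the six parameters to
observed bivariate trajectories by multi-start Nelder-Mead least squares, and
fits the classical single-trait growth equations (Gompertz, Korf, Richards,
logistic) for model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._kernels import cri_rk4, nm_minimize_gls
from .errors import FitError, IntegrationError, InvalidInputError

#: absolute threshold below which a beta coefficient counts as exactly zero
#: when classifying the interaction strategy
ZERO_BETA_TOL = 1e-8

#: default internal RK4 step in years
DEFAULT_RK4_STEP = 0.01

STRATEGY_NEUTRAL = "neutral"
STRATEGY_COOPERATIVE = "cooperative"
STRATEGY_ANTAGONISTIC = "antagonistic"

CLASSICAL_MODELS = ("gompertz", "korf", "richards", "logistic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CRIParams:
    """The six parameters of the coupled growth system.

    alpha_h, alpha_d : intrinsic growth rates (1/time), > 0
    k_h, k_d         : asymptotic trait values, > 0
    beta_hd          : effect of diameter on height growth (per diameter unit)
    beta_dh          : effect of height on diameter growth (per height unit)
    """

    alpha_h: float
    k_h: float
    beta_hd: float
    alpha_d: float
    k_d: float
    beta_dh: float

    def __post_init__(self):
        vals = (self.alpha_h, self.k_h, self.beta_hd,
                self.alpha_d, self.k_d, self.beta_dh)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError("CRIParams must be finite")
        if self.alpha_h <= 0 or self.alpha_d <= 0:
            raise InvalidInputError("growth rates alpha must be positive")
        if self.k_h <= 0 or self.k_d <= 0:
            raise InvalidInputError("asymptotes K must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha_h, self.k_h, self.beta_hd,
                         self.alpha_d, self.k_d, self.beta_dh])

    @classmethod
    def from_array(cls, theta) -> "CRIParams":
        t = np.asarray(theta, dtype=float)
        return cls(t[0], t[1], t[2], t[3], t[4], t[5])

    def to_dict(self) -> dict:
        return {"alpha_h": self.alpha_h, "k_h": self.k_h, "beta_hd": self.beta_hd,
                "alpha_d": self.alpha_d, "k_d": self.k_d, "beta_dh": self.beta_dh}


@dataclass
class TraitState:
    """Instantaneous state of the two traits at time ``t``."""

    h: float
    d: float
    t: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.h) and math.isfinite(self.d)):
            raise InvalidInputError("trait state must be finite")
        if self.h < 0 or self.d < 0:
            raise InvalidInputError("trait values must be non-negative")


@dataclass
class Trajectory:
    """RK4 solution of the coupled system on a requested time grid."""

    times: np.ndarray
    height: np.ndarray
    diameter: np.ndarray

    def stacked(self) -> np.ndarray:
        """Stacked (height; diameter) vector of length 2T."""
        return np.concatenate([self.height, self.diameter])


@dataclass
class GrowthDecomposition:
    """Independent vs interactive derivative components along a trajectory.

    At every time point ``independent_* + interactive_*`` equals the full
    right-hand side of the growth system evaluated on the same trajectory.
    Cumulative variants are trapezoid running integrals (starting at 0).
    """

    times: np.ndarray
    independent_h: np.ndarray
    interactive_h: np.ndarray
    independent_d: np.ndarray
    interactive_d: np.ndarray
    cumulative_independent_h: np.ndarray = field(default=None)
    cumulative_interactive_h: np.ndarray = field(default=None)
    cumulative_independent_d: np.ndarray = field(default=None)
    cumulative_interactive_d: np.ndarray = field(default=None)


@dataclass
class ClassicalFit:
    """Result of fitting one growth equation to a single-trait trajectory."""

    model_name: str
    params: np.ndarray
    param_names: tuple
    r_squared: float
    residuals: np.ndarray
    aic: float
    bic: float
    degenerate: bool = False
    fitted: np.ndarray = None


@dataclass
class CRIFit:
    """Result of fitting the coupled system to a bivariate trajectory."""

    params: CRIParams
    init: TraitState
    r_squared: float
    r_squared_height: float
    r_squared_diameter: float
    residuals: np.ndarray  # stacked (height; diameter), fitted - observed
    aic: float
    bic: float
    sse: float
    n_obs: int
    converged: bool = True


# ---------------------------------------------------------------------------
# core dynamics
# ---------------------------------------------------------------------------

def cri_rhs(state: TraitState, params: CRIParams) -> tuple:
    """Right-hand side (dH/dt, dD/dt) of the coupled system at ``state``."""
    h, d = state.h, state.d
    dh = params.alpha_h * (1.0 - h / params.k_h) * h + params.alpha_h * params.beta_hd * h * d
    dd = params.alpha_d * (1.0 - d / params.k_d) * d + params.alpha_d * params.beta_dh * d * h
    return dh, dd


def integrate_cri(params: CRIParams, init: TraitState, times,
                  step: float = DEFAULT_RK4_STEP) -> Trajectory:
    """Solve the coupled system with classic fixed-step RK4.

    ``times`` must be strictly increasing; the trajectory starts exactly at
    ``init``.  Raises :class:`IntegrationError` if the state blows up.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise InvalidInputError("times must be a non-empty 1-d grid")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be strictly increasing")
    traj = cri_rk4(params.to_array(), float(init.h), float(init.d), t, float(step))
    if not np.all(np.isfinite(traj)):
        bad = int(np.argmax(~np.isfinite(traj[:, 0])))
        raise IntegrationError(
            f"integration produced non-finite state near t={t[bad]:g}", time=float(t[bad]))
    return Trajectory(times=t, height=traj[:, 0], diameter=traj[:, 1])


def decompose_growth(params: CRIParams, trajectory: Trajectory) -> GrowthDecomposition:
    """Split the derivative along ``trajectory`` into self-regulated and
    interactive components, with trapezoid running integrals of each."""
    h = np.asarray(trajectory.height, dtype=float)
    d = np.asarray(trajectory.diameter, dtype=float)
    t = np.asarray(trajectory.times, dtype=float)
    if not (h.shape == d.shape == t.shape):
        raise InvalidInputError("trajectory arrays must share one length")
    ind_h = params.alpha_h * (1.0 - h / params.k_h) * h
    int_h = params.alpha_h * params.beta_hd * h * d
    ind_d = params.alpha_d * (1.0 - d / params.k_d) * d
    int_d = params.alpha_d * params.beta_dh * d * h

    def cum(y):
        out = np.zeros_like(y)
        if y.size > 1:
            out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
        return out

    return GrowthDecomposition(
        times=t,
        independent_h=ind_h, interactive_h=int_h,
        independent_d=ind_d, interactive_d=int_d,
        cumulative_independent_h=cum(ind_h), cumulative_interactive_h=cum(int_h),
        cumulative_independent_d=cum(ind_d), cumulative_interactive_d=cum(int_d),
    )


def classify_strategy(beta_hd: float, beta_dh: float,
                      zero_tol: float = ZERO_BETA_TOL) -> str:
    """Classify the interaction strategy from the signs of the two coupling
    coefficients: both (numerically) zero -> neutral; any negative ->
    antagonistic; otherwise cooperative."""
    if not (math.isfinite(beta_hd) and math.isfinite(beta_dh)):
        raise InvalidInputError("beta coefficients must be finite")
    s1 = 0 if abs(beta_hd) < zero_tol else (1 if beta_hd > 0 else -1)
    s2 = 0 if abs(beta_dh) < zero_tol else (1 if beta_dh > 0 else -1)
    if s1 == 0 and s2 == 0:
        return STRATEGY_NEUTRAL
    if s1 < 0 or s2 < 0:
        return STRATEGY_ANTAGONISTIC
    return STRATEGY_COOPERATIVE


# ---------------------------------------------------------------------------
# fitting the coupled system
# ---------------------------------------------------------------------------

def _moment_starts(heights, diameters, times, n_starts):
    """Deterministic multi-start grid around method-of-moments guesses:
    K near 1.05x the max observation, alpha from the early log-slope,
    betas starting at zero."""
    kh0 = 1.05 * float(np.max(heights))
    kd0 = 1.05 * float(np.max(diameters))
    dt = times[1] - times[0]
    ah0 = abs(math.log(max(heights[1], 1e-9) / max(heights[0], 1e-9))) / dt
    ad0 = abs(math.log(max(diameters[1], 1e-9) / max(diameters[0], 1e-9))) / dt
    ah0 = min(max(ah0, 0.05), 3.0)
    ad0 = min(max(ad0, 0.05), 3.0)
    alpha_f = np.exp(np.linspace(-0.9, 0.9, n_starts))
    k_f = np.exp(np.linspace(0.0, 0.45, n_starts))
    starts = []
    for i in range(n_starts):
        starts.append(np.array([ah0 * alpha_f[i], kh0 * k_f[i], 0.0,
                                ad0 * alpha_f[n_starts - 1 - i], kd0 * k_f[i], 0.0]))
    return starts


def fit_cri(heights, diameters, times, init_params: CRIParams | None = None,
            n_starts: int = 10, step: float = DEFAULT_RK4_STEP,
            maxiter: int = 4000) -> CRIFit:
    """Fit the six coupled-growth parameters to one observed bivariate
    trajectory by multi-start Nelder-Mead least squares on the RK4 solution.

    Initial values H(t0), D(t0) are fixed to the first observations, so the
    free parameter count stays at six.  The objective is the residual sum of
    squares with each trait weighted by the inverse variance of its
    observations, which balances the two traits' units.
    """
    h = np.asarray(heights, dtype=float)
    d = np.asarray(diameters, dtype=float)
    t = np.asarray(times, dtype=float)
    if h.size < 6:
        raise InvalidInputError("need at least 6 time points to fit 6 parameters")
    if np.any(h <= 0) or np.any(d <= 0):
        raise InvalidInputError("trajectories must be positive")

    T = t.size
    ybar = np.concatenate([h, d])
    wh = 1.0 / max(np.var(h), 1e-12)
    wd = 1.0 / max(np.var(d), 1e-12)
    sinv = np.diag(np.concatenate([np.full(T, wh), np.full(T, wd)]))

    starts = _moment_starts(h, d, t, n_starts)
    if init_params is not None:
        starts.insert(0, init_params.to_array())

    best_x, best_f = None, np.inf
    for x0 in starts:
        x, f, _ = nm_minimize_gls(x0, ybar, sinv, t, h[0], d[0], step, maxiter, 1e-12)
        if f < best_f:
            best_x, best_f = x, f
    # polish from the best point with a fresh simplex
    for _ in range(2):
        x, f, _ = nm_minimize_gls(best_x, ybar, sinv, t, h[0], d[0], step, maxiter, 1e-14)
        if f < best_f:
            best_x, best_f = x, f

    if best_x is None or not np.isfinite(best_f) or best_f >= 1e29:
        raise FitError("CRI fit did not converge from any start", best=best_x)

    params = CRIParams.from_array(best_x)
    traj = integrate_cri(params, TraitState(h[0], d[0], t[0]), t, step=step)
    fitted = traj.stacked()
    resid = fitted - ybar
    sse_h = float(np.sum(resid[:T] ** 2))
    sse_d = float(np.sum(resid[T:] ** 2))
    sst_h = float(np.sum((h - h.mean()) ** 2))
    sst_d = float(np.sum((d - d.mean()) ** 2))
    r2_h = 1.0 - sse_h / sst_h if sst_h > 0 else 1.0
    r2_d = 1.0 - sse_d / sst_d if sst_d > 0 else 1.0
    # pooled R^2 on per-trait standardized scale
    r2 = 1.0 - (sse_h * wh + sse_d * wd) / (sst_h * wh + sst_d * wd)
    n_obs = 2 * T
    sse = sse_h + sse_d
    k = 7  # 6 parameters + error variance
    aic = n_obs * math.log(max(sse / n_obs, 1e-300)) + 2 * k
    bic = n_obs * math.log(max(sse / n_obs, 1e-300)) + k * math.log(n_obs)
    return CRIFit(params=params, init=TraitState(h[0], d[0], t[0]),
                  r_squared=r2, r_squared_height=r2_h, r_squared_diameter=r2_d,
                  residuals=resid, aic=aic, bic=bic, sse=sse, n_obs=n_obs)


# ---------------------------------------------------------------------------
# classical single-trait growth equations
# ---------------------------------------------------------------------------

def _gompertz(t, a, b, c):
    return a * np.exp(-b * np.exp(-c * t))


def _korf(t, a, b, c):
    return a * np.exp(-b * np.power(t, -c))


def _richards(t, a, b, c, m):
    base = 1.0 - b * np.exp(-c * t)
    base = np.clip(base, 1e-12, None)
    return a * np.power(base, 1.0 / (1.0 - m))


def _logistic(t, a, b, c):
    return a / (1.0 + b * np.exp(-c * t))


_CLASSICAL = {
    "gompertz": (_gompertz, ("a", "b", "c")),
    "korf": (_korf, ("a", "b", "c")),
    "richards": (_richards, ("a", "b", "c", "m")),
    "logistic": (_logistic, ("a", "b", "c")),
}


def fit_classical(model_name: str, values, times) -> ClassicalFit:
    """Least-squares fit of one classical growth equation to a single-trait
    trajectory; returns parameters, R^2, AIC/BIC for comparison with the
    coupled-system fit.  A (near-)constant trajectory is flagged degenerate
    (asymptote = the constant, rate ~ 0) rather than failed."""
    if model_name not in _CLASSICAL:
        raise InvalidInputError(
            f"unsupported model {model_name!r}; supported: {sorted(_CLASSICAL)}")
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    func, names = _CLASSICAL[model_name]

    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        fitted = np.full_like(y, y.mean())
        params = {"gompertz": [y.mean(), 0.0, 0.0], "korf": [y.mean(), 0.0, 0.0],
                  "richards": [y.mean(), 0.0, 0.0, 0.5],
                  "logistic": [y.mean(), 0.0, 0.0]}[model_name]
        return ClassicalFit(model_name=model_name, params=np.array(params),
                            param_names=names, r_squared=1.0,
                            residuals=fitted - y, aic=-np.inf, bic=-np.inf,
                            degenerate=True, fitted=fitted)

    a0 = 1.05 * float(np.max(y))
    span = t[-1] - t[0]
    p0s = {
        "gompertz": [[a0, 3.0, 2.0 / span], [a0, 5.0, 4.0 / span], [1.5 * a0, 2.0, 1.0 / span]],
        "korf": [[a0, 3.0, 1.0], [1.5 * a0, 5.0, 0.5], [a0, 2.0, 2.0]],
        "richards": [[a0, 0.9, 2.0 / span, 0.5], [a0, 0.7, 4.0 / span, -1.0],
                     [1.5 * a0, 0.95, 1.0 / span, 0.3]],
        "logistic": [[a0, 10.0, 4.0 / span], [a0, 30.0, 2.0 / span], [1.5 * a0, 5.0, 1.0 / span]],
    }[model_name]
    bounds = {
        "gompertz": ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
        "korf": ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
        "richards": ([1e-9, 1e-9, 1e-9, -10.0], [np.inf, 1.0 - 1e-9, np.inf, 0.999]),
        "logistic": ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
    }[model_name]

    best_p, best_sse = None, np.inf
    for p0 in p0s:
        try:
            popt, _ = curve_fit(func, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((func(t, *popt) - y) ** 2))
        if sse < best_sse:
            best_p, best_sse = popt, sse
    if best_p is None:
        raise FitError(f"{model_name} fit failed from all starts")

    fitted = func(t, *best_p)
    resid = fitted - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 1.0
    n = y.size
    k = len(names) + 1
    aic = n * math.log(max(best_sse / n, 1e-300)) + 2 * k
    bic = n * math.log(max(best_sse / n, 1e-300)) + k * math.log(n)
    return ClassicalFit(model_name=model_name, params=np.asarray(best_p),
                        param_names=names, r_squared=r2, residuals=resid,
                        aic=aic, bic=bic, fitted=fitted)


def logistic_closed_form(alpha: float, k: float, y0: float, times) -> np.ndarray:
    """Analytic solution of the uncoupled logistic limit, used as an oracle
    for the RK4 integrator: K y0 e^{alpha t} / (K + y0 (e^{alpha t} - 1))."""
    t = np.asarray(times, dtype=float) - np.asarray(times, dtype=float)[0]
    e = np.exp(alpha * t)
    return k * y0 * e / (k + y0 * (e - 1.0))
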