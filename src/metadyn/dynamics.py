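"""Second-order step-response model of metabolite pool transients.

A metabolite pool responding to a sudden, sustained change of an
extracellular substrate (a step of magnitude ``M`` mM) is modelled as a
second-order linear process with numerator dynamics — the classical
"two surge tanks in series" model with a zero added to capture inertia,
overshoot and inverse responses.  In the Laplace domain the deviation
``y'`` of the pool from its pre-step steady state is

    overdamped:   y'(s) = K * M * (tau_a*s + 1) / ((tau1*s + 1) * (tau2*s + 1))
    underdamped:  y'(s) = K * M * (tau_a*s + 1) / (tau**2*s**2 + 2*zeta*tau*s + 1)

with steady-state gain ``K`` (pool units per mM), numerator time constant
``tau_a`` (min, may be negative for inverse response), real time constants
``tau1 >= tau2 > 0`` (overdamped) or natural period ``tau > 0`` and damping
``0 < zeta < 1`` (underdamped).  This module provides the closed-form
time-domain step responses, descriptor extraction (settling time, damping
coefficient) and the two-stage weighted least-squares fit of observed
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelParams",
    "FitResult",
    "step_response",
    "damping_coefficient",
    "settling_time",
    "mean_fitting_error",
    "fit_metabolite",
]

OVERDAMPED = "overdamped"
UNDERDAMPED = "underdamped"

# below this relative gap tau1/tau2 are treated as a repeated root and the
# analytic confluent limit is used instead of the distinct-root formula
_REPEATED_ROOT_RTOL = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one step-response model branch.

    Overdamped parameters are stored with the ``tau1 >= tau2`` convention
    (the model is symmetric under swapping, so the constructor reorders).
    """

    scenario: str
    K: float
    tau_a: float
    tau1: float | None = None
    tau2: float | None = None
    tau: float | None = None
    zeta: float | None = None

    def __post_init__(self) -> None:
        if self.scenario == OVERDAMPED:
            if self.tau1 is None or self.tau2 is None:
                raise ValueError("overdamped params require tau1 and tau2")
            if self.tau1 <= 0 or self.tau2 <= 0:
                raise ValueError(
                    f"time constants must be positive, got tau1={self.tau1}, tau2={self.tau2}"
                )
            if self.tau1 < self.tau2:  # enforce ordering convention
                t1, t2 = self.tau2, self.tau1
                object.__setattr__(self, "tau1", t1)
                object.__setattr__(self, "tau2", t2)
        elif self.scenario == UNDERDAMPED:
            if self.tau is None or self.zeta is None:
                raise ValueError("underdamped params require tau and zeta")
            if self.tau <= 0:
                raise ValueError(f"tau must be positive, got {self.tau}")
            if not 0.0 < self.zeta < 1.0:
                raise ValueError(f"underdamped requires 0 < zeta < 1, got {self.zeta}")
        else:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def overdamped(cls, K: float, tau_a: float, tau1: float, tau2: float) -> "ModelParams":
        return cls(OVERDAMPED, K, tau_a, tau1=tau1, tau2=tau2)

    @classmethod
    def underdamped(cls, K: float, tau_a: float, tau: float, zeta: float) -> "ModelParams":
        return cls(UNDERDAMPED, K, tau_a, tau=tau, zeta=zeta)


def step_response(params: ModelParams, M: float, t) -> np.ndarray:
    """Closed-form deviation y'(t) for a step of magnitude ``M`` at t = 0.

    Times before the step (t < 0) return zero deviation.  The response
    satisfies y'(0) = 0 and y'(t) -> K*M as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    tp = np.where(t < 0.0, 0.0, t)
    KM = params.K * M
    if params.scenario == OVERDAMPED:
        t1, t2, ta = params.tau1, params.tau2, params.tau_a
        if abs(t1 - t2) < _REPEATED_ROOT_RTOL * t1:
            # confluent (repeated-root) limit tau1 = tau2 = tau
            tau = 0.5 * (t1 + t2)
            x = tp / tau
            core = 1.0 - np.exp(-x) * (1.0 + (1.0 - ta / tau) * x)
        else:
            with np.errstate(over="ignore", invalid="ignore"):
                c1 = (t1 - ta) / (t2 - t1)
                c2 = (t2 - ta) / (t1 - t2)
                core = 1.0 + c1 * np.exp(-tp / t1) + c2 * np.exp(-tp / t2)
    else:
        tau, z, ta = params.tau, params.zeta, params.tau_a
        wd = math.sqrt(1.0 - z * z) / tau
        decay = np.exp(-z * tp / tau)
        coeff = (z - ta / tau) / math.sqrt(1.0 - z * z)
        core = 1.0 - decay * (np.cos(wd * tp) + coeff * np.sin(wd * tp))
    out = KM * core
    # y'(0) = 0 holds analytically; enforce it exactly against rounding
    return np.where(t <= 0.0, 0.0, out)


def damping_coefficient(params: ModelParams) -> float:
    """Effective damping: stored zeta (underdamped) or (tau1+tau2)/(2*sqrt(tau1*tau2))."""
    if params.scenario == UNDERDAMPED:
        return float(params.zeta)
    return (params.tau1 + params.tau2) / (2.0 * math.sqrt(params.tau1 * params.tau2))


def _slowest_timescale(params: ModelParams) -> float:
    if params.scenario == OVERDAMPED:
        return max(params.tau1, params.tau2)
    return params.tau / params.zeta  # envelope decay constant


def settling_time(
    params: ModelParams,
    M: float,
    y0: float = 0.0,
    band_frac: float = 0.05,
    n_grid: int = 4096,
) -> float:
    """Last time the pool y(t) = y0 + y'(t) leaves the +/- band around y(inf).

    The band half-width is ``band_frac`` of the final pool level y(inf)
    (not of the step change), so near-flat responses settle at t = 0.
    Found by dense evaluation plus bisection on the continuous curve.
    """
    yinf = y0 + params.K * M
    if yinf <= 0.0:
        raise ValueError("settling time undefined for non-positive final level")
    band = band_frac * abs(yinf)

    tslow = _slowest_timescale(params)
    T = 20.0 * tslow
    for _ in range(60):  # extend horizon until the tail is safely settled
        tail = np.linspace(0.9 * T, T, 64)
        if np.all(np.abs(y0 + step_response(params, M, tail) - yinf) <= band):
            break
        T *= 2.0

    tt = np.linspace(0.0, T, n_grid)
    dev = np.abs(y0 + step_response(params, M, tt) - yinf)
    outside = dev > band
    if not outside.any():
        return 0.0
    i = int(np.max(np.nonzero(outside)[0]))  # last grid point outside the band
    lo, hi = tt[i], tt[min(i + 1, n_grid - 1)]

    def g(t: float) -> float:
        return abs(y0 + float(step_response(params, M, t)) - yinf) - band

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_fitting_error(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Percent error: 100 * mean|fitted - observed| / mean(observed).

    Normalised by the time-averaged observed level so the metric stays
    defined for flat profiles.  NaN observations are ignored.
    """
    fitted = np.asarray(fitted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = np.isfinite(observed) & np.isfinite(fitted)
    if not ok.any():
        raise ValueError("no finite observations")
    denom = float(np.mean(observed[ok]))
    if denom <= 0.0:
        raise ValueError("mean observed level must be positive")
    return 100.0 * float(np.mean(np.abs(fitted[ok] - observed[ok]))) / denom


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of fitting one trajectory: parameters, quality and curve."""

    params: ModelParams | None
    y0: float
    mean_fit_error: float
    accepted: bool
    fitted: np.ndarray
    times: np.ndarray
    ssr: float = math.inf
    converged: bool = False
    M: float = float("nan")

    @property
    def scenario(self) -> str | None:
        return None if self.params is None else self.params.scenario


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x > -50 else math.exp(x)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1.0 - p))


def _decode(theta: np.ndarray, scenario: str) -> ModelParams:
    K, ta = float(theta[0]), float(theta[1])
    if scenario == OVERDAMPED:
        t1 = min(max(math.exp(theta[2]), 1e-3), 1e6)
        t2 = min(max(math.exp(theta[3]), 1e-3), 1e6)
        return ModelParams.overdamped(K, ta, t1, t2)
    tau = min(max(math.exp(theta[2]), 1e-3), 1e6)
    z = min(max(_sigmoid(float(theta[3])), 1e-9), 1.0 - 1e-9)
    return ModelParams.underdamped(K, ta, tau, z)


def _starts(scenario: str, K0: float, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
    starts = []
    if scenario == OVERDAMPED:
        starts.append(np.array([K0, 1.0, math.log(20.0), math.log(5.0)]))
    else:
        starts.append(np.array([K0, 1.0, math.log(15.0), _logit(0.6)]))
    for _ in range(max(0, n_starts - 1)):
        K = K0 * rng.uniform(0.3, 2.0) if K0 != 0.0 else rng.normal(0.0, 0.1)
        ta = rng.uniform(-5.0, 15.0)
        if scenario == OVERDAMPED:
            l1 = math.log(rng.uniform(5.0, 60.0))
            l2 = math.log(rng.uniform(1.0, 20.0))
            starts.append(np.array([K, ta, l1, l2]))
        else:
            lt = math.log(rng.uniform(2.0, 40.0))
            z = _logit(rng.uniform(0.15, 0.95))
            starts.append(np.array([K, ta, lt, z]))
    return starts


def _fit_one_scenario(
    scenario: str,
    times: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    y0: float,
    M: float,
    K0: float,
    n_starts: int,
    rng: np.random.Generator,
) -> tuple[ModelParams | None, float]:
    """Two-stage fit of one scenario: unweighted multi-start, then weighted refine.

    Returns (best params, weighted SSR)."""

    def resid(theta: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
        try:
            p = _decode(theta, scenario)
        except (ValueError, OverflowError):
            return np.full(times.size, 1e6)
        model = y0 + step_response(p, M, times)
        r = model - y
        if weights is not None:
            r = r * weights
        return np.where(np.isfinite(r), r, 1e6)

    best_theta, best_cost = None, math.inf
    for x0 in _starts(scenario, K0, n_starts, rng):
        try:  # stage 1: unweighted — first estimate of the parameters
            sol = least_squares(resid, x0, args=(None,), method="lm", max_nfev=400)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_theta, best_cost = sol.x, sol.cost
    if best_theta is None:
        return None, math.inf

    try:  # stage 2: SD-weighted refinement from the stage-1 estimate
        sol = least_squares(resid, best_theta, args=(w,), method="lm", max_nfev=400)
        theta = sol.x
    except Exception:
        theta = best_theta
    wssr = float(np.sum(resid(theta, w) ** 2))
    try:
        return _decode(theta, scenario), wssr
    except (ValueError, OverflowError):
        return None, math.inf


def _weights(sd: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stabilized 1/sd weights; all-zero/missing SDs degrade to unweighted.

    Raw replicate SDs at n = 3 are extremely noisy (2 df), and inverting
    them directly lets a lucky small SD dominate the fit.  Since replicate
    noise is multiplicative, the SD is shrunk halfway toward a relative-
    noise model sd ~ cv_hat * |y| with cv_hat the median observed relative
    SD, before inversion.
    """
    scale = float(np.nanmean(np.abs(y)))
    floor = 1e-6 * scale if scale > 0 else 1e-12
    sd = np.where(np.isfinite(sd) & (sd > floor), sd, np.nan)
    if np.all(np.isnan(sd)):
        return np.ones_like(y)
    fill = float(np.nanmedian(sd))
    sd = np.where(np.isnan(sd), fill, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_hat = float(np.nanmedian(sd / np.abs(y)))
    model_sd = np.maximum(cv_hat * np.abs(y), floor)
    sd = np.sqrt(0.5 * sd**2 + 0.5 * model_sd**2)
    return 1.0 / sd


def fit_metabolite(
    times,
    mean,
    sd=None,
    *,
    M: float = 1.0,
    error_threshold: float = 5.0,
    n_starts: int = 8,
    seed: int = 0,
    scenario_tie_rtol: float = 0.01,
) -> FitResult:
    """Fit one averaged trajectory to both model branches and keep the winner.

    ``times`` must contain one pre-step point (t < 0) whose mean fixes the
    baseline y0; post-step points are fit in deviation form.  Both the
    overdamped and underdamped branches are fit with a two-stage procedure
    (multi-start unweighted least squares, then SD-weighted refinement);
    the branch with the lower weighted residual wins, with ties inside
    ``scenario_tie_rtol`` resolved toward the overdamped branch.  The fit
    is accepted when the mean fitting error is at or below
    ``error_threshold`` percent.
    """
    times = np.asarray(times, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.full_like(mean, np.nan) if sd is None else np.asarray(sd, dtype=float)

    ok = np.isfinite(mean)
    t, y, s = times[ok], mean[ok], sd[ok]
    if t.size < 6:
        raise ValueError(f"need >= 6 usable time points, got {t.size}")
    pre = t < 0.0
    if not pre.any():
        raise ValueError("no pre-step point to estimate the baseline")
    y0 = float(np.mean(y[pre]))

    w = _weights(s, y)
    K0 = (float(y[-1]) - y0) / M
    rng = np.random.default_rng(seed)

    candidates: dict[str, tuple[ModelParams | None, float]] = {}
    for scen in (OVERDAMPED, UNDERDAMPED):
        candidates[scen] = _fit_one_scenario(scen, t, y, w, y0, M, K0, n_starts, rng)

    p_over, c_over = candidates[OVERDAMPED]
    p_under, c_under = candidates[UNDERDAMPED]
    if p_over is None and p_under is None:
        return FitResult(None, y0, math.inf, False, np.full_like(times, np.nan), times, M=M)

    if p_under is None or (
        p_over is not None and c_over <= c_under * (1.0 + scenario_tie_rtol)
    ):
        params, ssr = p_over, c_over
    else:
        params, ssr = p_under, c_under

    fitted = y0 + step_response(params, M, times)
    err = mean_fitting_error(fitted[ok], y)
    return FitResult(
        params=params,
        y0=y0,
        mean_fit_error=err,
        accepted=err <= error_threshold,
        fitted=fitted,
        times=times,
        ssr=ssr,
        converged=True,
        M=M,
    )
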