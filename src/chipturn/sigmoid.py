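"""Sigmoidal (log-logistic) modeling of time-course coverage.

The model is the four/five-parameter sigmoid

    y = d + (a - d) / (1 + exp(b * (x - c)))**f

where ``b`` is the incorporation rate index (IRI, slope at the inflection
point), ``c`` a time offset, ``f`` a positive asymmetry factor (fixed at 1
by default, giving the symmetric 4P model), and ``a``/``d`` the two
plateaus.  With ``b < 0`` the curve increases from ``d`` (early plateau)
to ``a`` (late plateau); with ``b > 0`` it decreases from ``a`` to ``d``.
Under this convention rises carry a negative IRI and falls a positive one,
and the reported lower/upper asymptotes are ``min(a, d)`` / ``max(a, d)``.

The turnover time index (TTI) is the time at which the curve crosses the
midpoint ``(a + d) / 2`` between its plateaus; for ``f = 1`` this
coincides with the inflection point and equals ``c`` exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "SigmoidParams",
    "FitResult",
    "LinearFit",
    "FlatDataError",
    "sigmoid_eval",
    "inflection_point",
    "turnover_time_index",
    "fit_sigmoid",
    "fit_linear",
]

PARAM_NAMES = ("a", "b", "c", "d", "f")


class FlatDataError(ValueError):
    """Raised when a series carries no variation to constrain a sigmoid."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameter tuple (a, b, c, d, f) of the 4P/5P sigmoid."""

    a: float
    b: float
    c: float
    d: float
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError(f"asymmetry factor f must be positive, got {self.f}")
        if self.b == 0:
            raise ValueError("incorporation rate index b must be non-zero")

    @property
    def lower_asymptote(self) -> float:
        return min(self.a, self.d)

    @property
    def upper_asymptote(self) -> float:
        return max(self.a, self.d)

    @property
    def direction(self) -> str:
        """'increasing' iff b < 0 (rise), else 'decreasing' (fall)."""
        return "increasing" if self.b < 0 else "decreasing"

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.f], dtype=float)


def sigmoid_eval(params: SigmoidParams, x):
    """Evaluate the sigmoid at time(s) ``x``.

    Uses ``(1 + e^z)^f = exp(f * log1p(e^z))`` through ``logaddexp`` so
    that large ``|b (x - c)|`` saturates to the appropriate plateau
    without overflow.
    """
    x = np.asarray(x, dtype=float)
    z = params.b * (x - params.c)
    # log(1 + e^z), numerically stable for any z
    log_denom = np.logaddexp(0.0, z)
    y = params.d + (params.a - params.d) * np.exp(-params.f * log_denom)
    return y if y.ndim else float(y)


def inflection_point(params: SigmoidParams) -> float:
    """Root of the second derivative: x = c - ln(f)/b (exactly c for f=1)."""
    if params.b == 0:
        raise ValueError("inflection point undefined for b = 0")
    if params.f == 1.0:
        return params.c
    return params.c - math.log(params.f) / params.b


def turnover_time_index(params: SigmoidParams) -> float:
    """Time at which the curve reaches the plateau midpoint (a + d) / 2.

    Closed form: x = c + ln(2**(1/f) - 1) / b, which reduces to c when
    f = 1.  Undefined for flat curves (a == d) or b == 0.
    """
    if params.b == 0:
        raise ValueError("TTI undefined for b = 0")
    if params.a == params.d:
        raise ValueError("TTI undefined for a flat curve (a == d)")
    if params.f == 1.0:
        return params.c
    return params.c + math.log(2.0 ** (1.0 / params.f) - 1.0) / params.b


@dataclass
class FitResult:
    """A fitted sigmoid with uncertainty and goodness-of-fit bookkeeping.

    ``rss`` holds the residual sum of squares for the least-squares
    objective and the negative log-likelihood for the Poisson objective.
    ``std_errors`` is aligned to (a, b, c, d, f); entries for parameters
    held fixed are NaN.
    """

    params: SigmoidParams
    std_errors: np.ndarray
    rss: float
    objective: Literal["least_squares", "poisson"]
    converged: bool
    tti: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.tti):
            try:
                self.tti = turnover_time_index(self.params)
            except ValueError:
                self.tti = float("nan")

    @property
    def direction(self) -> str:
        return self.params.direction


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    rss: float


def fit_linear(times: Sequence[float], ys: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line, the comparison model for sigmoid fits."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(ys, dtype=float)
    if t.size < 2:
        raise ValueError("linear fit requires at least 2 points")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return LinearFit(float(slope), float(intercept), float(np.sum(resid**2)))


# ---------------------------------------------------------------------------
# fitting


def _validate_series(t: np.ndarray, y: np.ndarray) -> None:
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and ys must be 1-D arrays of equal length")
    if np.any(y < 0):
        raise ValueError("coverage values must be non-negative")
    if np.ptp(y) == 0:
        raise FlatDataError("all coverage values identical; sigmoid unconstrained")


def _initial_guess(t: np.ndarray, y: np.ndarray, increasing: bool) -> Tuple[float, ...]:
    lo, hi = float(np.min(y)), float(np.max(y))
    span = float(t[-1] - t[0]) or 1.0
    mid = 0.5 * (lo + hi)
    # first time the series crosses its own midrange
    above = y >= mid
    crossing = np.nonzero(above != above[0])[0]
    c0 = float(t[crossing[0]]) if crossing.size else float(t[len(t) // 2])
    b_mag = max(4.0 * (hi - lo) / span / max(hi - lo, 1e-12), 0.5)  # ~4/span
    b0 = -b_mag if increasing else b_mag
    # a is the late plateau when b<0, the early plateau when b>0
    a0, d0 = hi, lo
    return a0, b0, c0, d0


def _theta_to_params(free: Sequence[str], theta: np.ndarray, fixed: dict) -> SigmoidParams:
    """Assemble SigmoidParams from free-parameter vector + fixed values.

    Free-plateau fits use the ordered parametrization a = d + delta with
    delta >= 0, which pins a as the upper and d as the lower plateau, so
    the fitted curve is increasing exactly when b < 0 (for every f).
    """
    kw = dict(fixed)
    kw.update(zip(free, theta))
    if "delta" in kw:
        kw["a"] = kw["d"] + kw.pop("delta")
    return SigmoidParams(**kw)


def _pack_model(
    free: Sequence[str],
    fixed: dict,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    def model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
        return sigmoid_eval(_theta_to_params(free, theta, fixed), t)

    return model


def _poisson_nll(yhat: np.ndarray, y: np.ndarray) -> float:
    yhat = np.maximum(yhat, 1e-9)
    return float(np.sum(yhat - y * np.log(yhat)))


def fit_sigmoid(
    times: Sequence[float],
    ys: Sequence[float],
    objective: Literal["least_squares", "poisson"] = "least_squares",
    fix_f: bool = True,
    fixed_plateaus: Optional[Tuple[float, float]] = None,
) -> FitResult:
    """Fit the sigmoid to a coverage series.

    Both plateaus are constrained non-negative.  The sign of ``b`` is not
    imposed: the optimizer is started from both an increasing and a
    decreasing seed and the better optimum wins, so the fitted direction
    is informative for downstream prediction verification.

    ``fixed_plateaus=(a, d)`` pins the plateaus and fits only (b, c)
    [and f when free], which permits fitting very short segments of a
    double sigmoid.  The Poisson objective maximizes
    ``sum(y * log(yhat) - yhat)`` and requires count-like (integer-valued)
    input; use least squares for continuous normalized coverage.

    Returns ``converged=False`` (rather than raising) when the optimizer
    fails; raises on structurally unfittable input (too few points, flat
    data, negative values).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ys, dtype=float)
    _validate_series(t, y)

    free = ["b", "c"] if fixed_plateaus is not None else ["d", "delta", "b", "c"]
    if not fix_f:
        free = free + ["f"]
    n_par = len(free)
    if t.size < n_par:
        raise ValueError(
            f"need at least {n_par} points to fit {n_par} free parameters, got {t.size}"
        )
    if objective == "poisson" and np.any(np.abs(y - np.round(y)) > 1e-8):
        raise ValueError(
            "Poisson objective requires count-like (integer-valued) input; "
            "use objective='least_squares' for continuous normalized coverage"
        )

    span = float(t[-1] - t[0]) or 1.0
    ymax = float(np.max(y))
    fixed = {"f": 1.0} if fix_f else {}
    if fixed_plateaus is not None:
        fixed["a"], fixed["d"] = float(fixed_plateaus[0]), float(fixed_plateaus[1])

    bounds_map = {
        "b": None,  # filled per sign branch
        "c": (float(t[0]) - span, float(t[-1]) + span),
        "d": (0.0, 3.0 * ymax),
        "delta": (0.0, 3.0 * ymax),
        "f": (0.1, 10.0),
    }

    a0, b0_inc, c0, d0 = _initial_guess(t, y, increasing=True)
    seeds = {
        "c": c0,
        "d": d0,
        "delta": a0 - d0,
        "f": 1.0,
    }
    model = _pack_model(free, fixed)

    best = None
    rng = np.random.default_rng(0)
    for sign in (-1.0, 1.0):
        b_bounds = (1e-6, 1e3) if sign > 0 else (-1e3, -1e-6)
        lo = np.array([b_bounds[0] if p == "b" else bounds_map[p][0] for p in free])
        hi = np.array([b_bounds[1] if p == "b" else bounds_map[p][1] for p in free])
        theta0 = np.array(
            [sign * abs(b0_inc) if p == "b" else seeds[p] for p in free]
        )
        theta0 = np.clip(theta0, lo, hi)
        attempts = [theta0]
        # one multi-start restart with perturbed seed
        attempts.append(np.clip(theta0 * rng.uniform(0.7, 1.3, n_par) + 1e-3, lo, hi))
        for theta_init in attempts:
            res = _optimize_branch(model, theta_init, lo, hi, t, y, objective)
            if res is None:
                continue
            if best is None or res[1] < best[1]:
                best = res
            if best is not None and best[3]:
                break  # converged on first attempt of this branch

    if best is None:
        # optimizer failed on every branch; report a non-converged fit at the seed
        theta0 = np.array([seeds.get(p, b0_inc) for p in free])
        params = _theta_to_params(free, theta0, fixed)
        return FitResult(params, np.full(5, np.nan), float("inf"), objective, converged=False)

    theta, obj_val, jac, success = best
    params = _theta_to_params(free, theta, fixed)
    cov = _param_covariance(model, theta, t, y, objective, jac)
    se_full = _map_std_errors(free, cov)
    return FitResult(params, se_full, float(obj_val), objective, converged=bool(success))


def _optimize_branch(model, theta0, lo, hi, t, y, objective):
    """One bounded optimization; returns (theta, objective, jac|None, success)."""
    try:
        if objective == "least_squares":
            res = optimize.least_squares(
                lambda th: model(th, t) - y,
                theta0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=500 * theta0.size,
            )
            rss = float(np.sum(res.fun**2))
            # an objective at the numerical floor is converged even if the
            # optimizer ran out of evaluations wandering a flat ridge
            success = bool(res.success) or rss <= 1e-10 * max(1.0, float(np.sum(y**2)))
            return res.x, rss, res.jac, success
        res = optimize.minimize(
            lambda th: _poisson_nll(model(th, t), y),
            theta0,
            bounds=list(zip(lo, hi)),
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        return res.x, float(res.fun), None, bool(res.success)
    except (ValueError, np.linalg.LinAlgError):
        return None


def _param_covariance(model, theta, t, y, objective, jac) -> Optional[np.ndarray]:
    """Curvature-based covariance of the free parameters.

    Least squares: Gauss-Newton, cov = s^2 (J'J)^-1 with s^2 = RSS/(n-p).
    Poisson: inverse observed information (finite-difference Hessian of
    the negative log-likelihood).
    """
    n, p = t.size, theta.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if objective == "least_squares":
                if jac is None or n <= p:
                    return None
                rss = float(np.sum((model(theta, t) - y) ** 2))
                s2 = rss / (n - p)
                return s2 * np.linalg.pinv(jac.T @ jac)
            hess = _fd_hessian(lambda th: _poisson_nll(model(th, t), y), theta)
            return np.linalg.pinv(hess)
        except (ValueError, np.linalg.LinAlgError):
            return None


def _map_std_errors(free: Sequence[str], cov: Optional[np.ndarray]) -> np.ndarray:
    """Standard errors on the (a, b, c, d, f) scale; fixed entries NaN.

    With the ordered parametrization, var(a) = var(d + delta) follows
    from the full covariance of (d, delta).
    """
    se_full = np.full(5, np.nan)
    if cov is None:
        return se_full
    idx = {name: k for k, name in enumerate(free)}

    def _sd(var: float) -> float:
        return math.sqrt(var) if var >= 0 else float("nan")

    for name in ("b", "c", "d", "f"):
        if name in idx:
            se_full[PARAM_NAMES.index(name)] = _sd(cov[idx[name], idx[name]])
    if "delta" in idx:
        i, j = idx["d"], idx["delta"]
        se_full[PARAM_NAMES.index("a")] = _sd(cov[i, i] + cov[j, j] + 2 * cov[i, j])
    return se_full


def _fd_hessian(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    p = x.size
    h = eps * np.maximum(np.abs(x), 1.0)
    hess = np.empty((p, p))
    f0 = fn(x)
    for i in range(p):
        for j in range(i, p):
            xi = x.copy()
            xi[i] += h[i]
            xj = x.copy()
            xj[j] += h[j]
            xij = xi.copy()
            xij[j] += h[j]
            hess[i, j] = hess[j, i] = (fn(xij) - fn(xi) - fn(xj) + f0) / (h[i] * h[j])
    return hess
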