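"""Nonlinear least-squares fitting of time-activity models.

Fits are deterministic: the initial guess is a documented closed-form
construction (log-linear regression for the monoexponential, a last-segment
rate estimate for the biexponentials) and no random restarts are performed by
default.  Unconstrained problems use Levenberg-Marquardt; when the decay
constants are constrained to be at least the physical decay constant, a
bounded trust-region least-squares solver enforces the box bound.  The
contract is "least-squares minimum respecting bounds", not a specific
algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BiExp3Params,
    BiExp4Params,
    ModelParams,
    MonoExpParams,
    NuclideConstants,
    LU177,
    eval_model,
    n_params,
)

__all__ = [
    "TimeActivitySeries", "FitSpec", "FitResult",
    "fit_curve", "initial_guess", "fit_diagnostics",
    "DECAY_CONVENTIONS", "POINT_SELECTORS",
]

DECAY_CONVENTIONS = ("corrected_to_injection", "corrected_to_scan_start", "none")

#: subset selectors for the points entering the fit
POINT_SELECTORS = ("all", "last_3", "from_second")

_LAM_FLOOR = 1e-6  # 1/h; floor for degenerate rate guesses


@dataclass(frozen=True)
class TimeActivitySeries:
    """One region's sampled activities at the imaging time points.

    ``decay_convention`` records what reference time the activities are
    decay-corrected to: ``corrected_to_injection`` (each value rescaled to
    injection time by exp(+lam_physical*t)), ``corrected_to_scan_start``
    (reference is each scan's own start, numerically the as-measured value
    for organ-level series), or ``none`` (as-measured).
    """

    region_id: str
    times: tuple            # hours post-injection, strictly increasing, > 0
    activities: tuple       # MBq, >= 0, same length
    decay_convention: str = "none"
    injected_activity: Optional[float] = None  # MBq

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "activities", tuple(a))
        if len(t) != len(a):
            raise ValueError(
                f"{self.region_id}: times and activities differ in length "
                f"({len(t)} vs {len(a)})")
        if len(t) < 2:
            raise ValueError(f"{self.region_id}: need >= 2 time points")
        if np.any(t <= 0):
            raise ValueError(f"{self.region_id}: times must be > 0 h")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{self.region_id}: times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError(f"{self.region_id}: activities must be >= 0")
        if self.decay_convention not in DECAY_CONVENTIONS:
            raise ValueError(
                f"unknown decay convention {self.decay_convention!r}; "
                f"expected one of {DECAY_CONVENTIONS}")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def a(self) -> np.ndarray:
        return np.asarray(self.activities, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def with_activities(self, activities, decay_convention=None
                        ) -> "TimeActivitySeries":
        return TimeActivitySeries(
            region_id=self.region_id,
            times=self.times,
            activities=tuple(np.asarray(activities, dtype=float)),
            decay_convention=decay_convention or self.decay_convention,
            injected_activity=self.injected_activity,
        )


@dataclass(frozen=True)
class FitSpec:
    """How to fit one model family to a series."""

    model_family: str
    constrain_lambda_physical: bool = False
    weighting: str = "unweighted"      # unweighted | relative | user_supplied
    sigma: Optional[tuple] = None      # per-point sd for user_supplied
    points_used: str = "all"           # all | last_3 | from_second
    init_strategy: str = "default"
    n_restarts: int = 0
    restart_seed: int = 0

    def __post_init__(self) -> None:
        n_params(self.model_family)  # validates family
        if self.points_used not in POINT_SELECTORS:
            raise ValueError(
                f"unknown points selector {self.points_used!r}; "
                f"expected one of {POINT_SELECTORS}")
        if self.weighting not in ("unweighted", "relative", "user_supplied"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weighting == "user_supplied" and self.sigma is None:
            raise ValueError("user_supplied weighting requires sigma")


@dataclass
class FitResult:
    """Converged (or not) least-squares fit with diagnostics."""

    params: Optional[ModelParams]
    model_family: str
    residuals: np.ndarray
    r_squared: float
    aic: float
    aicc: Optional[float]          # None when n - k - 1 <= 0
    converged: bool
    warnings: list = field(default_factory=list)
    n_points: int = 0
    rss: float = float("nan")
    message: str = ""


def _select_points(series: TimeActivitySeries, selector: str):
    t, a = series.t, series.a
    if selector == "last_3":
        return t[-3:], a[-3:]
    if selector == "from_second":
        return t[1:], a[1:]
    return t, a


def _weights(a: np.ndarray, spec: FitSpec) -> np.ndarray:
    """Per-point 1/sigma weights applied to the residuals."""
    if spec.weighting == "unweighted":
        return np.ones_like(a)
    if spec.weighting == "relative":
        floor = 0.01 * float(np.max(a)) if np.max(a) > 0 else 1.0
        sigma = np.maximum(a, floor)
        return 1.0 / sigma
    sigma = np.asarray(spec.sigma, dtype=float)
    if sigma.shape != a.shape:
        raise ValueError("sigma length must match the selected points")
    return 1.0 / sigma


def initial_guess(series: TimeActivitySeries, model_family: str,
                  points: Optional[tuple] = None) -> np.ndarray:
    """Deterministic closed-form starting values for the optimiser.

    monoexp: log-linear regression on the positive activities.
    biexp3:  washout rate from the last two points, uptake rate 10x faster,
             amplitude scaled so the model peak matches the data peak.
    biexp4:  same rate construction; slow amplitude back-extrapolated from
             the last point, fast amplitude from the residual at the peak.
    Rate estimates that come out non-positive are clipped to a small
    positive floor (1e-6 / h).
    """
    if points is not None:
        t, a = points
    else:
        t, a = series.t, series.a
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)

    if model_family == "monoexp":
        pos = a > 0
        if pos.sum() < 2:
            raise ValueError("need >= 2 positive activities for a monoexp guess")
        slope, intercept = np.polyfit(t[pos], np.log(a[pos]), 1)
        lam = max(-slope, _LAM_FLOOR)
        return np.array([math.exp(intercept), lam])

    # washout rate from the last segment
    if a[-2] > 0 and a[-1] > 0 and a[-2] != a[-1]:
        lam1 = math.log(a[-2] / a[-1]) / (t[-1] - t[-2])
    else:
        lam1 = _LAM_FLOOR
    lam1 = max(lam1, _LAM_FLOOR)
    lam2 = 10.0 * lam1
    peak = float(np.max(a))

    if model_family == "biexp3":
        shape = np.exp(-lam1 * t) - np.exp(-lam2 * t)
        smax = float(np.max(shape))
        A = peak / smax if smax > 0 else peak
        return np.array([A, lam1, lam2])

    if model_family == "biexp4":
        A1 = a[-1] * math.exp(lam1 * t[-1])
        ipeak = int(np.argmax(a))
        resid = peak - A1 * math.exp(-lam1 * t[ipeak])
        A2 = max(resid, 0.0) / math.exp(-lam2 * t[ipeak])
        if A2 == 0.0:
            A2 = 0.5 * peak
        return np.array([A1, A2, lam1, lam2])

    raise ValueError(f"unknown model family {model_family!r}")


def _vector_to_params(model_family: str, x: np.ndarray):
    """Map the optimiser vector to a params dataclass, canonicalising order.

    Returns (params, extra_warnings).  For the biexponentials the two phases
    are reordered so the washout rate is the smaller one; a biexp3 whose
    canonical amplitude would be negative is reported with a warning.
    """
    warnings = []
    if model_family == "monoexp":
        A, lam = x
        if A < 0:
            warnings.append("negative_amplitude")
            A = 0.0
        return MonoExpParams(A=A, lam=lam), warnings
    if model_family == "biexp3":
        A, lam1, lam2 = x
        if lam1 > lam2:  # swapping the rates flips the curve's sign
            lam1, lam2 = lam2, lam1
            A = -A
        if A < 0:
            warnings.append("negative_amplitude")
            A = 0.0
        return BiExp3Params(A=A, lam1=lam1, lam2=lam2), warnings
    A1, A2, lam1, lam2 = x
    if lam1 > lam2:
        lam1, lam2 = lam2, lam1
        A1, A2 = A2, A1
    if A1 < 0 or A2 < 0:
        # legitimate for an uptake-shaped curve; kept, but surfaced
        warnings.append("negative_amplitude")
    return BiExp4Params(A1=A1, A2=A2, lam1=lam1, lam2=lam2), warnings


def _model_curve(model_family: str, x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the raw optimiser vector without canonicalisation checks.

    Overflow while the optimiser explores very negative decay constants is
    benign (infinite residuals steer it back), so it is silenced here.
    """
    with np.errstate(over="ignore"):
        if model_family == "monoexp":
            A, lam = x
            return A * np.exp(-lam * t)
        if model_family == "biexp3":
            A, lam1, lam2 = x
            return A * (np.exp(-lam1 * t) - np.exp(-lam2 * t))
        A1, A2, lam1, lam2 = x
        return A1 * np.exp(-lam1 * t) + A2 * np.exp(-lam2 * t)


def fit_curve(series: TimeActivitySeries, spec: FitSpec,
              constants: NuclideConstants = LU177) -> FitResult:
    """Least-squares fit of ``spec.model_family`` to the series.

    With ``constrain_lambda_physical`` every decay constant is box-bounded
    below by the physical decay constant (amplitudes below by 0).  Failure to
    converge is reported through ``converged=False`` rather than an
    exception.  Fitting exactly four points with the four-parameter
    biexponential is permitted but flagged ``ill_conditioned_4param``.
    """
    t, a = _select_points(series, spec.points_used)
    k = n_params(spec.model_family)
    warnings: list = []

    if spec.model_family == "biexp4" and len(t) == k:
        warnings.append("ill_conditioned_4param")
    elif len(t) < k:
        raise ValueError(
            f"{len(t)} points cannot determine {k} parameters "
            f"({spec.model_family})")
    if np.all(a == 0):
        raise ValueError("all-zero activities cannot be fitted")

    w = _weights(a, spec)
    x0 = initial_guess(series, spec.model_family, points=(t, a))

    def resid(x):
        return w * (_model_curve(spec.model_family, x, t) - a)

    solver_opts = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    sol = least_squares(resid, x0, method="lm", **solver_opts)
    if spec.constrain_lambda_physical:
        lam_lo = constants.lam_physical
        if spec.model_family == "monoexp":
            lower = np.array([0.0, lam_lo])
        elif spec.model_family == "biexp3":
            lower = np.array([0.0, lam_lo, lam_lo])
        else:
            lower = np.array([0.0, 0.0, lam_lo, lam_lo])
        if not (bool(sol.success) and np.all(sol.x >= lower)):
            # the free optimum violates the box: solve the bounded problem
            x0b = np.maximum(x0, lower)
            sol = least_squares(resid, x0b, bounds=(lower, np.inf),
                                method="trf", **solver_opts)
            # snap rates that converged onto the bound to the exact bound
            x = np.asarray(sol.x, dtype=float)
            at_bound = (x - lower) <= 1e-10 * np.maximum(np.abs(lower), 1.0)
            x[at_bound] = lower[at_bound]
            sol.x = x

    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    params = None
    if converged:
        try:
            params, extra = _vector_to_params(spec.model_family, sol.x)
            warnings.extend(extra)
        except ValueError:
            converged = False

    residuals = _model_curve(spec.model_family, sol.x, t) - a
    rss = float(np.sum(residuals ** 2))
    tss = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else float("nan"))
    n = len(t)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = None
        warnings.append("aicc_undefined")

    if (params is not None and series.injected_activity is not None):
        a0 = float(eval_model(spec.model_family, params, 0.0))
        if a0 > series.injected_activity:
            warnings.append("nonphysiological_t0_activity")

    return FitResult(
        params=params,
        model_family=spec.model_family,
        residuals=residuals,
        r_squared=r2,
        aic=aic,
        aicc=aicc,
        converged=converged,
        warnings=warnings,
        n_points=n,
        rss=rss,
        message=sol.message,
    )


def fit_diagnostics(fit: FitResult, series: TimeActivitySeries,
                    spec: FitSpec) -> dict:
    """Goodness-of-fit record for a converged fit.

    Reports R^2, AIC = n*ln(RSS/n) + 2k, AICc (None when n - k - 1 <= 0),
    the per-point residual table, and sanity flags such as a fitted t=0
    activity exceeding the injected activity.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    t, a = _select_points(series, spec.points_used)
    fitted = np.asarray(eval_model(fit.model_family, fit.params, t))
    flags = list(fit.warnings)
    return {
        "region_id": series.region_id,
        "model_family": fit.model_family,
        "r_squared": fit.r_squared,
        "aic": fit.aic,
        "aicc": fit.aicc,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "residual_table": {
            "time_h": list(t),
            "observed_MBq": list(a),
            "fitted_MBq": list(fitted),
            "residual_MBq": list(fitted - a),
        },
        "flags": flags,
    }
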