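"""Exponential time-activity model families with closed-form integrals.

Three families cover the fits used in organ-level radiopharmaceutical
dosimetry of 4-point imaging data:

* ``monoexp``  -- ``A(t) = A * exp(-lam * t)``; instantaneous uptake followed
  by a single washout phase.  The workhorse model for healthy organs.
* ``biexp3``   -- ``A(t) = A * (exp(-lam1 * t) - exp(-lam2 * t))``; an uptake
  phase (rate ``lam2``) followed by washout (rate ``lam1``), constructed so
  the activity is exactly zero at ``t = 0``.  Three free parameters.
* ``biexp4``   -- ``A(t) = A1 * exp(-lam1 * t) + A2 * exp(-lam2 * t)``; the
  unconstrained two-phase sum.  Four free parameters, ill-conditioned when
  fitted to exactly four time points.

A separate :class:`PhysicalTailParams` describes the "assume physical decay
after the last scan" extrapolation: ``A(t) = A_p4 * exp(-lam_physical *
(t - t_p4))`` for ``t >= t_p4``.

Times are hours post-injection, activities MBq, integrals (TIA segments)
MBq*h throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "MonoExpParams", "BiExp3Params", "BiExp4Params", "PhysicalTailParams",
    "NuclideConstants", "LU177", "MODEL_FAMILIES", "n_params",
    "eval_model", "integral_closed_form", "physical_tail_integral",
    "DivergentIntegralError",
]

#: relative tolerance below which biexp3 switches to its equal-rate limit form
_DEGENERATE_RTOL = 1e-9


class DivergentIntegralError(ValueError):
    """Improper integral to infinity does not converge (decay constant <= 0)."""


@dataclass(frozen=True)
class NuclideConstants:
    """Physical decay data of the radionuclide.

    Default is 177Lu with a half-life of 6.6475 days (published nuclear
    data); any radionuclide can be configured through ``half_life`` in hours.
    """

    half_life: float = 6.6475 * 24.0  # hours

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")

    @property
    def lam_physical(self) -> float:
        """Physical decay constant ln(2)/half_life in 1/h."""
        return math.log(2.0) / self.half_life


#: Default 177Lu constants (half-life 6.6475 d = 159.54 h).
LU177 = NuclideConstants()


@dataclass(frozen=True)
class MonoExpParams:
    """Monoexponential washout: A(t) = A * exp(-lam * t)."""

    A: float      # activity at time 0, MBq
    lam: float    # decay constant, 1/h

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")

    family = "monoexp"


@dataclass(frozen=True)
class BiExp3Params:
    """Three-parameter biexponential: A(t) = A*(exp(-lam1*t) - exp(-lam2*t)).

    ``lam2`` is the uptake rate and must exceed the washout rate ``lam1`` for
    the curve to be non-negative; the curve is exactly zero at t = 0.  When
    the two rates coincide to within 1e-9 relative, evaluation switches to
    the limit form ``A * lam * t * exp(-lam * t)``.
    """

    A: float
    lam1: float   # washout, 1/h
    lam2: float   # uptake, 1/h

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")
        if not self._degenerate() and self.lam2 < self.lam1:
            raise ValueError(
                f"uptake rate lam2 ({self.lam2}) must be >= washout rate "
                f"lam1 ({self.lam1}) for a non-negative curve"
            )

    def _degenerate(self) -> bool:
        scale = abs(self.lam1) if self.lam1 != 0 else 1.0
        return abs(self.lam1 - self.lam2) < _DEGENERATE_RTOL * scale

    family = "biexp3"


@dataclass(frozen=True)
class BiExp4Params:
    """Four-parameter biexponential: A(t) = A1*exp(-lam1*t) + A2*exp(-lam2*t).

    Amplitudes may be negative (a negative fast phase represents uptake);
    fitted to exactly four points the problem is ill-conditioned (flagged
    upstream).
    """

    A1: float
    A2: float
    lam1: float
    lam2: float

    family = "biexp4"


@dataclass(frozen=True)
class PhysicalTailParams:
    """Physical-decay extrapolation beyond the last time point.

    A(t) = A_p4 * exp(-lam_physical * (t - t_p4)) for t >= t_p4.
    """

    A_p4: float          # activity at the last time point, MBq
    t_p4: float          # last time point, h
    lam_physical: float  # physical decay constant, 1/h

    def __post_init__(self) -> None:
        if self.A_p4 < 0:
            raise ValueError(f"A_p4 must be >= 0, got {self.A_p4}")
        if not self.lam_physical > 0:
            raise ValueError(
                f"lam_physical must be > 0, got {self.lam_physical}")


ModelParams = Union[MonoExpParams, BiExp3Params, BiExp4Params]

MODEL_FAMILIES = ("monoexp", "biexp3", "biexp4")

_N_PARAMS = {"monoexp": 2, "biexp3": 3, "biexp4": 4}


def n_params(model_family: str) -> int:
    """Number of free parameters of a model family."""
    _check_family(model_family)
    return _N_PARAMS[model_family]


def _check_family(model_family: str) -> None:
    if model_family not in MODEL_FAMILIES:
        raise ValueError(
            f"unknown model family {model_family!r}; "
            f"expected one of {MODEL_FAMILIES}"
        )


def _check_params(model_family: str, params: ModelParams) -> None:
    _check_family(model_family)
    if params.family != model_family:
        raise ValueError(
            f"params are for family {params.family!r}, not {model_family!r}")


def eval_model(model_family: str, params: ModelParams, t):
    """Evaluate a model family at time(s) ``t`` (hours).

    Returns activity in MBq with the same shape as ``t``.  Valid parameters
    never produce negative activities.
    """
    _check_params(model_family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if model_family == "monoexp":
        out = params.A * np.exp(-params.lam * t)
    elif model_family == "biexp3":
        if params._degenerate():
            lam = params.lam1
            out = params.A * lam * t * np.exp(-lam * t)
        else:
            out = params.A * (np.exp(-params.lam1 * t)
                              - np.exp(-params.lam2 * t))
    else:  # biexp4
        out = (params.A1 * np.exp(-params.lam1 * t)
               + params.A2 * np.exp(-params.lam2 * t))
    return out if out.ndim else float(out)


def _exp_segment(amplitude: float, lam: float, a: float, b: float) -> float:
    """Integral of amplitude*exp(-lam*t) over [a, b] (b may be inf)."""
    if math.isinf(b):
        if lam <= 0:
            if amplitude == 0:
                return 0.0
            raise DivergentIntegralError(
                f"integral to infinity diverges: decay constant {lam} <= 0")
        return amplitude / lam * math.exp(-lam * a)
    if lam == 0:
        return amplitude * (b - a)
    return amplitude / lam * (math.exp(-lam * a) - math.exp(-lam * b))


def _degenerate_segment(A: float, lam: float, a: float, b: float) -> float:
    """Integral of A*lam*t*exp(-lam*t) over [a, b]; antiderivative is
    -A*exp(-lam*t)*(t + 1/lam)."""
    if lam <= 0:
        if A == 0:
            return 0.0
        raise DivergentIntegralError(
            f"integral diverges: decay constant {lam} <= 0")
    lo = A * math.exp(-lam * a) * (a + 1.0 / lam)
    hi = 0.0 if math.isinf(b) else A * math.exp(-lam * b) * (b + 1.0 / lam)
    return lo - hi


def integral_closed_form(model_family: str, params: ModelParams,
                         a: float, b: float) -> float:
    """Exact integral of the model over [a, b] in MBq*h; ``b`` may be inf.

    Uses the analytic antiderivative term by term.  An improper integral with
    a non-positive decay constant raises :class:`DivergentIntegralError`.
    """
    _check_params(model_family, params)
    if a < 0 or b < a:
        raise ValueError(f"need 0 <= a <= b, got a={a}, b={b}")
    if model_family == "monoexp":
        return _exp_segment(params.A, params.lam, a, b)
    if model_family == "biexp3":
        if params._degenerate():
            return _degenerate_segment(params.A, params.lam1, a, b)
        return (_exp_segment(params.A, params.lam1, a, b)
                - _exp_segment(params.A, params.lam2, a, b))
    return (_exp_segment(params.A1, params.lam1, a, b)
            + _exp_segment(params.A2, params.lam2, a, b))


def physical_tail_integral(tail: PhysicalTailParams) -> float:
    """TIA of the physical-decay tail from t_p4 to infinity: A_p4/lam_physical."""
    return tail.A_p4 / tail.lam_physical
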