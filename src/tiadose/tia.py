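"""Piecewise time-integrated activity over the three intervals I1/I2/I3.

A piecewise method is a (head rule, body rule, tail rule) triple:

* head (I1, from time 0 to the first sampled point, or to the second when
  the first point is excluded): ``constant_to_second_tp`` (rectangle at the
  second point's activity), ``linear_from_origin`` (line from (0, 0) to the
  first point), or ``model_extension`` (the fitted body model evaluated back
  to time 0);
* body (between the sampled points): a fitted exponential model or
  ``trapezoid`` interpolation (straight lines connecting the data points);
* tail (I3, beyond the last point to infinity): ``model_extension`` of the
  fitted body, ``monoexp_last3`` (effective decay rate fitted to the last
  three points, extrapolated from the last measured activity),
  ``physical_decay`` (radionuclide half-life only), or ``linear_to_zero``
  (the last segment's line continued to its zero crossing).

Reported interval contributions use a single comparability convention for
every method: I1 is the area from 0 to the FIRST time point, I2 from the
first to the last time point, I3 beyond the last point.  For constant-head
methods the rectangle's remainder over [t1, t2] is therefore booked into I2.
The split is exact: i1 + i2 + i3 == total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import FitResult, FitSpec, TimeActivitySeries, fit_curve
from .models import (
    LU177,
    DivergentIntegralError,
    NuclideConstants,
    PhysicalTailParams,
    eval_model,
    integral_closed_form,
    physical_tail_integral,
)

__all__ = [
    "PiecewiseTIAMethod", "TIAResult", "trapezoid_area", "compute_tia",
    "report_interval_contributions", "tail_fraction_check",
    "default_catalog", "catalog_from_config", "method_to_dict",
    "HEAD_RULES", "TAIL_RULES",
]

HEAD_RULES = ("constant_to_second_tp", "linear_from_origin", "model_extension")
TAIL_RULES = ("model_extension", "monoexp_last3", "physical_decay",
              "linear_to_zero")

#: EANM guidance: the extrapolated tail should contribute less than 20% of TIA
EANM_TAIL_FRACTION = 0.20


@dataclass(frozen=True)
class PiecewiseTIAMethod:
    """One catalog entry: head rule, body rule, tail rule."""

    method_id: str
    head_rule: str
    body_rule: Union[str, FitSpec]   # "trapezoid" or a FitSpec
    tail_rule: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.head_rule not in HEAD_RULES:
            raise ValueError(f"unknown head rule {self.head_rule!r}")
        if self.tail_rule not in TAIL_RULES:
            raise ValueError(f"unknown tail rule {self.tail_rule!r}")
        fitted = isinstance(self.body_rule, FitSpec)
        if not fitted and self.body_rule != "trapezoid":
            raise ValueError(
                f"body rule must be 'trapezoid' or a FitSpec, "
                f"got {self.body_rule!r}")
        if not fitted and (self.head_rule == "model_extension"
                           or self.tail_rule == "model_extension"):
            raise ValueError(
                "model_extension head/tail requires a fitted body model")
        if (fitted and self.head_rule == "constant_to_second_tp"
                and self.body_rule.points_used == "all"):
            raise ValueError(
                "constant_to_second_tp excludes the first point; the body "
                "fit must use points_used='from_second' or 'last_3'")

    @property
    def fitted_body(self) -> bool:
        return isinstance(self.body_rule, FitSpec)


@dataclass
class TIAResult:
    """Total TIA with the per-interval split and QC flags."""

    method_id: str
    total: float          # MBq*h (nan when the tail diverges)
    i1: float
    i2: float
    i3: float
    tail_fraction: float  # i3/total
    qc_flags: list = field(default_factory=list)
    fit: Optional[FitResult] = None


def trapezoid_area(series: TimeActivitySeries, a: float, b: float) -> float:
    """Integral of the piecewise-linear interpolant of the samples over [a, b].

    ``a`` and ``b`` must lie within the sampled time range.
    """
    t, act = series.t, series.a
    if a > b:
        raise ValueError(f"need a <= b, got a={a}, b={b}")
    if a < t[0] or b > t[-1]:
        raise ValueError(
            f"[{a}, {b}] h outside the sampled range [{t[0]}, {t[-1]}] h")
    interior = t[(t > a) & (t < b)]
    knots = np.concatenate([[a], interior, [b]])
    values = np.interp(knots, t, act)
    return float(np.trapezoid(values, knots))


def _fit_effective_last3(series: TimeActivitySeries,
                         constants: NuclideConstants) -> float:
    """Effective decay constant from an unweighted monoexp fit to the last
    three points."""
    spec = FitSpec(model_family="monoexp", points_used="last_3")
    fit = fit_curve(series, spec, constants)
    if not fit.converged or fit.params is None:
        raise DivergentIntegralError("last-3 monoexponential fit failed")
    return fit.params.lam


def _tail_integral(series: TimeActivitySeries, method: PiecewiseTIAMethod,
                   fit: Optional[FitResult], constants: NuclideConstants,
                   flags: list) -> float:
    t4 = series.t[-1]
    a4 = series.a[-1]
    if method.tail_rule == "physical_decay":
        return physical_tail_integral(PhysicalTailParams(
            A_p4=a4, t_p4=t4, lam_physical=constants.lam_physical))
    if method.tail_rule == "monoexp_last3":
        lam_eff = _fit_effective_last3(series, constants)
        if lam_eff <= 0:
            raise DivergentIntegralError(
                f"last-3 effective decay constant {lam_eff:.3g} <= 0")
        # extrapolate from the last measured point (continuous with the body)
        return a4 / lam_eff
    if method.tail_rule == "linear_to_zero":
        t3, a3 = series.t[-2], series.a[-2]
        slope = (a4 - a3) / (t4 - t3)
        if slope >= 0:
            raise DivergentIntegralError(
                f"last segment slope {slope:.3g} >= 0: a line to zero "
                "requires decreasing activity")
        return a4 * (a4 / -slope) / 2.0  # triangle down to the zero crossing
    # model_extension
    return integral_closed_form(fit.model_family, fit.params, t4, math.inf)


def compute_tia(series: TimeActivitySeries, method: PiecewiseTIAMethod,
                constants: NuclideConstants = LU177) -> TIAResult:
    """Piecewise TIA of one series under one catalog method.

    A divergent tail (fitted decay constant <= 0 with an infinite upper
    limit, or a non-decreasing last segment under ``linear_to_zero``) is
    reported as a ``divergent_tail`` QC flag with NaN totals rather than an
    exception; a body fit that fails to converge is flagged
    ``fit_not_converged`` the same way.
    """
    t, act = series.t, series.a
    if method.tail_rule == "monoexp_last3" and len(t) < 3:
        raise ValueError("monoexp_last3 tail requires >= 3 points")
    flags: list = []

    fit: Optional[FitResult] = None
    if method.fitted_body:
        fit = fit_curve(series, method.body_rule, constants)
        flags.extend(fit.warnings)
        if not fit.converged or fit.params is None:
            return TIAResult(method.method_id, math.nan, math.nan, math.nan,
                             math.nan, math.nan,
                             flags + ["fit_not_converged"], fit)

    t1 = t[0]
    body_start = t[1] if method.head_rule == "constant_to_second_tp" else t1

    # ---- head over [0, body_start] and its split at t1 ----
    if method.head_rule == "linear_from_origin":
        head = 0.5 * t1 * act[0]
        head_i1, head_i2 = head, 0.0
    elif method.head_rule == "constant_to_second_tp":
        a2, t2 = act[1], t[1]
        head = a2 * t2
        head_i1, head_i2 = a2 * t1, a2 * (t2 - t1)
    else:  # model_extension
        grid = np.linspace(0.0, body_start, 33)
        if np.any(np.asarray(eval_model(fit.model_family, fit.params, grid))
                  < -1e-12 * max(act.max(), 1.0)):
            flags.append("negative_model_head_clipped")
            head_i1 = max(integral_closed_form(
                fit.model_family, fit.params, 0.0, t1), 0.0)
            head_rest = max(integral_closed_form(
                fit.model_family, fit.params, t1, body_start), 0.0)
        else:
            head_i1 = integral_closed_form(fit.model_family, fit.params,
                                           0.0, t1)
            head_rest = integral_closed_form(fit.model_family, fit.params,
                                             t1, body_start)
        head_i2 = head_rest
        head = head_i1 + head_i2

    # ---- body over [body_start, t4] ----
    if method.fitted_body:
        body = integral_closed_form(fit.model_family, fit.params,
                                    body_start, t[-1])
        if body < 0:
            flags.append("negative_body_clipped")
            body = 0.0
    else:
        body = trapezoid_area(series, body_start, t[-1])

    # ---- tail over [t4, inf) ----
    try:
        tail = _tail_integral(series, method, fit, constants, flags)
    except DivergentIntegralError as err:
        flags.append("divergent_tail")
        return TIAResult(method.method_id, math.nan, math.nan, math.nan,
                         math.nan, math.nan, flags, fit)
    if tail < 0:
        flags.append("negative_tail_clipped")
        tail = 0.0

    i1 = head_i1
    i2 = head_i2 + body
    i3 = tail
    total = i1 + i2 + i3
    tail_fraction = i3 / total if total > 0 else math.nan
    result = TIAResult(method.method_id, total, i1, i2, i3, tail_fraction,
                       flags, fit)
    tail_fraction_check(result)
    return result


def tail_fraction_check(result: TIAResult,
                        threshold: float = EANM_TAIL_FRACTION) -> bool:
    """Flag ``tail_fraction_exceeds_20pct`` iff i3/total is STRICTLY above
    the threshold (guideline: the extrapolated contribution should be less
    than 20% of the TIA).  Returns True when the flag is raised."""
    flag = f"tail_fraction_exceeds_{round(threshold * 100):d}pct"
    raised = bool(result.tail_fraction > threshold)
    if raised and flag not in result.qc_flags:
        result.qc_flags.append(flag)
    return raised


def report_interval_contributions(
        series: TimeActivitySeries,
        methods: Sequence[PiecewiseTIAMethod],
        constants: NuclideConstants = LU177) -> pd.DataFrame:
    """Per-method I1/I2/I3 table for one series (one row per method).

    Interval contributions follow the uniform comparability convention
    (I1 = area from 0 to the first time point for every method, including
    constant-head ones).  Per-method failures are propagated as flagged
    NaN rows, not exceptions.
    """
    rows = []
    for method in methods:
        try:
            res = compute_tia(series, method, constants)
        except ValueError as err:
            res = TIAResult(method.method_id, math.nan, math.nan, math.nan,
                            math.nan, math.nan, [f"error: {err}"])
        rows.append({
            "region": series.region_id,
            "method_id": res.method_id,
            "i1": res.i1,
            "i2": res.i2,
            "i3": res.i3,
            "total": res.total,
            "tail_fraction": res.tail_fraction,
            "flags": ";".join(res.qc_flags),
        })
    return pd.DataFrame(rows)


def _fitspec(family: str, **kw) -> FitSpec:
    return FitSpec(model_family=family, **kw)


def default_catalog(include_biexp4: bool = True) -> List[PiecewiseTIAMethod]:
    """The default 11-method catalog spanning the attested head/body/tail
    combinations.

    Trapezoid bodies pair with the three explicit tails; exponential bodies
    extend into head and tail; the monoexponential appears constrained and
    unconstrained, on all points, on the last three, and on points 2-4; the
    biexponentials cover the zero-at-origin 3-parameter form and the
    ill-conditioned 4-parameter form.
    """
    cat = [
        PiecewiseTIAMethod(
            "m01", "linear_from_origin", "trapezoid", "physical_decay",
            "trapezoid body, physical-decay tail (most conservative)"),
        PiecewiseTIAMethod(
            "m02", "linear_from_origin", "trapezoid", "monoexp_last3",
            "trapezoid body, effective-decay tail from last 3 points"),
        PiecewiseTIAMethod(
            "m03", "constant_to_second_tp", "trapezoid", "monoexp_last3",
            "constant head to 2nd point, trapezoid body, effective tail"),
        PiecewiseTIAMethod(
            "m04", "linear_from_origin", "trapezoid", "linear_to_zero",
            "trapezoid body, last segment extended linearly to zero"),
        PiecewiseTIAMethod(
            "m05", "model_extension",
            _fitspec("monoexp", constrain_lambda_physical=True),
            "model_extension",
            "monoexp, decay constant constrained >= physical"),
        PiecewiseTIAMethod(
            "m06", "model_extension", _fitspec("monoexp"), "model_extension",
            "monoexp, unconstrained"),
        PiecewiseTIAMethod(
            "m07", "linear_from_origin",
            _fitspec("monoexp", points_used="last_3"), "model_extension",
            "linear uptake head, monoexp on last 3 points"),
        PiecewiseTIAMethod(
            "m08", "constant_to_second_tp",
            _fitspec("monoexp", points_used="from_second"), "model_extension",
            "constant head to 2nd point, monoexp on points 2-4"),
        PiecewiseTIAMethod(
            "m09", "model_extension", _fitspec("biexp3"), "model_extension",
            "3-parameter biexponential (zero at origin)"),
        PiecewiseTIAMethod(
            "m10", "linear_from_origin",
            _fitspec("monoexp", constrain_lambda_physical=True,
                     points_used="last_3"),
            "model_extension",
            "linear head, constrained monoexp on last 3 points"),
    ]
    if include_biexp4:
        cat.append(PiecewiseTIAMethod(
            "m11", "model_extension", _fitspec("biexp4"), "model_extension",
            "4-parameter biexponential (ill-conditioned on 4 points)"))
    return cat


def method_to_dict(method: PiecewiseTIAMethod) -> dict:
    d = {
        "method_id": method.method_id,
        "head_rule": method.head_rule,
        "tail_rule": method.tail_rule,
        "description": method.description,
    }
    if method.fitted_body:
        spec = method.body_rule
        d["body_rule"] = {
            "model_family": spec.model_family,
            "constrain_lambda_physical": spec.constrain_lambda_physical,
            "weighting": spec.weighting,
            "points_used": spec.points_used,
        }
    else:
        d["body_rule"] = "trapezoid"
    return d


def catalog_from_config(entries: Sequence[dict]) -> List[PiecewiseTIAMethod]:
    """Build a catalog from config dictionaries (the inverse of
    :func:`method_to_dict`)."""
    methods = []
    for e in entries:
        body = e["body_rule"]
        if isinstance(body, dict):
            body = FitSpec(**body)
        methods.append(PiecewiseTIAMethod(
            method_id=e["method_id"],
            head_rule=e["head_rule"],
            body_rule=body,
            tail_rule=e["tail_rule"],
            description=e.get("description", ""),
        ))
    return methods
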