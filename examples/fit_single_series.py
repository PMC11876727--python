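"""Fit exponential washout models to one organ's 4-point time-activity data.

Builds a noiseless kidney-like series sampled at 3.7, 27.7, 103.1 and
124.0 h post-injection, fits the monoexponential (constrained and
unconstrained) and the 3-parameter biexponential, and prints parameters and
goodness-of-fit metrics.  The recovered decay constant is the effective
(physical + biological) clearance rate in 1/h; R^2 near 1 and a low AIC mark
the model the data supports.
"""

import numpy as np

from tiadose import (
    FitSpec,
    MonoExpParams,
    SCHEDULES,
    TimeActivitySeries,
    eval_model,
    fit_curve,
)

true = MonoExpParams(A=100.0, lam=0.013)  # 100 MBq at t=0, T1/2,eff ~ 53 h
times = SCHEDULES["patientA"]
activities = eval_model("monoexp", true, np.asarray(times))
series = TimeActivitySeries("kidney_left", times, tuple(activities))

for label, spec in [
    ("monoexp (unconstrained)", FitSpec("monoexp")),
    ("monoexp (lam >= physical)", FitSpec("monoexp",
                                          constrain_lambda_physical=True)),
    ("biexp3", FitSpec("biexp3")),
]:
    fit = fit_curve(series, spec)
    print(f"{label}:")
    print(f"  params = {fit.params}")
    print(f"  R^2 = {fit.r_squared:.6f}   AIC = {fit.aic:.2f}   "
          f"warnings = {fit.warnings}")

print("\nThe unconstrained monoexponential recovers the generating "
      "parameters (A = 100 MBq, lam = 0.013 / h) exactly; the biexponential "
      "collapses onto the same washout because the data contain no uptake "
      "phase.")
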