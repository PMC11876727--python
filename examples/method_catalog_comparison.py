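"""Compare the TIA method catalog on one noisy lesion curve.

Samples a lesion with an uptake phase (zero-at-origin biexponential) at the
patient B schedule with 5% noise, runs all 11 catalog methods, and prints
each method's interval contributions I1 (before the first scan), I2 (between
scans), I3 (extrapolated beyond the last scan) and the tail fraction.  The
spread in I3 dominates the across-method spread in total TIA, and the
physical-decay tail (m01) sits at the conservative top; tail fractions above
20% are flagged against the extrapolation guideline.
"""

import numpy as np

from tiadose import (
    BiExp3Params,
    RegionKineticsSpec,
    default_catalog,
    make_truth,
    report_interval_contributions,
    sample_series,
)

spec = RegionKineticsSpec(
    "lesion1", "lesion", BiExp3Params(A=150.0, lam1=0.008, lam2=0.12),
    schedule="patientB", noise_sd=0.05)
truth = make_truth(spec)
series = sample_series(truth, spec, seed=11)

table = report_interval_contributions(series, default_catalog())
print(f"ground-truth TIA: {truth.tia:.0f} MBq*h\n")
print(table.round({"i1": 0, "i2": 0, "i3": 0, "total": 0,
                   "tail_fraction": 3}).to_string(index=False))

ok = table[np.isfinite(table["total"])]
spread = {c: ok[c].max() - ok[c].min() for c in ("i1", "i2", "i3")}
print(f"\nacross-method spread (max - min, MBq*h): "
      f"I1 = {spread['i1']:.0f}, I2 = {spread['i2']:.0f}, "
      f"I3 = {spread['i3']:.0f}")
print("The extrapolated interval I3 drives the method-to-method variability.")
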