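# tiadose

Time–activity curve fitting, time-integrated activity (TIA) and
absorbed-dose (AD) variability analysis for radiopharmaceutical-therapy
dosimetry.

## The problem

Internal dosimetry after a therapeutic injection (e.g. a ¹⁷⁷Lu-labelled
agent) starts from a handful of organ/lesion activity measurements —
typically four quantitative SPECT/CT time points over one to eight days.
The activity curve A(t) must be interpolated between the scans, extrapolated
back to injection and forward to infinity, and integrated:

    TIA = ∫₀^∞ A(t) dt        (MBq·h)
    AD  = TIA × S             (Gy, with S the self-dose factor in Gy/(MBq·h))

Different centers make different choices at every step — which model, which
points, whether the decay constant is constrained to be at least the
physical one, how the tail beyond the last scan is extrapolated — and those
choices alone spread the reported doses. `tiadose` packages the whole chain
so that this spread can be measured, decomposed and reproduced:

* **curve models** — monoexponential `A·e^(−λt)`, the zero-at-origin
  biexponential `A·(e^(−λ₁t) − e^(−λ₂t))` for uptake-then-washout kinetics,
  and the 4-parameter biexponential `A₁e^(−λ₁t) + A₂e^(−λ₂t)`, all with
  exact closed-form integrals including the improper tail to infinity;
* **fitting** — deterministic least squares (Levenberg–Marquardt, or a
  bounded trust-region solver when λ ≥ λ_physical is enforced), optional
  relative or user-supplied weighting, point-subset selectors, R²/AIC/AICc
  diagnostics and sanity flags (ill-conditioned 4-parameter fits on 4
  points, non-physiological back-extrapolated t=0 activity);
* **piecewise TIA** — an 11-method catalog of (head, body, tail) rules over
  the three intervals I1 (before the first scan), I2 (between scans) and I3
  (beyond the last scan), including trapezoid bodies with physical-decay,
  effective-decay or linear-to-zero tails, with per-interval contributions
  and the <20% extrapolation-fraction guideline check;
* **dose conversion** — self-dose factors with optional inverse-mass
  scaling, mass-weighted kidney combination, decay-correction convention
  handling, healthy-organ TIA with contained-lesion subtraction;
* **variability statistics** — quartile coefficient of dispersion
  QCD = (Q3−Q1)/(Q3+Q1), IQR with 1.5×IQR outlier fences, the per-region
  QCD difference between a "fit it yourself" task and a "shared reference
  TIA" task, and the paired ΔAD/mean analysis;
* **synthetic cohorts** — a seeded generator of virtual multi-center
  challenges on two 4-time-point patient schedules, with injectable
  participant error modes (missed decay-correction undo, lesions counted in
  healthy liver, unweighted kidney summation).

## Worked example

`examples/virtual_cohort_variability.py` simulates a 24-participant
challenge on the patient A design (scans at 3.7, 27.7, 103.1 and 124.0 h,
series released decay-corrected to injection time, 5% sampling noise, a few
participants committing classic bookkeeping errors) and prints:

```
QCD(task4) - QCD(task5) per region, percentage points:
    kidney_left:   16.5
   kidney_right:   16.0
   kidney_total:   17.5
        lesion1:   11.5
        lesion2:   12.9
          liver:   19.0
         spleen:   16.1

paired dAD / mean(task5 AD):
    kidney_left: median -0.006  IQR 0.381  outliers: -
   kidney_right: median +0.000  IQR 0.370  outliers: -
   kidney_total: median -0.009  IQR 0.313  outliers: P017
        lesion1: median +0.091  IQR 0.266  outliers: P007, P012, P014, P024
        lesion2: median +0.210  IQR 0.325  outliers: P008
          liver: median +0.022  IQR 0.457  outliers: P005
         spleen: median +0.007  IQR 0.370  outliers: -
```

Each QCD difference is the dispersion added by letting participants fit
their own curves instead of sharing one reference TIA — the fitting- and
integration-attributable variability.  The paired analysis normalises each
participant's task-4 minus task-5 dose difference by the cohort-mean task-5
dose; its IQR measures across-method disagreement, and the flagged outliers
trace back to the injected error modes.  The other example scripts fit a
single series (`fit_single_series.py`), compare the full method catalog on
one lesion curve (`method_catalog_comparison.py`), and quantify the
decay-correction pitfall (`decay_correction_pitfall.py`).

A thin CLI wraps the same functions:

```
tiadose simulate --seed 3 --out cohort.csv
tiadose variability cohort.csv
tiadose run --config config.yaml
```

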