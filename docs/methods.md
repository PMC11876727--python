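# Methods

## Models and units

Time is hours post-injection, activity MBq, TIA MBq·h, absorbed dose Gy.
Three time–activity model families are supported:

* monoexponential `A·e^(−λt)` — instantaneous uptake, single washout phase;
  appropriate for most healthy organs.
* 3-parameter biexponential `A·(e^(−λ₁t) − e^(−λ₂t))` with uptake rate
  λ₂ > washout rate λ₁ — exactly zero at t = 0, the natural model for
  lesions and slow-uptake organs.  When the fitted rates coincide to within
  1e-9 relative the evaluation switches to the limit form `A·λ·t·e^(−λt)`
  (and its antiderivative), which keeps evaluation and integration finite
  and continuous in the parameters along that ridge.
* 4-parameter biexponential `A₁e^(−λ₁t) + A₂e^(−λ₂t)` — amplitudes may be
  negative (a negative fast phase represents uptake).  Fitted to exactly
  four points the problem is ill-conditioned (parameters = data points) and
  is always flagged `ill_conditioned_4param`; the fit is still performed
  because the point of this package is to measure what such choices do.

All integrals, including the improper tail to infinity, use the analytic
antiderivative term by term; an improper integral with a non-positive decay
constant raises a catchable `DivergentIntegralError`.

The physical decay constant defaults to ¹⁷⁷Lu with a half-life of 6.6475 d
(published nuclear data; the value is configurable, so the package is
radionuclide-agnostic).

## Fitting

Unweighted nonlinear least squares via Levenberg–Marquardt with tight
termination (ftol = xtol = gtol = 1e-14, generous evaluation budget).  When
the decay constants are constrained to be ≥ λ_physical, the free optimum is
used directly if it already satisfies the bound (it is then the constrained
minimum); otherwise a bounded trust-region solver enforces the box and rates
that converge onto the bound are snapped to it exactly.  The contract is "a
least-squares minimum respecting the bounds", not a specific algorithm.

Initial guesses are deterministic closed forms: log-linear regression for
the monoexponential; for the biexponentials the washout rate from the last
segment, an uptake rate 10× faster, and amplitudes scaled to the observed
peak.  No random restarts are performed by default, so a fit is a pure
function of (series, spec).  Degenerate rate estimates are clipped to a
floor of 1e-6 /h.

Weighting options: `unweighted` (default, matching the baseline analysis
this package is built around), `relative` (σᵢ ∝ activityᵢ, floored at 1% of
the peak so zero-activity points cannot dominate), or a user-supplied σ
vector.  The relative scheme is this package's own simple heteroscedasticity
model, not a reimplementation of any published error model.

Diagnostics per fit: R², AIC = n·ln(RSS/n) + 2k, AICc (reported as undefined
when n − k − 1 ≤ 0, which is always the case for the 4-parameter model on
four points), the residual table, and a `nonphysiological_t0_activity` flag
when the back-extrapolated activity at t = 0 exceeds the injected activity.

## Piecewise TIA and the method catalog

A method is a (head, body, tail) triple over the intervals I1 = [0, t₁],
I2 = [t₁, t₄], I3 = [t₄, ∞).  Heads: linear from (0,0) to the first point;
constant at the *second* point's activity over [0, t₂] (the first point
excluded from both head and body fit); or the fitted body model extended to
0 (negative model values clipped at zero with a warning).  Bodies: a fitted
model or trapezoidal interpolation.  Tails: the fitted model extended to
infinity; a monoexponential effective rate fitted to the last three points;
physical decay from the last point; or the last segment's line continued to
its zero crossing (an error when the segment does not decrease).

Two deliberate conventions:

* **Reported interval split.**  Every method reports I1 as the area from 0
  to the *first* time point, so constant-head methods are comparable with
  the rest; the rectangle's remainder over [t₁, t₂] is booked into I2.  The
  split is exact: i1 + i2 + i3 == total.
* **Effective tail anchored at the last measurement.**  The `monoexp_last3`
  tail integrates `A(t₄)·e^(−λ_eff(t−t₄))`, i.e. the effective rate comes
  from the last-3 fit but the amplitude is the measured last point.  This
  keeps the piecewise curve continuous with a trapezoid body and makes the
  ordering "physical-decay tail ≥ effective tail whenever λ_eff ≥
  λ_physical" an exact identity (A(t₄)/λ_phys vs A(t₄)/λ_eff) rather than a
  statistical tendency.

The default catalog holds 11 methods spanning the attested combinations:
four trapezoid-body variants (physical, effective ×2 heads, linear-to-zero
tails), constrained and unconstrained monoexponentials on all points, the
last three points, and points 2–4, the 3-parameter biexponential (two
heads), and the 4-parameter biexponential.  The full published enumeration
of such catalogs is not reconstructible in general, so the catalog is
configurable (YAML/JSON) and the default is a representative spanning set.

Tail fractions i3/total are checked against the guideline that the
extrapolated contribution should be *less than* 20% of the TIA; the flag
uses a strict inequality, so exactly 20% passes.

## Dose conversion

AD = TIA × S with per-region self-dose factors (Gy/(MBq·h)) and masses from
an editable CSV; optional inverse-mass rescaling of S by
reference_mass/actual_mass (the standard organ-level approximation,
documented as such).  The model is deliberately self-dose-only: cross-organ
photon dose and voxel kernels live downstream of the variability questions
this package addresses.  The shipped factors are synthetic placeholders
with plausible magnitudes, not claims about any phantom library.

Bookkeeping utilities implement the three classic pitfalls exactly:

* decay-correction conventions — `corrected_to_injection` values equal
  as-measured values × e^(+λ_phys·t); `corrected_to_scan_start` is
  numerically the identity for organ-level series because each sample's
  reference time is its own acquisition time; conversions are exact
  inverses, so a round trip reproduces the input bitwise (up to floating
  multiplication);
* the "total kidney" AD is the mass-weighted average of the two kidneys;
  the naive sum strictly exceeds it whenever both doses are positive;
* healthy-organ TIA subtracts contained-lesion TIA; a negative result
  raises rather than silently clipping.

## Variability statistics

QCD = (Q3 − Q1)/(Q3 + Q1); IQR = Q3 − Q1 with outliers strictly outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] (values exactly on a fence are kept).  The
quantile convention defaults to linear interpolation between order
statistics and is selectable among the standard conventions, because QCD
shifts slightly across them.  Percentages are reported to one decimal
place.  The paired analysis uses only participants present in both tasks
for a region and normalises by the cohort-mean task-5 dose (not each
participant's own); regions with fewer than two paired participants are
flagged, not summarised.  Rows whose AD could not be computed (divergent
tails, failed fits) are dropped before summarising.

## Synthetic cohort generator

The generator emulates a two-patient, four-time-point study design:
schedules 3.7/27.7/103.1/124.0 h ("patient A", series released
decay-corrected to injection time) and 3.7/32.6/99.6/193.3 h ("patient B",
corrected to scan start).  Default regions: a liver (monoexp, effective
T½ ≈ 69 h) with two contained lesions (biexponential; bulky for A, small
for B), a spleen (A only), and two kidneys (fast monoexponential for A,
slow-uptake biexponential for B).  All washout rates exceed λ_physical, as
they must for a tracer that clears.  Amplitudes are illustrative
round numbers on the scale of a several-GBq injection; no claim of matching
any specific patient is made.

Noise is multiplicative Gaussian on each sample (default sd 5%, truncated
at zero), chosen for transparency over any published error model; it stands
in for the region-level quantification differences between participants
applying the same volumes of interest.  It does not emulate image formation,
segmentation differences, partial-volume effects or voxel-level
registration artifacts — so passing tests show the fitting/integration
chain behaves correctly and the statistics respond as designed, not that
real inter-center variability is numerically predicted.

A virtual cohort draws, per participant: a catalog method from a frequency
table (uniform by default), a software class label, independent Bernoulli
error modes, and an independent noisy sampling of every region.  Task-4
doses go through the participant's full fit→TIA→dose chain; task-5 doses
push the shared ground-truth TIA through only the participant's dose step,
so the task difference isolates fitting/integration (plus injected
dose-step errors, as in the real design).  A cohort is a pure function of
(regions, config): the seed fans out through a seed sequence, and identical
inputs give byte-identical CSVs.

## Problem sizes and numerical choices

The acceptance checks run 1000 random parameter draws per family against
adaptive quadrature (1e-6 relative for finite integrals, 1e-4 against
quadrature truncated at 20 half-lives for improper ones), 500 random
datasets for the constraint contract, 500 washout series for the
tail-ordering identity, 1000 random vectors against a brute-force
order-statistic oracle, and 100 seeded 24-participant cohorts for the
dispersion analysis.  The acceptance script uses 24 participants per
patient, 5% noise, and error rates of 12.5% per mode — a cohort size and
error prevalence chosen to mirror a realistic challenge round.

Known limitations: the triexponential family is not implemented (no
defining equations to hand); voxel-level fitting, image I/O and
segmentation are out of scope; the dose model ignores cross-organ dose;
and the "linear decay after the last point" rule is implemented as the
last segment's line continued to its zero crossing — one of several
readings of that phrase, isolated behind a single configurable tail rule.
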