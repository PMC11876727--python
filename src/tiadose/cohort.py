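"""Synthetic ground-truth kinetics and virtual multi-center cohorts.

The generator emulates the structure of a multi-center dosimetry challenge
on two virtual patients imaged at four time points:

* patient A schedule: 3.7, 27.7, 103.1, 124.0 h post-injection;
* patient B schedule: 3.7, 32.6, 99.6, 193.3 h post-injection.

Healthy organs take up the agent almost instantaneously and follow a
monoexponential washout; lesions (and patient B's slower kidneys) show an
uptake phase followed by washout, i.e. the zero-at-origin biexponential.
Sampled activities carry multiplicative Gaussian noise (default sd 5%,
truncated so activities stay non-negative), emulating the region-level
quantification spread between participants applying the same volumes of
interest.

A virtual cohort pairs two tasks: in task 4 every participant fits their own
sampled curves with a method drawn from a frequency table over the catalog;
in task 5 all participants share the reference (ground-truth) TIA and differ
only in the dose-conversion step.  Three documented participant error modes
can be injected at configurable rates:

* ``skip_decay_uncorrection`` -- activities released decay-corrected to the
  injection time are used as-is, inflating each point by
  exp(+lam_physical * t_i);
* ``include_lesions_in_liver`` -- lesions contained in the liver are counted
  toward the healthy-liver activity;
* ``sum_kidneys_unweighted`` -- the "total kidney" AD is the plain sum of
  the two kidneys instead of their mass-weighted average.

A cohort is a pure function of (regions, config): identical inputs yield
byte-identical cohort tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dose import (
    DoseFactorTable,
    apply_decay_correction,
    combine_kidneys,
    healthy_organ_tia,
    tia_to_ad,
)
from .fitting import TimeActivitySeries
from .models import (
    LU177,
    BiExp3Params,
    ModelParams,
    MonoExpParams,
    NuclideConstants,
    eval_model,
    integral_closed_form,
)
from .tia import PiecewiseTIAMethod, compute_tia, default_catalog

__all__ = [
    "SCHEDULES", "RegionKineticsSpec", "CohortConfig", "TruthRecord",
    "make_truth", "sample_series", "default_regions", "default_dose_factors",
    "simulate_cohort", "recovery_suite", "ERROR_MODES",
]

SCHEDULES: Dict[str, Tuple[float, ...]] = {
    "patientA": (3.7, 27.7, 103.1, 124.0),
    "patientB": (3.7, 32.6, 99.6, 193.3),
}

REGION_CLASSES = ("organ_instant_uptake", "organ_slow_uptake", "lesion")

ERROR_MODES = ("skip_decay_uncorrection", "include_lesions_in_liver",
               "sum_kidneys_unweighted")


@dataclass(frozen=True)
class RegionKineticsSpec:
    """Ground-truth kinetics of one region and how it is sampled."""

    region_id: str
    region_class: str
    params: ModelParams
    schedule: Union[str, Tuple[float, ...]] = "patientA"
    noise_sd: float = 0.05           # multiplicative Gaussian sd (fraction)
    decay_convention: str = "none"   # convention of the emitted series
    contained_in: Optional[str] = None  # parent organ for lesions
    constants: NuclideConstants = LU177

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        lam_p = self.constants.lam_physical
        if self.region_class == "organ_instant_uptake":
            if not isinstance(self.params, MonoExpParams):
                raise ValueError(
                    "organ_instant_uptake requires monoexponential params")
            if self.params.lam < lam_p:
                raise ValueError(
                    f"{self.region_id}: effective decay constant "
                    f"{self.params.lam} below physical {lam_p:.6g}")
        else:
            if not isinstance(self.params, BiExp3Params):
                raise ValueError(
                    f"{self.region_class} requires zero-at-origin "
                    "biexponential params")
            if self.params.lam1 < lam_p:
                raise ValueError(
                    f"{self.region_id}: washout constant {self.params.lam1} "
                    f"below physical {lam_p:.6g}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def model_family(self) -> str:
        return self.params.family

    @property
    def times(self) -> Tuple[float, ...]:
        if isinstance(self.schedule, str):
            return SCHEDULES[self.schedule]
        return tuple(self.schedule)


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters and the exact closed-form TIA of a region."""

    region_id: str
    model_family: str
    params: ModelParams
    tia: float  # MBq*h, integral over [0, inf)


def make_truth(spec: RegionKineticsSpec, seed: Optional[int] = None
               ) -> TruthRecord:
    """Exact ground truth of a region (deterministic; the seed is accepted
    for interface symmetry with :func:`sample_series` and unused)."""
    tia = integral_closed_form(spec.model_family, spec.params, 0.0, math.inf)
    return TruthRecord(spec.region_id, spec.model_family, spec.params, tia)


def sample_series(truth: TruthRecord, spec: RegionKineticsSpec,
                  seed: Union[int, np.random.Generator, None] = 0
                  ) -> TimeActivitySeries:
    """Sample the truth curve at the schedule with multiplicative noise.

    activities = model(t_i) * (1 + eps_i), eps_i ~ N(0, sd^2), truncated so
    activities stay >= 0; the series is emitted in the spec's decay
    convention.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.asarray(spec.times, dtype=float)
    clean = np.asarray(eval_model(truth.model_family, truth.params, t))
    noise = rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd > 0 \
        else np.zeros_like(t)
    activities = np.maximum(clean * (1.0 + noise), 0.0)
    series = TimeActivitySeries(
        region_id=truth.region_id,
        times=tuple(t),
        activities=tuple(activities),
        decay_convention="none",
    )
    if spec.decay_convention != "none":
        series = apply_decay_correction(series, spec.decay_convention,
                                        spec.constants)
    return series


def default_regions(patient: str = "A", noise_sd: float = 0.05,
                    decay_convention: Optional[str] = None,
                    constants: NuclideConstants = LU177
                    ) -> List[RegionKineticsSpec]:
    """Default region set mirroring a two-patient study design.

    Patient A: liver with two contained lesions, spleen, two fast-uptake
    kidneys; series released decay-corrected to injection time.  Patient B:
    liver with two contained lesions, two slow-uptake kidneys; series
    released corrected to scan start (numerically as-measured).  Washout
    effective half-lives are all shorter than the physical half-life.
    """
    if patient not in ("A", "B"):
        raise ValueError("patient must be 'A' or 'B'")
    sched = "patientA" if patient == "A" else "patientB"
    if decay_convention is None:
        decay_convention = ("corrected_to_injection" if patient == "A"
                            else "corrected_to_scan_start")
    kw = dict(schedule=sched, noise_sd=noise_sd,
              decay_convention=decay_convention, constants=constants)
    regions = [
        RegionKineticsSpec("liver", "organ_instant_uptake",
                           MonoExpParams(A=350.0, lam=0.010), **kw),
    ]
    if patient == "A":
        # two bulky liver lesions carrying a large share of the organ TIA
        regions += [
            RegionKineticsSpec("lesion1", "lesion",
                               BiExp3Params(A=150.0, lam1=0.008, lam2=0.12),
                               contained_in="liver", **kw),
            RegionKineticsSpec("lesion2", "lesion",
                               BiExp3Params(A=80.0, lam1=0.0065, lam2=0.06),
                               contained_in="liver", **kw),
            RegionKineticsSpec("spleen", "organ_instant_uptake",
                               MonoExpParams(A=120.0, lam=0.011), **kw),
            RegionKineticsSpec("kidney_left", "organ_instant_uptake",
                               MonoExpParams(A=85.0, lam=0.013), **kw),
            RegionKineticsSpec("kidney_right", "organ_instant_uptake",
                               MonoExpParams(A=80.0, lam=0.0125), **kw),
        ]
    else:
        # small liver lesions, slow-uptake kidneys
        regions += [
            RegionKineticsSpec("lesion1", "lesion",
                               BiExp3Params(A=30.0, lam1=0.009, lam2=0.10),
                               contained_in="liver", **kw),
            RegionKineticsSpec("lesion2", "lesion",
                               BiExp3Params(A=18.0, lam1=0.0075, lam2=0.08),
                               contained_in="liver", **kw),
            RegionKineticsSpec("kidney_left", "organ_slow_uptake",
                               BiExp3Params(A=95.0, lam1=0.011, lam2=0.09),
                               **kw),
            RegionKineticsSpec("kidney_right", "organ_slow_uptake",
                               BiExp3Params(A=90.0, lam1=0.0105, lam2=0.10),
                               **kw),
        ]
    return regions


def default_dose_factors(regions: Sequence[RegionKineticsSpec]
                         ) -> DoseFactorTable:
    """Synthetic self-dose factors and masses for the default regions.

    Values are plausible organ-level magnitudes for a beta emitter but are
    deliberately generic placeholders, editable via CSV.
    """
    defaults = {
        "liver": (1.2e-4, 1800.0),
        "spleen": (3.0e-4, 180.0),
        "kidney_left": (2.4e-4, 150.0),
        "kidney_right": (2.4e-4, 140.0),
        "lesion1": (8.0e-4, 30.0),
        "lesion2": (9.0e-4, 20.0),
    }
    table = DoseFactorTable()
    for spec in regions:
        factor, mass = defaults.get(spec.region_id, (5.0e-4, 50.0))
        table.add(spec.region_id, factor, mass, reference_mass=mass)
    return table


@dataclass(frozen=True)
class CohortConfig:
    """Virtual-cohort design: size, method mix, error rates, seed."""

    n_participants: int = 24
    method_freq: Optional[Dict[str, float]] = None  # None -> uniform
    error_rates: Dict[str, float] = field(default_factory=dict)
    software_class_mix: Dict[str, float] = field(
        default_factory=lambda: {"in_house": 0.5, "commercial": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for mode, rate in self.error_rates.items():
            if mode not in ERROR_MODES:
                raise ValueError(f"unknown error mode {mode!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"error rate for {mode} must be in [0, 1]")
        if self.method_freq is not None:
            tot = sum(self.method_freq.values())
            if not math.isclose(tot, 1.0, rel_tol=1e-9):
                raise ValueError(f"method frequencies must sum to 1, got {tot}")


def _whole_organ_series(organ: TimeActivitySeries,
                        lesions: Sequence[TimeActivitySeries]
                        ) -> TimeActivitySeries:
    """Organ series including contained lesions (activities add pointwise)."""
    total = organ.a.copy()
    for les in lesions:
        total = total + les.a
    return organ.with_activities(total)


def simulate_cohort(regions: Sequence[RegionKineticsSpec],
                    config: CohortConfig,
                    catalog: Optional[Sequence[PiecewiseTIAMethod]] = None,
                    dose_table: Optional[DoseFactorTable] = None,
                    constants: NuclideConstants = LU177
                    ) -> Tuple[pd.DataFrame, dict]:
    """Simulate a two-task virtual cohort.

    Task 4: each participant samples their own noisy series per region,
    (correctly or not) normalises the decay convention, fits/integrates with
    their drawn catalog method, and converts TIA to AD.  Task 5: one shared
    reference TIA per region (the ground truth) goes through each
    participant's dose-conversion step only.  Returns the cohort table (one
    row per participant x task x region) and a ground-truth ledger.
    """
    if catalog is None:
        catalog = default_catalog()
    if dose_table is None:
        dose_table = default_dose_factors(regions)
    methods = {m.method_id: m for m in catalog}
    if config.method_freq is None:
        ids = sorted(methods)
        probs = np.full(len(ids), 1.0 / len(ids))
    else:
        ids = sorted(config.method_freq)
        missing = set(ids) - set(methods)
        if missing:
            raise ValueError(f"method_freq references unknown methods: {missing}")
        probs = np.array([config.method_freq[i] for i in ids], dtype=float)

    sw_ids = sorted(config.software_class_mix)
    sw_probs = np.array([config.software_class_mix[s] for s in sw_ids])
    sw_probs = sw_probs / sw_probs.sum()

    specs = {s.region_id: s for s in regions}
    truths = {s.region_id: make_truth(s) for s in regions}
    lesion_parents: Dict[str, List[str]] = {}
    for s in regions:
        if s.contained_in:
            lesion_parents.setdefault(s.contained_in, []).append(s.region_id)

    # reference (task-5) TIAs: healthy-organ truth for organs with lesions
    ref_tia: Dict[str, float] = {}
    for rid, truth in truths.items():
        ref_tia[rid] = truth.tia
    has_kidneys = "kidney_left" in specs and "kidney_right" in specs

    seed_seq = np.random.SeedSequence(config.seed)
    child_seqs = seed_seq.spawn(config.n_participants)

    rows: List[dict] = []
    ledger_participants = []
    for p_idx, child in enumerate(child_seqs):
        rng = np.random.default_rng(child)
        pid = f"P{p_idx + 1:03d}"
        method_id = str(rng.choice(ids, p=probs))
        method = methods[method_id]
        software = str(rng.choice(sw_ids, p=sw_probs))
        errors = {mode: bool(rng.random() < config.error_rates.get(mode, 0.0))
                  for mode in ERROR_MODES}

        # each participant's own noisy sampling of every region
        series: Dict[str, TimeActivitySeries] = {
            rid: sample_series(truths[rid], specs[rid], rng)
            for rid in specs
        }

        def working_series(s: TimeActivitySeries) -> TimeActivitySeries:
            if errors["skip_decay_uncorrection"]:
                # activities used exactly as released, whatever the convention
                return s.with_activities(s.a, decay_convention="none")
            return apply_decay_correction(s, "none", constants)

        # ---- task 4: fit -> TIA -> AD ----
        tia4: Dict[str, float] = {}
        flags: Dict[str, str] = {}
        for rid in specs:
            s = series[rid]
            if rid in lesion_parents and errors["include_lesions_in_liver"]:
                s = _whole_organ_series(s, [series[l]
                                            for l in lesion_parents[rid]])
            s = working_series(s)
            try:
                res = compute_tia(s, method, constants)
                tia4[rid] = res.total
                flags[rid] = ";".join(res.qc_flags)
            except ValueError as err:
                tia4[rid] = math.nan
                flags[rid] = f"error: {err}"

        ad4 = {rid: (tia_to_ad(t, rid, dose_table)
                     if math.isfinite(t) else math.nan)
               for rid, t in tia4.items()}
        ad5 = {rid: tia_to_ad(ref_tia[rid], rid, dose_table) for rid in specs}

        if has_kidneys:
            ml = dose_table["kidney_left"].mass
            mr = dose_table["kidney_right"].mass
            for ad, label in ((ad4, "task4"), (ad5, "task5")):
                left, right = ad["kidney_left"], ad["kidney_right"]
                if errors["sum_kidneys_unweighted"]:
                    ad["kidney_total"] = left + right
                else:
                    ad["kidney_total"] = combine_kidneys(left, ml, right, mr)

        for rid in sorted(ad4):
            rows.append({
                "participant_id": pid, "task": "task4", "region": rid,
                "ad_Gy": ad4[rid], "method_id": method_id,
                "software_class": software,
            })
        for rid in sorted(ad5):
            rows.append({
                "participant_id": pid, "task": "task5", "region": rid,
                "ad_Gy": ad5[rid], "method_id": "shared_tia",
                "software_class": software,
            })
        ledger_participants.append({
            "participant_id": pid,
            "method_id": method_id,
            "software_class": software,
            "errors": {k: v for k, v in errors.items() if v},
            "tia_task4": {k: tia4[k] for k in sorted(tia4)},
            "qc_flags": {k: v for k, v in flags.items() if v},
        })

    cohort = pd.DataFrame(rows,
                          columns=["participant_id", "task", "region",
                                   "ad_Gy", "method_id", "software_class"])
    ledger = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "truth_tia_MBq_h": {k: truths[k].tia for k in sorted(truths)},
        "reference_tia_MBq_h": {k: ref_tia[k] for k in sorted(ref_tia)},
        "participants": ledger_participants,
    }
    return cohort, ledger


def recovery_suite(regions: Sequence[RegionKineticsSpec],
                   catalog: Optional[Sequence[PiecewiseTIAMethod]] = None,
                   n_replicates: int = 100,
                   seed: int = 0,
                   constants: NuclideConstants = LU177) -> pd.DataFrame:
    """Bias and spread of TIA versus truth per region x method.

    Each replicate draws a fresh noisy series (in the 'none' convention, to
    isolate fitting/integration from bookkeeping errors), runs every catalog
    method, and records the relative TIA error.  Returns one row per
    region x method with median/mean relative bias and IQR spread.
    """
    if catalog is None:
        catalog = default_catalog()
    rows = []
    seq = np.random.SeedSequence(seed)
    for spec in regions:
        spec_none = replace(spec, decay_convention="none")
        truth = make_truth(spec_none)
        rel_err: Dict[str, List[float]] = {m.method_id: [] for m in catalog}
        child = np.random.default_rng(seq.spawn(1)[0])
        for _ in range(n_replicates):
            series = sample_series(truth, spec_none, child)
            for method in catalog:
                try:
                    res = compute_tia(series, method, constants)
                    err = (res.total - truth.tia) / truth.tia
                except ValueError:
                    err = math.nan
                rel_err[method.method_id].append(err)
        for mid, errs in rel_err.items():
            e = np.asarray(errs)
            ok = e[np.isfinite(e)]
            q1, q3 = (np.quantile(ok, [0.25, 0.75]) if ok.size
                      else (math.nan, math.nan))
            rows.append({
                "region": spec.region_id,
                "method_id": mid,
                "n_ok": int(ok.size),
                "rel_bias_median": float(np.median(ok)) if ok.size else math.nan,
                "rel_bias_mean": float(np.mean(ok)) if ok.size else math.nan,
                "rel_iqr": float(q3 - q1),
            })
    return pd.DataFrame(rows)
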