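"""Readers/writers, run configuration, and the end-to-end pipeline driver.

CSV is the interchange format (UTF-8, comma-separated, '.' decimal, header
row mandatory).  Schemas:

* series CSV: ``region, time_h, activity_MBq, decay_convention``
  (optionally ``injected_activity_MBq``);
* cohort CSV: ``participant_id, task, region, ad_Gy, method_id,
  software_class``;
* dose-factor CSV: ``region, factor_Gy_per_MBq_h, mass_g, reference_mass_g``.

``run_pipeline`` executes fit -> TIA -> AD -> variability on a validated
YAML/JSON config, emits per-fit diagnostics, tail-fraction and
decay-convention consistency warnings, and writes a structured report
(CSV tables plus a JSON summary embedding the config hash and seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    RegionKineticsSpec,
    default_dose_factors,
    default_regions,
    simulate_cohort,
)
from .dose import DoseFactorTable
from .fitting import DECAY_CONVENTIONS, TimeActivitySeries
from .models import LU177, NuclideConstants
from .stats import paired_delta_analysis, qcd_difference, variability_report
from .tia import (
    catalog_from_config,
    default_catalog,
    report_interval_contributions,
)

__all__ = [
    "read_series_csv", "write_series_csv", "read_cohort_csv",
    "write_cohort_csv", "RunConfig", "load_config", "run_pipeline",
    "validate_against_reference",
]

SERIES_COLUMNS = ["region", "time_h", "activity_MBq", "decay_convention"]


def read_series_csv(path) -> List[TimeActivitySeries]:
    """Read time-activity series (one row per sample, grouped by region).

    Validation errors name the offending region and CSV row numbers.
    """
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for region, sub in df.groupby("region", sort=True):
        rows = (sub.index + 2).tolist()  # 1-based incl. header
        conventions = sub["decay_convention"].unique()
        if len(conventions) != 1:
            raise ValueError(
                f"{path}: region {region!r} mixes decay conventions "
                f"{sorted(conventions)} (rows {rows})")
        times = sub["time_h"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise ValueError(
                f"{path}: region {region!r} has duplicated times (rows {rows})")
        order = np.argsort(times)
        inj = None
        if "injected_activity_MBq" in sub.columns:
            vals = sub["injected_activity_MBq"].dropna().unique()
            if len(vals) == 1:
                inj = float(vals[0])
        try:
            series = TimeActivitySeries(
                region_id=str(region),
                times=tuple(times[order]),
                activities=tuple(
                    sub["activity_MBq"].to_numpy(dtype=float)[order]),
                decay_convention=str(conventions[0]),
                injected_activity=inj,
            )
        except ValueError as err:
            raise ValueError(f"{path}: rows {rows}: {err}") from err
        out.append(series)
    return out


def write_series_csv(series_list: Sequence[TimeActivitySeries], path) -> None:
    rows = []
    for s in series_list:
        for t, a in zip(s.times, s.activities):
            row = {"region": s.region_id, "time_h": t, "activity_MBq": a,
                   "decay_convention": s.decay_convention}
            if s.injected_activity is not None:
                row["injected_activity_MBq"] = s.injected_activity
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "task", "region", "ad_Gy"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


_KNOWN_KEYS = {
    "seed", "output_dir", "nuclide", "regions", "patient", "noise_sd",
    "catalog", "cohort", "dose_factors", "series_csv", "report",
}

_KNOWN_COHORT_KEYS = {"n_participants", "method_freq", "error_rates",
                      "software_class_mix"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: Path = Path("tiadose_out")
    constants: NuclideConstants = LU177
    patient: str = "A"
    noise_sd: float = 0.05
    regions: Optional[List[RegionKineticsSpec]] = None
    catalog_entries: Optional[list] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dose_factors_path: Optional[Path] = None
    series_csv: Optional[Path] = None
    raw: dict = field(default_factory=dict)

    def resolved_regions(self) -> List[RegionKineticsSpec]:
        if self.regions is not None:
            return self.regions
        return default_regions(self.patient, noise_sd=self.noise_sd,
                               constants=self.constants)

    def resolved_catalog(self):
        if self.catalog_entries:
            return catalog_from_config(self.catalog_entries)
        return default_catalog()

    def resolved_dose_table(self, regions) -> DoseFactorTable:
        if self.dose_factors_path is not None:
            return DoseFactorTable.from_csv(self.dose_factors_path)
        return default_dose_factors(regions)


def load_config(path, seed: Optional[int] = None) -> RunConfig:
    """Load and strictly validate a YAML/JSON config (unknown keys rejected)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    nuclide = data.get("nuclide", {})
    constants = (NuclideConstants(half_life=float(nuclide["half_life_h"]))
                 if "half_life_h" in nuclide else LU177)
    cohort_raw = data.get("cohort", {})
    unknown = set(cohort_raw) - _KNOWN_COHORT_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown cohort keys {sorted(unknown)}")
    cfg_seed = int(data.get("seed", 0)) if seed is None else int(seed)
    cohort = CohortConfig(
        n_participants=int(cohort_raw.get("n_participants", 24)),
        method_freq=cohort_raw.get("method_freq"),
        error_rates=cohort_raw.get("error_rates", {}),
        software_class_mix=cohort_raw.get(
            "software_class_mix", {"in_house": 0.5, "commercial": 0.5}),
        seed=cfg_seed,
    )
    return RunConfig(
        seed=cfg_seed,
        output_dir=Path(data.get("output_dir", "tiadose_out")),
        constants=constants,
        patient=str(data.get("patient", "A")),
        noise_sd=float(data.get("noise_sd", 0.05)),
        catalog_entries=data.get("catalog"),
        cohort=cohort,
        dose_factors_path=(Path(data["dose_factors"])
                           if "dose_factors" in data else None),
        series_csv=(Path(data["series_csv"]) if "series_csv" in data else None),
        raw=data,
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> fit -> TIA -> AD -> variability and write reports.

    Returns the report bundle as a dict; CSV tables and a JSON summary are
    written under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = config.resolved_regions()
    catalog = config.resolved_catalog()
    dose_table = config.resolved_dose_table(regions)

    cohort, ledger = simulate_cohort(regions, config.cohort, catalog,
                                     dose_table, config.constants)
    cohort.to_csv(outdir / "cohort.csv", index=False)

    # per-region, per-method interval contributions on one noiseless sampling
    from .cohort import make_truth, sample_series
    from dataclasses import replace as _replace
    interval_tables = []
    qc_warnings: List[str] = []
    for spec in regions:
        clean = _replace(spec, noise_sd=0.0, decay_convention="none")
        series = sample_series(make_truth(clean), clean, seed=config.seed)
        table = report_interval_contributions(series, catalog,
                                              config.constants)
        interval_tables.append(table)
        for _, row in table.iterrows():
            if row["flags"]:
                qc_warnings.append(
                    f"{spec.region_id}/{row['method_id']}: {row['flags']}")
    intervals = pd.concat(interval_tables, ignore_index=True)
    intervals.to_csv(outdir / "interval_contributions.csv", index=False)

    conventions = {s.decay_convention for s in regions}
    if len(conventions) > 1:
        qc_warnings.append(
            f"mixed decay conventions across regions: {sorted(conventions)}")

    qcd_diff = qcd_difference(cohort)
    deltas, delta_reports = paired_delta_analysis(cohort)
    deltas.to_csv(outdir / "paired_deltas.csv", index=False)

    region_reports = {}
    for (region, task), sub in cohort.groupby(["region", "task"]):
        vals = sub["ad_Gy"].to_numpy()
        vals = vals[np.isfinite(vals)]
        rep = variability_report(vals, region=region,
                                 ids=sub["participant_id"].tolist())
        region_reports[f"{region}/{task}"] = {
            "n": rep.n, "median_Gy": rep.median, "qcd_pct": rep.qcd_percent,
            "iqr_Gy": rep.iqr, "outlier_fraction": rep.outlier_fraction,
        }

    summary = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_participants": config.cohort.n_participants,
        "regions": [s.region_id for s in regions],
        "methods": [m.method_id for m in catalog],
        "qcd_task4_minus_task5_pct": {k: round(v, 1)
                                      for k, v in qcd_diff.items()},
        "delta_ad_reports": [
            {"region": r.region, "n": r.n, "median": r.median, "iqr": r.iqr,
             "outlier_ids": list(map(str, r.outlier_ids)), "flags": r.flags}
            for r in delta_reports
        ],
        "region_reports": region_reports,
        "qc_warnings": qc_warnings,
        "truth_tia_MBq_h": ledger["truth_tia_MBq_h"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    return {
        "cohort": cohort,
        "ledger": ledger,
        "intervals": intervals,
        "qcd_difference": qcd_diff,
        "paired_deltas": deltas,
        "delta_reports": delta_reports,
        "summary": summary,
    }


DEFAULT_TOLERANCES = {"float_rel": 1e-6, "int_abs": 0}


def validate_against_reference(path_reference, path_candidate,
                               tolerances: Optional[dict] = None) -> dict:
    """Field-wise comparison of two result CSVs in the package schema.

    Intended for validating an in-house reimplementation against a
    well-established reference run: float columns compare at a relative
    tolerance (default 1e-6), non-float columns exactly.  Returns a dict
    with ``passed`` and the list of differing cells.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    ref = pd.read_csv(path_reference)
    cand = pd.read_csv(path_candidate)
    if list(ref.columns) != list(cand.columns):
        raise ValueError(
            f"schema mismatch: {list(ref.columns)} vs {list(cand.columns)}")
    if len(ref) != len(cand):
        return {"passed": False,
                "differences": [f"row count {len(ref)} vs {len(cand)}"]}
    diffs = []
    for col in ref.columns:
        a, b = ref[col], cand[col]
        if pd.api.types.is_float_dtype(a) or pd.api.types.is_float_dtype(b):
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            both_nan = np.isnan(av) & np.isnan(bv)
            close = np.isclose(av, bv, rtol=tol["float_rel"], atol=0.0)
            bad = ~(close | both_nan)
        else:
            bad = (a != b).to_numpy()
        for i in np.flatnonzero(bad):
            diffs.append(f"column {col!r}, row {i}: "
                         f"{a.iloc[i]!r} != {b.iloc[i]!r}")
    return {"passed": not diffs, "differences": diffs}
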