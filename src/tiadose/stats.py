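"""Robust variability statistics for cohorts of absorbed-dose submissions.

The headline measure is the quartile coefficient of dispersion,
QCD = (Q3 - Q1)/(Q3 + Q1), chosen over the coefficient of variation because
it is less sensitive to outliers; outliers themselves are flagged with the
standard 1.5 x IQR fences (a value is an outlier iff it lies STRICTLY outside
[Q1 - 1.5*IQR, Q3 + 1.5*IQR]).

Two cohort-level analyses compare a "participants fit their own curves" task
(task4) with a "shared reference TIA" task (task5):

* ``qcd_difference`` -- per-region QCD(task4) - QCD(task5), the estimate of
  the variability attributable to the fitting/integration step;
* ``paired_delta_analysis`` -- per participant, (AD_task4 - AD_task5)
  normalised by the MEAN task-5 AD over all participants for the region,
  summarised by median/IQR with outliers labelled by method and software
  class.

The quantile convention defaults to linear interpolation between order
statistics and is selectable among numpy's standard methods, since QCD
values shift slightly across conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VariabilityReport", "quartiles", "qcd", "iqr_outliers",
    "variability_report", "paired_delta_analysis", "qcd_difference",
    "COHORT_COLUMNS",
]

#: cohort table schema (one row per participant x task x region)
COHORT_COLUMNS = ["participant_id", "task", "region", "ad_Gy",
                  "method_id", "software_class"]

DEFAULT_QUANTILE_METHOD = "linear"


@dataclass
class VariabilityReport:
    """Median/quartile summary of one region's values with outlier flags."""

    region: str
    n: int
    median: float
    q1: float
    q3: float
    qcd: float
    iqr: float
    outlier_ids: List = field(default_factory=list)
    outlier_fraction: float = 0.0
    flags: List[str] = field(default_factory=list)

    @property
    def qcd_percent(self) -> float:
        return 100.0 * self.qcd


def quartiles(values, convention: str = DEFAULT_QUANTILE_METHOD
              ) -> Tuple[float, float, float]:
    """(Q1, median, Q3) under the given quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quartiles of an empty vector are undefined")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=convention)
    return float(q1), float(med), float(q3)


def qcd(values, convention: str = DEFAULT_QUANTILE_METHOD) -> float:
    """Quartile coefficient of dispersion (Q3 - Q1)/(Q3 + Q1)."""
    q1, _, q3 = quartiles(values, convention)
    if q3 + q1 == 0:
        raise ValueError("QCD undefined: Q1 + Q3 == 0")
    return (q3 - q1) / (q3 + q1)


def iqr_outliers(values, convention: str = DEFAULT_QUANTILE_METHOD
                 ) -> Tuple[float, np.ndarray]:
    """IQR and a boolean outlier mask under the 1.5 x IQR fence rule.

    A value is an outlier iff it lies strictly outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR]; values exactly on a fence are kept.
    """
    v = np.asarray(values, dtype=float)
    q1, _, q3 = quartiles(v, convention)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (v < lo) | (v > hi)
    return float(iqr), mask


def variability_report(values, region: str = "", ids: Optional[Sequence] = None,
                       convention: str = DEFAULT_QUANTILE_METHOD
                       ) -> VariabilityReport:
    """Full robust summary of one region's distribution."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = quartiles(v, convention)
    iqr, mask = iqr_outliers(v, convention)
    flags = []
    if v.size < 4:
        flags.append("n_below_4_fences_unreliable")
    if ids is None:
        ids = list(range(v.size))
    outlier_ids = [i for i, m in zip(ids, mask) if m]
    return VariabilityReport(
        region=region,
        n=int(v.size),
        median=med,
        q1=q1,
        q3=q3,
        qcd=(q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else math.nan,
        iqr=iqr,
        outlier_ids=outlier_ids,
        outlier_fraction=float(mask.mean()),
        flags=flags,
    )


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = {"participant_id", "task", "region", "ad_Gy"} - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    dup = cohort.duplicated(subset=["participant_id", "task", "region"])
    if dup.any():
        raise ValueError(
            "cohort table has duplicate (participant, task, region) rows: "
            f"{cohort.loc[dup, ['participant_id', 'task', 'region']].to_dict('records')}")
    # rows whose AD could not be computed (e.g. divergent tails) are dropped
    return cohort[np.isfinite(cohort["ad_Gy"])]


def paired_delta_analysis(cohort: pd.DataFrame,
                          convention: str = DEFAULT_QUANTILE_METHOD
                          ) -> Tuple[pd.DataFrame, List[VariabilityReport]]:
    """Per-participant (AD_task4 - AD_task5)/mean(task-5 ADs) by region.

    Only participants present in BOTH tasks for a region enter; the
    normaliser is the mean task-5 AD over all such participants (not each
    participant's own value).  Returns the per-participant delta table and a
    per-region :class:`VariabilityReport` list; regions with fewer than two
    paired participants are flagged and not summarised.
    """
    cohort = _check_cohort(cohort)
    rows = []
    reports: List[VariabilityReport] = []
    for region, sub in cohort.groupby("region", sort=True):
        t4 = sub[sub["task"] == "task4"].set_index("participant_id")
        t5 = sub[sub["task"] == "task5"].set_index("participant_id")
        paired = t4.index.intersection(t5.index)
        if len(paired) < 2:
            reports.append(VariabilityReport(
                region=region, n=len(paired), median=math.nan, q1=math.nan,
                q3=math.nan, qcd=math.nan, iqr=math.nan,
                flags=["insufficient_paired_participants"]))
            continue
        mean_t5 = float(t5.loc[paired, "ad_Gy"].mean())
        delta = (t4.loc[paired, "ad_Gy"].to_numpy()
                 - t5.loc[paired, "ad_Gy"].to_numpy()) / mean_t5
        for pid, d in zip(paired, delta):
            rows.append({
                "region": region,
                "participant_id": pid,
                "delta_over_mean_task5": d,
                "method_id": t4.loc[pid].get("method_id"),
                "software_class": t4.loc[pid].get("software_class"),
            })
        reports.append(variability_report(delta, region=region,
                                          ids=list(paired),
                                          convention=convention))
    return pd.DataFrame(rows), reports


def qcd_difference(cohort: pd.DataFrame, as_percent: bool = True,
                   convention: str = DEFAULT_QUANTILE_METHOD) -> pd.Series:
    """Per-region QCD(task4) - QCD(task5), only over paired participants.

    The signed difference estimates the dispersion attributable to the
    fitting/integration step; reported in percentage points by default.
    """
    cohort = _check_cohort(cohort)
    out = {}
    for region, sub in cohort.groupby("region", sort=True):
        t4 = sub[sub["task"] == "task4"].set_index("participant_id")
        t5 = sub[sub["task"] == "task5"].set_index("participant_id")
        paired = t4.index.intersection(t5.index)
        if len(paired) == 0 or len(t4) == 0 or len(t5) == 0:
            raise ValueError(f"region {region!r} missing one of the tasks")
        d = (qcd(t4.loc[paired, "ad_Gy"], convention)
             - qcd(t5.loc[paired, "ad_Gy"], convention))
        out[region] = 100.0 * d if as_percent else d
    return pd.Series(out, name="qcd_task4_minus_task5"
                     + ("_pct" if as_percent else ""))
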