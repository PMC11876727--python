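"""TIA-to-absorbed-dose conversion with organ-level self-dose factors.

The dose model is deliberately self-dose-only: AD = TIA x S, with the
self-dose factor S (Gy per MBq*h) optionally rescaled by
reference_mass/actual_mass (the standard organ-level inverse-mass
approximation).  Cross-organ photon dose and voxel kernels are out of scope;
the variability questions this package addresses live upstream of the dose
step.

Also here: the decay-correction conventions and the two classic
activity-bookkeeping pitfalls (a paired-organ AD combined without mass
weighting, and lesions counted inside a healthy organ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import DECAY_CONVENTIONS, TimeActivitySeries
from .models import LU177, NuclideConstants

__all__ = [
    "DoseFactorTable", "ADResult", "tia_to_ad", "combine_kidneys",
    "apply_decay_correction", "healthy_organ_tia",
]


@dataclass(frozen=True)
class RegionDoseFactor:
    factor: float                       # Gy per MBq*h (self-dose)
    mass: float                         # g
    reference_mass: Optional[float] = None  # g

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"dose factor must be > 0, got {self.factor}")
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.reference_mass is not None and not self.reference_mass > 0:
            raise ValueError("reference_mass must be > 0")


@dataclass
class DoseFactorTable:
    """region -> (self-dose factor, mass, optional reference mass)."""

    regions: Dict[str, RegionDoseFactor] = field(default_factory=dict)

    def add(self, region: str, factor: float, mass: float,
            reference_mass: Optional[float] = None) -> None:
        self.regions[region] = RegionDoseFactor(factor, mass, reference_mass)

    def __contains__(self, region: str) -> bool:
        return region in self.regions

    def __getitem__(self, region: str) -> RegionDoseFactor:
        if region not in self.regions:
            raise KeyError(f"region {region!r} not in dose-factor table")
        return self.regions[region]

    @classmethod
    def from_csv(cls, path) -> "DoseFactorTable":
        df = pd.read_csv(path)
        required = {"region", "factor_Gy_per_MBq_h", "mass_g"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dose-factor CSV missing columns: {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            ref = row.get("reference_mass_g")
            if ref is not None and (isinstance(ref, float) and math.isnan(ref)):
                ref = None
            table.add(str(row["region"]), float(row["factor_Gy_per_MBq_h"]),
                      float(row["mass_g"]),
                      float(ref) if ref is not None else None)
        return table

    def to_csv(self, path) -> None:
        rows = [{
            "region": r,
            "factor_Gy_per_MBq_h": d.factor,
            "mass_g": d.mass,
            "reference_mass_g": d.reference_mass,
        } for r, d in self.regions.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ADResult:
    region: str
    ad: float                 # Gy
    method_id: Optional[str] = None
    participant_id: Optional[str] = None
    task: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isnan(self.ad) and self.ad < 0:
            raise ValueError(f"absorbed dose must be >= 0, got {self.ad}")


def tia_to_ad(tia: float, region: str, table: DoseFactorTable,
              mass_scaling: bool = False) -> float:
    """AD (Gy) = TIA (MBq*h) x self-dose factor, with optional inverse-mass
    rescaling of the factor by reference_mass/actual_mass."""
    entry = table[region]
    scale = 1.0
    if mass_scaling:
        if entry.reference_mass is None:
            raise ValueError(
                f"region {region!r} has no reference_mass for mass scaling")
        scale = entry.reference_mass / entry.mass
    return tia * entry.factor * scale


def combine_kidneys(ad_left: float, mass_left: float,
                    ad_right: float, mass_right: float) -> float:
    """Mass-weighted average AD of the two kidneys.

    This is the correct way to report a single "total kidney" AD; the naive
    sum ad_left + ad_right always exceeds it when both ADs are positive and
    is one of the error modes behind inflated total-kidney variability.
    """
    if mass_left <= 0 or mass_right <= 0:
        raise ValueError("kidney masses must be > 0")
    return (mass_left * ad_left + mass_right * ad_right) / (mass_left + mass_right)


def _factor_to_none(convention: str, times: np.ndarray,
                    constants: NuclideConstants) -> np.ndarray:
    """Multiplier taking activities in `convention` to as-measured values."""
    if convention == "corrected_to_injection":
        # corrected value = measured * exp(+lam*t)  =>  undo with exp(-lam*t)
        return np.exp(-constants.lam_physical * times)
    if convention in ("corrected_to_scan_start", "none"):
        # the reference time of each sample is its own acquisition time
        return np.ones_like(times)
    raise ValueError(f"unknown decay convention {convention!r}")


def apply_decay_correction(series: TimeActivitySeries, target_convention: str,
                           constants: NuclideConstants = LU177
                           ) -> TimeActivitySeries:
    """Convert a series between decay-correction conventions.

    Each activity is multiplied by exp(+/- lam_physical * t_i) as needed;
    already being in the target convention is the identity, and a round trip
    recovers the original values exactly.
    """
    if target_convention not in DECAY_CONVENTIONS:
        raise ValueError(f"unknown decay convention {target_convention!r}")
    t = series.t
    to_none = _factor_to_none(series.decay_convention, t, constants)
    from_none = 1.0 / _factor_to_none(target_convention, t, constants)
    return series.with_activities(series.a * to_none * from_none,
                                  decay_convention=target_convention)


def healthy_organ_tia(organ_tia: float, lesion_tias: Sequence[float],
                      lesions_inside: bool = True) -> float:
    """Healthy-tissue TIA of an organ containing lesions.

    Lesion activity inside an organ must not be counted toward the healthy
    organ; when ``lesions_inside``, the contained lesions' TIAs are
    subtracted from the whole-organ TIA.  A negative result signals
    inconsistent inputs and raises.
    """
    if not lesions_inside or not len(list(lesion_tias)):
        return organ_tia
    healthy = organ_tia - float(np.sum(lesion_tias))
    if healthy < 0:
        raise ValueError(
            f"lesion TIA sum {organ_tia - healthy:.6g} exceeds the "
            f"whole-organ TIA {organ_tia:.6g}")
    return healthy
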