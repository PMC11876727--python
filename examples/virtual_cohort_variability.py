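"""Simulate a virtual multi-center cohort and quantify AD variability.

Generates a 24-participant challenge on the patient A design: in task 4
every participant samples their own noisy curves, picks a fitting method
from the catalog and converts TIA to absorbed dose; in task 5 everyone
shares the reference TIA.  A few participants commit the classic errors
(missed decay-correction undo, lesions counted in healthy liver, unweighted
kidney summation).  Printed per region: the quartile coefficient of
dispersion (QCD) difference between tasks -- the variability attributable to
fitting/integration -- and the IQR of the paired dose differences with
flagged outliers.
"""

from tiadose import (
    CohortConfig,
    default_regions,
    paired_delta_analysis,
    qcd_difference,
    simulate_cohort,
)

regions = default_regions("A", noise_sd=0.05)
config = CohortConfig(
    n_participants=24,
    seed=2025,
    error_rates={
        "skip_decay_uncorrection": 0.125,
        "include_lesions_in_liver": 0.125,
        "sum_kidneys_unweighted": 0.125,
    },
)
cohort, ledger = simulate_cohort(regions, config)

print("QCD(task4) - QCD(task5) per region, percentage points:")
for region, val in qcd_difference(cohort).items():
    print(f"  {region:>13s}: {val:6.1f}")

print("\npaired dAD / mean(task5 AD):")
deltas, reports = paired_delta_analysis(cohort)
for rep in reports:
    outliers = ", ".join(map(str, rep.outlier_ids)) or "-"
    print(f"  {rep.region:>13s}: median {rep.median:+.3f}  "
          f"IQR {rep.iqr:.3f}  outliers: {outliers}")

errs = {p["participant_id"]: sorted(p["errors"])
        for p in ledger["participants"] if p["errors"]}
print(f"\ninjected participant errors: {errs}")
print("Positive QCD differences show task 4 (own fitting) disperses more "
      "than task 5 (shared TIA); outliers trace back to the injected error "
      "modes and ill-conditioned fits.")
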