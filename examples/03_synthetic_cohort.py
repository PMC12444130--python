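"""Generating a synthetic neonate cohort and summarizing its removal rates.

Defaults emulate a 30-neonate severe-hyperbilirubinemia cohort (weight
3520 ± 352 g, baseline TSB 498.1 ± 37.6 μmol/L, TSB sampled every 15 min
over a 120-min exchange).  The generating kinetics include calibrated
production/rebound so observed-style curves flatten like real ones; zeroing
the extension recovers the ideal washout model exactly.
"""

import numpy as np

from biliwash import (
    CohortConfig,
    cohort_mean_curve,
    conversion_rate,
    generate_cohort,
    half_removal_rates,
)

cohort = generate_cohort(CohortConfig(n_patients=30, seed=42))
mean = cohort_mean_curve(cohort)
print("cohort mean curve (umol/L):", np.round(mean.concentrations_umol_L, 1))
print(f"mean conversion at 60 min: "
      f"{conversion_rate(mean.baseline, mean.value_at(60.0)):.1f} % "
      "(ideal washout would give 63.2 %)")

halves = [half_removal_rates(p.series) for p in cohort.patients]
first = np.array([h["first_half_pct"] for h in halves])
second = np.array([h["second_half_vs_split_pct"] for h in halves])
print(f"per-patient first-half removal:  {first.mean():.1f} ± {first.std(ddof=1):.1f} %")
print(f"per-patient second-half removal: {second.mean():.1f} ± {second.std(ddof=1):.1f} % "
      "(of the 60-min value)")
# Per-patient percentages average lower/noisier than the curve-of-means
# figure — two different estimands, both reported.

ideal = generate_cohort(CohortConfig(n_patients=30, seed=42,
                                     measurement_noise_sd=0.0).zero_extension())
m2 = cohort_mean_curve(ideal)
print("noiseless zero-extension conversion at 60 min:",
      round(conversion_rate(m2.baseline, m2.value_at(60.0)), 1), "%")
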