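# biliwash

Bilirubin washout kinetics for continuous peripheral arteriovenous exchange
transfusion in neonates with severe hyperbilirubinemia — a one-compartment
dilution model with a standardized dosing rule, decline-curve analysis, a
synthetic-cohort simulator, and the contingency/repeated-measures statistics
used on exchange-transfusion safety data.

## Who this is for

Neonatologists and clinical modellers reasoning about exchange-transfusion
*volume and timing*: how much of the circulating bilirubin a single- or
double-volume exchange can remove, how fast, and why observed decline curves
flatten below the ideal model in the second hour. The package is a Python
library first (`import biliwash`); a thin `biliwash` CLI wraps the pipeline
for shell use, and `examples/` contains one short narrative script per
capability.

## The model

Treat the neonatal vascular pool (volume *V* mL, well mixed) as a single
compartment exchanged continuously at *k* mL/min against bilirubin-free
donor blood. Total serum bilirubin *b* (μmol/L) then obeys

    V · db/dt = −k · b        ⟹        b(t) = c₀ · e^(−kt/V)

For the standardized procedure — total exchange volume 2V delivered over
120 min, i.e. k = 2V/120 — this collapses to **b = c₀ · e^(−t/60)**
independently of the patient's blood volume: one blood volume (60 min)
removes 1 − e⁻¹ = 63.2 % of baseline, two volumes remove 86.5 %.

The *conversion (removal) rate* at time t is (c₀ − b_t)/c₀ × 100 %.
Observed curves remove less than the model predicts (≈44 % rather than
63.2 % at 60 min) because bilirubin keeps being produced and re-diffuses
from tissue as the plasma level falls; an optional two-compartment
extension

    V  · db/dt = −k·b + production + q·(s − b)
    Vₛ · ds/dt = −q·(s − b)

captures both effects and reduces exactly to the closed form when its
parameters are zero.

Cohort-level statistics cover the designs these data are analyzed with:
uncorrected Pearson χ² and the two-sided Fisher exact test on 2×2
adverse-event tables (first vs second hour), one-way repeated-measures
ANOVA for serial measurements, and pooled/paired t statistics.

## Worked example

```python
import numpy as np
from biliwash import (ExchangeParams, conversion_rate, standard_curve,
                      time_to_target)

params = ExchangeParams.from_weight(3520.0)   # V = 281.6 mL, k = 4.69 mL/min
curve = standard_curve(498.1, params, np.arange(0, 121, 30))
print(np.round(curve.concentrations_umol_L, 1))
print(round(conversion_rate(498.1, curve.value_at(60.0)), 1), "% removed at 60 min")
print(round(time_to_target(498.1, 278.4, params), 1), "min to reach 278.4 umol/L")
```

prints

```
[498.1 302.1 183.2 111.1  67.4]
63.2 % removed at 60 min
34.9 min to reach 278.4 umol/L
```

Starting from a baseline of 498.1 μmol/L, the ideal standardized exchange
reaches 183.2 μmol/L after one hour (63.2 % removed) and 67.4 μmol/L after
two; a concentration that real cohorts only reach at 60 min (278.4 μmol/L,
44.1 % conversion) would take ~35 min under ideal washout. Run
`python examples/03_synthetic_cohort.py` to simulate a 30-neonate cohort
whose mean curve flattens like observed data (≈43 % conversion at 60 min,
per-patient first-half removal ≈43 ± 3 %), and
`python examples/04_adverse_event_stats.py` for the 2×2 tests
(e.g. increased heart rate 2/30 vs 12/30 gives χ² = 9.32).

The same pipeline from the shell:

```sh
biliwash report --seed 2024 --out run_out     # cohort, curves, stats, report
biliwash model --c0 498.1 --target 278.4      # standard-curve calculator
```

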