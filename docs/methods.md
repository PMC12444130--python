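# Methods

## Washout model

The core model treats the neonatal vascular pool as one well-mixed
compartment of volume *V* (mL) from which blood is withdrawn continuously at
*k* (mL/min) and replaced, at the same rate, by donor blood assumed to carry
no bilirubin. The plasma bilirubin concentration *b* (μmol/L) satisfies
V·db/dt = −k·b, hence b(t) = c₀·e^(−kt/V). Assumptions: instantaneous
mixing, constant V and k over the procedure, bilirubin-free replacement
blood (no option to relax this in v1), and no sources or sinks other than
the exchange itself.

**Units.** Volumes are mL, rates mL/min, concentrations μmol/L, time min
throughout. Descriptions of this model sometimes quote V in litres next to
k in mL/min; the package normalizes to mL and converts explicitly wherever
a litre-based quantity enters (see the production term below).

**Standardization.** `standard_rate(V, duration=120, volumes=2)` returns
k = 2V/120, the rate that exchanges two blood volumes in two hours. Under
this rule kt/V = t/60, so the normalized curve b/c₀ is the same for every
patient — the property the tests check across V ∈ {100, 282, 500} mL. Blood
volume defaults to 80 mL per kg of body weight (`ExchangeParams.from_weight`),
the single-volume figure implied by a 160 mL/kg double-volume exchange; it
is overridable everywhere.

**Inversion.** `time_to_target` returns (V/k)·ln(c₀/target); it refuses
targets above c₀ or at 0, and reports a zero rate as "unreachable".

## Two-compartment extension

Observed decline curves flatten below the ideal model late in the procedure.
Two mechanisms are modelled: continued bilirubin production entering plasma,
and re-diffusion from an extravascular store as the plasma level falls:

    V  · db/dt = −k·b + 1000·p + q·(s − b)
    Vₛ · ds/dt = −q·(s − b)

with p the production rate (μmol/min), q a plasma↔tissue transfer
coefficient (mL/min), and s the concentration of an apparent tissue pool of
volume Vₛ (mL). Bookkeeping is in concentration·mL units; since p is stated
in μmol/min while the other terms are (μmol/L)·mL/min, the production term
enters as p divided by the plasma volume *in litres* (equivalently 1000·p in
the mL bookkeeping). In the degenerate case k = q = 0 the plasma
concentration rises linearly at p/(V/1000) μmol/L per minute, which the
tests assert.

The structure is a deliberately minimal mechanistic sketch: parameters are
not identifiable from a single mean curve and no claim of physiological
calibration is made beyond the defaults below. With p = q = 0 the extension
reduces exactly to the closed form, so it is strictly opt-in.

**Integrator.** Fixed-step classical RK4 with step ≤ 0.1 min, sub-stepped so
every requested grid point is hit exactly. The system is linear and
non-stiff at physiological parameters (time constants ≥ tens of minutes), so
RK4 at this step agrees with the analytic solution to ~1e−13 relative —
comfortably inside the 1e−6 tolerance the acceptance property asserts. A
non-finite state aborts with the time reached.

## Curve analysis

* `conversion_rate(c₀, b) = (c₀ − b)/c₀ × 100 %` — the efficacy statistic.
* `summarize_removal` reports the conversion at every sample, per-interval
  removal as differences of consecutive conversions (they telescope to the
  final conversion by construction), and a log-linear exponential fit.
* **Two estimands, both reported.** The mean of per-patient conversion
  percentages differs from the conversion of the mean curve (Jensen-type
  gap plus noise); the cohort layer reports per-patient summaries, the
  curve layer reports curve-of-means summaries, and they are labelled
  distinctly in the pipeline metrics.
* **Second-half conventions.** Removal in the second hour can be quoted
  against baseline or against the 60-min value; published summaries are
  usually closer to the latter. `half_removal_rates` returns
  `second_half_vs_baseline_pct` and `second_half_vs_split_pct` side by side.
* `fit_exponential` is ordinary least squares on ln b vs t: exact on
  noiseless model data (r² = 1, rate to machine precision), initialization-
  free, and matched to the model's log-linearity. Nonlinear least squares is
  deliberately out of scope for v1. Two points are accepted (the fit is then
  exact interpolation); non-positive concentrations are rejected.
* `tangent_slope` uses centered differences at interior samples and
  one-sided differences at the ends; `analytic_slope` is −(k/V)·b(t) for the
  model.
* `compare_to_standard` anchors the model at the observed baseline, so the
  deviation at t = 0 is zero by construction; it reports per-time absolute
  and relative deviations and the maximum.

## Synthetic cohort

The generator emulates a 30-neonate severe-hyperbilirubinemia cohort under a
standardized 120-min double-volume exchange: birth weight ~N(3520, 352²) g,
baseline TSB ~N(498.1, 37.6²) μmol/L (both truncated at 0, a >9 SD event at
these parameters, so truncation is immaterial), TSB sampled every 15 min,
per-patient V = 80 mL/kg, and five adverse-event types flagged independently
per half with first/second-hour probabilities {thrombocytopenia 0/30, 16/30;
hypocalcemia 1/30, 0/30; apnea 1/30, 3/30; increased heart rate 2/30, 12/30;
allergic reactions 2/30, 9/30}.

**Generating kinetics.** Default extension parameters p = 0.505 μmol/min,
q = 1.77 mL/min, Vₛ = 282 mL, s₀ = 498.1 μmol/L were calibrated once by
solving for (p, q) so the reference patient's modelled concentrations at 60
and 120 min match the observed-cohort mean curve (278.4 and 216.7 μmol/L
from a 498.1 baseline, i.e. ~44 % conversion at one hour instead of the
ideal 63 %); the residual of that 2-parameter fit is ~3 μmol/L. Because the
tissue pool and its initial concentration are fixed while weight and
baseline vary per patient, patients deviate from the reference curve in a
correlated, realistic way. `CohortConfig.zero_extension()` switches the
generator to the pure washout model, where every noiseless patient hits the
closed-form conversions exactly.

**Measurement noise.** No noise model is given for the source setting;
the default SD is 10 μmol/L (≈2 % of baseline), chosen once so synthetic
per-patient removal-rate SDs are of the same order as published per-patient
spreads (a few percentage points). It is a free parameter. The t = 0 sample
carries no noise: the baseline is the anchoring measurement by definition.

**What passing tests do not show.** The generator reproduces marginal
distributions and mean-curve shape, not real-data features such as
correlated adverse events, assay drift, irregular sampling, missing values,
or haemolysis-driven production bursts. Agreement on synthetic cohorts
validates the analysis machinery, not clinical effect sizes; cohort-level F
and t statistics from real patients are not reproducible without raw data
and are asserted only qualitatively (direction and significance).

## Statistics

* **Pearson χ² (2×2)**: n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], no Yates
  correction — the uncorrected form is what the targeted 2×2 tables print
  (9.31/9.32 and 5.45 on the heart-rate and allergy tables). A zero margin
  raises `ZeroMarginError`, directing callers to the Fisher test.
* **Fisher exact (two-sided)**: conditional on both margins, the p-value is
  the sum of hypergeometric probabilities not exceeding the observed
  table's. Probabilities are exact integers/rationals (math.comb,
  Fraction), so tie comparison involves no floating-point tolerance;
  degenerate margins give p = 1. Conventions for two-sided Fisher p differ
  across software; this is the most common one and matches scipy's.
* **Repeated-measures ANOVA (one-way, within-subjects)**: classical
  decomposition with the between-subject sum of squares removed,
  F = MS_time/MS_error on ((T−1), (T−1)(S−1)) df. No sphericity
  (Greenhouse–Geisser) correction in v1, matching how such tables are
  usually reported. Type-I calibration under the null is verified at
  5 % ± 1.5 % over 10,000 simulations.
* **t statistics**: pooled-variance unpaired and paired forms, sign
  convention mean(x) − mean(y).
* **Tail probabilities** for χ², F and t are assembled from the regularized
  incomplete gamma/beta functions (scipy.special), which agree with
  reference distribution implementations to well below 1e−8; the suite
  cross-checks every test against scipy.stats (and pingouin for the ANOVA).
* No multiple-testing adjustment is applied, matching the target analyses.

## Pipeline and IO

Long-format CSV (`patient_id,time_min,tsb_umol_L`, UTF-8, "." decimal) was
chosen over wide so variable sampling grids are representable; validation
errors name 1-based file rows. Run configuration round-trips losslessly
through YAML, and the metrics JSON embeds a SHA-256 hash of the canonical
config. All randomness flows from the single config seed through one
`numpy` generator, making reruns byte-identical — a property the tests
assert on every pipeline output file. Plotting is optional (`--plot`);
every numeric output exists without it.

## Problem sizes used in the checks

Acceptance-style properties run at: ODE-vs-closed-form on a 1-min grid over
[0, 120]; Fisher enumeration sweep over all 2×2 tables with row margins
≤ 20 (53,360 tables); ANOVA type-I calibration with 10,000 null datasets of
10 subjects × 5 timepoints; rate recovery over 100 seeded cohorts of 5
patients each at noise SD 10 μmol/L; event-rate calibration on one
3,000-patient cohort. These sizes give Monte-Carlo standard errors well
inside the asserted bands.

## Known limitations

* The washout model ignores haematocrit differences between patient and
  donor blood, intra-procedure volume shifts, and phototherapy.
* Extension parameters are not identifiable from a single mean curve; the
  defaults are a calibrated illustration, not estimates.
* Hemoglobin, platelet, calcium and glucose trajectories are not modelled
  mechanistically; adverse events are independent across types and halves
  because no correlation structure is available to emulate.
* Rebound after the procedure ends is out of scope: the model is only
  defined on the exchange interval.
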