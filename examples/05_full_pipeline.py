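"""End-to-end pipeline: simulate a cohort, analyze curves and events, write
a reproducible report.

Everything is determined by the run configuration (including the seed); the
metrics JSON is byte-identical across reruns and stamped with the config
hash.  Equivalent shell call:  biliwash report --seed 2024 --out run_out
"""

from biliwash import CohortConfig, RunConfig, run_pipeline

config = RunConfig(cohort=CohortConfig(n_patients=30, seed=2024),
                   output_dir="run_out")
metrics = run_pipeline(config)

print(f"outputs in {config.output_dir}/ (cohort.csv, curves.csv, "
      "metrics.json, report.txt)")
print(f"config hash: {metrics['config_hash'][:12]}…")
cm, sm = metrics["curve_of_means"], metrics["standard_model"]
print(f"conversion at 60 min: observed {cm['conversion_at_split_pct']:.1f} % "
      f"vs model {sm['conversion_at_split_pct']:.1f} %")
pp = metrics["per_patient_removal"]
print(f"per-patient first-half removal {pp['first_half_mean_pct']:.1f} "
      f"± {pp['first_half_sd_pct']:.1f} %")
ra = metrics["rm_anova"]
print(f"time effect F({ra['df'][0]}, {ra['df'][1]}) = {ra['F']:.1f}, p = {ra['p']:.2e}")
# The observed-vs-model gap at 60 min is the signature of ongoing bilirubin
# production and tissue rebound during the exchange.
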