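"""Optional decline-curve plotting. All numeric outputs exist without it."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cohort import SyntheticCohort, cohort_mean_curve
from .model import ExchangeParams, standard_curve, standard_rate

__all__ = ["plot_decline_curves"]


def plot_decline_curves(cohort: SyntheticCohort, path) -> None:
    """Per-patient curves (faint), cohort mean, and the standardized model."""
    cc = cohort.config
    fig, ax = plt.subplots(figsize=(6, 4))
    for p in cohort.patients:
        ax.plot(p.series.times_min, p.series.concentrations_umol_L, color="0.8", lw=0.6)
    mean = cohort_mean_curve(cohort)
    ax.plot(mean.times_min, mean.concentrations_umol_L, "o-", label="cohort mean")
    v = cc.blood_mL_per_kg * cc.weight_mean_g / 1000.0
    params = ExchangeParams(
        v, standard_rate(v, cc.duration_min, cc.volumes_exchanged), cc.duration_min
    )
    std = standard_curve(mean.baseline, params, mean.times_min)
    ax.plot(std.times_min, std.concentrations_umol_L, "--", label="standard model")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("TSB (μmol/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
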