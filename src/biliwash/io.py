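"""CSV and configuration round-tripping.

Series are stored long-format with columns ``patient_id,time_min,tsb_umol_L``
(optional extras such as ``weight_g`` are carried through), UTF-8,
comma-separated, ``.`` decimal.  Run configurations round-trip losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .model import BilirubinSeries, ExtendedModelParams

__all__ = [
    "SeriesValidationError",
    "RunConfig",
    "read_series_csv",
    "write_series_csv",
    "load_config",
    "save_config",
    "config_hash",
]

REQUIRED_COLUMNS = ("patient_id", "time_min", "tsb_umol_L")


class SeriesValidationError(ValueError):
    """A series CSV violated the format contract; message names the rows."""


def _rows(mask_or_index) -> str:
    # +2: one for the header line, one for 0-based indexing
    nums = [int(i) + 2 for i in np.atleast_1d(mask_or_index)]
    return ", ".join(map(str, nums))


def read_series_csv(path) -> dict[str, BilirubinSeries]:
    """Read a long-format series CSV into one BilirubinSeries per patient.

    Validation failures raise :class:`SeriesValidationError` naming the
    offending file rows (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    for col in ("time_min", "tsb_umol_L"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            raise SeriesValidationError(
                f"{path}: non-numeric or missing {col} at row(s) {_rows(df.index[bad])}"
            )
        df[col] = vals
        neg = df[col] < 0
        if neg.any():
            raise SeriesValidationError(
                f"{path}: negative {col} at row(s) {_rows(df.index[neg])}"
            )
    dup = df.duplicated(subset=["patient_id", "time_min"], keep=False)
    if dup.any():
        raise SeriesValidationError(
            f"{path}: duplicate (patient_id, time_min) at row(s) {_rows(df.index[dup])}"
        )
    out: dict[str, BilirubinSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_min")
        try:
            out[str(pid)] = BilirubinSeries(
                grp["time_min"].to_numpy(), grp["tsb_umol_L"].to_numpy(), "observed"
            )
        except ValueError as exc:
            raise SeriesValidationError(f"{path}: patient {pid!r}: {exc}") from exc
    return out


def write_series_csv(path, series_by_patient: dict[str, BilirubinSeries] | pd.DataFrame) -> None:
    """Write series (or an already long-format frame) to CSV."""
    if isinstance(series_by_patient, pd.DataFrame):
        df = series_by_patient
    else:
        rows = [
            {"patient_id": pid, "time_min": float(t), "tsb_umol_L": float(c)}
            for pid, ser in series_by_patient.items()
            for t, c in zip(ser.times_min, ser.concentrations_umol_L)
        ]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    split_min: float = 60.0
    output_dir: str = "biliwash_out"
    make_plots: bool = False

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["adverse_event_rates"] = {
            k: list(v) for k, v in self.cohort.adverse_event_rates.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cd = dict(d.pop("cohort", {}))
        if "extension" in cd and not isinstance(cd["extension"], ExtendedModelParams):
            cd["extension"] = ExtendedModelParams(**cd["extension"])
        if "adverse_event_rates" in cd:
            cd["adverse_event_rates"] = {
                k: tuple(v) for k, v in cd["adverse_event_rates"].items()
            }
        return cls(cohort=CohortConfig(**cd), **d)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    blob = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
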