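"""File formats and configuration.

Interchange formats are deliberately plain: the sample log is a CSV with a
fixed lower-snake header (perfusionists export spreadsheets; a fixed header
makes parsing bit-exact), the session is a single self-contained JSON
document, and configuration overrides come from a JSON or YAML file.  Times
are minutes since perfusion start; wall-clock conversion is the caller's
concern.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .physiology import (
    MVO2_PER_GRAM_RANGE,
    OER_TARGET_RANGE,
    BloodGasSample,
    InputError,
    OxygenParameters,
    PerfusionSettings,
    SampleSite,
)
from .recommender import NormalizationConstants
from .session import AdvisoryThresholds, UnitHints

#: Fixed sample-log CSV header, in column order.
SAMPLE_LOG_COLUMNS = [
    "time_min", "site", "po2_mmhg", "so2", "hb_g_dl", "lactate_mmol_l",
    "ph", "hco3_mmol_l", "ica_mmol_l", "k_mmol_l",
    "cbf_ml_min", "map_mmhg", "temp_c",
]

_FIELD_BY_COLUMN = {
    "time_min": "time",
    "po2_mmhg": "po2",
    "so2": "so2",
    "hb_g_dl": "hb",
    "lactate_mmol_l": "lactate",
    "ph": "ph",
    "hco3_mmol_l": "hco3",
    "ica_mmol_l": "ionized_ca",
    "k_mmol_l": "k",
}


class StandardSettings(BaseModel):
    """Standard machine-perfusion protocol defaults.

    Flow and pressure are windows (the pump is run somewhere inside them;
    midpoints are used as defaults); gas supply is a fixed hyperoxic mixture.
    """

    model_config = ConfigDict(frozen=True)

    cbf_window: tuple[float, float] = (700.0, 800.0)
    pressure_window: tuple[float, float] = (75.0, 80.0)
    temperature: float = 34.0
    gas_flow_ml_min: float = 150.0
    gas_o2_fraction: float = 0.85
    gas_co2_fraction: float = 0.01

    def perfusion_settings(self) -> PerfusionSettings:
        return PerfusionSettings(
            cbf_setting=sum(self.cbf_window) / 2.0,
            mean_aortic_pressure=sum(self.pressure_window) / 2.0,
            temperature=self.temperature,
        )


class ToolConfig(BaseModel):
    """Full override surface of the tool, validated against physiologic ranges."""

    model_config = ConfigDict(frozen=True)

    oxygen: OxygenParameters = OxygenParameters()
    normalization: NormalizationConstants = NormalizationConstants()
    thresholds: AdvisoryThresholds = AdvisoryThresholds()
    unit_hints: UnitHints = UnitHints()
    standard: StandardSettings = StandardSettings()
    pairing_tolerance: float = Field(default=5.0, gt=0)

    @model_validator(mode="after")
    def _physiologic_ranges(self):
        lo, hi = MVO2_PER_GRAM_RANGE
        if not lo <= self.oxygen.mvo2_per_gram <= hi:
            raise ValueError(
                f"mvo2_per_gram {self.oxygen.mvo2_per_gram} outside physiologic "
                f"range [{lo}, {hi}]"
            )
        lo, hi = OER_TARGET_RANGE
        if not lo <= self.oxygen.oer_target <= hi:
            raise ValueError(
                f"oer_target {self.oxygen.oer_target} outside physiologic range [{lo}, {hi}]"
            )
        return self


def load_config(path: str | Path | None) -> ToolConfig:
    """Load a ToolConfig from a JSON or YAML file (defaults when path is None)."""
    if path is None:
        return ToolConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return ToolConfig.model_validate(data)


def write_sample_log(
    samples: list[BloodGasSample],
    path: str | Path,
    settings: Optional[PerfusionSettings] = None,
) -> None:
    """Write samples to the fixed-header CSV; blank cells mean missing.

    When pump settings are supplied they are echoed on every arterial row so
    a downstream session reconstructs the flow/pressure actually in effect.
    """
    rows = []
    for s in sorted(samples, key=lambda s: (s.time, s.site.value)):
        row = {c: "" for c in SAMPLE_LOG_COLUMNS}
        row["time_min"] = s.time
        row["site"] = s.site.value
        for col, field in _FIELD_BY_COLUMN.items():
            if col == "time_min":
                continue
            value = getattr(s, field)
            if value is not None:
                row[col] = value
        if settings is not None and s.site is SampleSite.arterial:
            row["cbf_ml_min"] = settings.cbf_setting
            row["map_mmhg"] = settings.mean_aortic_pressure
            row["temp_c"] = settings.temperature
        rows.append(row)
    pd.DataFrame(rows, columns=SAMPLE_LOG_COLUMNS).to_csv(path, index=False)


def read_sample_log(path: str | Path) -> list[dict]:
    """Parse the sample-log CSV into raw row dicts (canonical field names).

    Each dict carries the blood-gas fields (missing cells dropped) plus an
    optional ``settings`` entry when the row declares pump settings, and the
    1-based data ``line`` for diagnostics.  Unit conversion is not applied
    here; that is the session's job.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_min", "site", "po2_mmhg", "so2", "hb_g_dl") if c not in df.columns]
    if missing:
        raise InputError(f"sample log is missing required columns: {missing}")
    rows: list[dict] = []
    for i, rec in enumerate(df.to_dict("records")):
        raw: dict = {"line": i + 2}  # 1-based, after header
        site = rec.get("site")
        if isinstance(site, str):
            raw["site"] = site.strip().lower()
        for col, field in _FIELD_BY_COLUMN.items():
            value = rec.get(col)
            if value is not None and pd.notna(value):
                raw[field] = float(value)
        if pd.notna(rec.get("cbf_ml_min")) and pd.notna(rec.get("map_mmhg")):
            raw["settings"] = PerfusionSettings(
                cbf_setting=float(rec["cbf_ml_min"]),
                mean_aortic_pressure=float(rec["map_mmhg"]),
                temperature=float(rec["temp_c"]) if pd.notna(rec.get("temp_c")) else 34.0,
            )
        rows.append(raw)
    return rows
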