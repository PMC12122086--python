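"""Perfusion-run state: sample ingestion, snapshot pairing, trends, advisories.

A :class:`PerfusionSession` accumulates the blood-gas time series of one ex
situ perfusion run.  Arterial and venous samples arriving within a pairing
tolerance (default ±5 min) are combined into
:class:`~pmpkit.physiology.MetabolicSnapshot` records, each computed at the
pump flow and pressure active at the pair's midpoint time; every snapshot
also triggers a serial flow recalibration from the measured MVO2.  Lactate
trends are classified by least-squares slope, and electrolyte advisories are
emitted whenever a sample's ionized calcium, bicarbonate/pH or potassium
falls outside configurable clinical reference ranges.
"""

from __future__ import annotations

import enum
import json
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .physiology import (
    BloodGasSample,
    DonorProfile,
    InputError,
    MetabolicSnapshot,
    OxygenParameters,
    PerfusionSettings,
    SampleSite,
    cvr,
    delta_po2,
    mdo2,
    meo2,
    mvo2_measured,
    oxygen_content,
)
from .recommender import (
    CBFRecommendation,
    NormalizationConstants,
    RecommendationWithheld,
    recalibrate_cbf,
)

# Hemoglobin unit bridge, g/dL per mmol/L (monomer convention).  Declared
# here and echoed in config because laboratory conventions differ.
HB_GDL_PER_MMOL = 1.6113

#: Lactate slope (mmol/L per hour) separating rising/falling from stable.
LACTATE_SLOPE_THRESHOLD = 0.1

#: Pairing window for arterial/venous samples, minutes.
DEFAULT_PAIRING_TOLERANCE = 5.0


class DuplicateSampleError(InputError):
    """A sample with this (time, site) key is already in the session."""


class Analyte(str, enum.Enum):
    ionized_calcium = "ionized_calcium"
    bicarbonate = "bicarbonate"
    potassium = "potassium"


class AdvisoryThresholds(BaseModel):
    """Electrolyte reference ranges (standard clinical defaults, mmol/L)."""

    model_config = ConfigDict(frozen=True)

    ionized_ca_low: float = 1.1
    hco3_low: float = 21.0
    ph_low: float = 7.30
    k_low: float = 3.5
    k_high: float = 5.5


class AdvisoryItem(BaseModel):
    """One supplementation advisory for an analyte outside its range."""

    model_config = ConfigDict(frozen=True)

    analyte: Analyte
    measured: float
    threshold_low: float
    threshold_high: Optional[float] = None
    action: str


class TrendDirection(str, enum.Enum):
    rising = "rising"
    falling = "falling"
    stable = "stable"


class TrendSeries(BaseModel):
    """A metric time series with a slope-classified direction.

    ``direction`` is present only when at least three points are available.
    """

    metric: str
    points: list[tuple[float, float]]
    direction: Optional[TrendDirection] = None
    slope_per_hour: Optional[float] = None


class UnitHints(BaseModel):
    """How raw sample values are to be interpreted at ingestion.

    ``hb_unit`` is 'g_dl' or 'mmol_l'; ``so2_unit`` is 'fraction', 'percent'
    or 'auto' (values above 1 read as percent).
    """

    model_config = ConfigDict(frozen=True)

    hb_unit: str = "g_dl"
    so2_unit: str = "auto"


def normalize_units(raw: dict, hints: UnitHints = UnitHints()) -> dict:
    """Convert a raw sample mapping to canonical units (g/dL, fraction, mmHg)."""
    out = dict(raw)
    hb = out.get("hb")
    if hb is not None and hints.hb_unit == "mmol_l":
        out["hb"] = hb * HB_GDL_PER_MMOL
    so2 = out.get("so2")
    if so2 is not None:
        if hints.so2_unit == "percent":
            so2 = so2 / 100.0
        elif hints.so2_unit == "auto" and so2 > 1.0:
            # values in (1, 5) are neither a valid fraction nor a plausible
            # percent saturation; reject instead of guessing
            if so2 < 5.0:
                raise InputError(
                    f"ambiguous so2 value {so2}: not a fraction in [0, 1] and "
                    "too low to be a percent"
                )
            so2 = so2 / 100.0
        if not 0.0 <= so2 <= 1.0:
            raise InputError(f"so2 outside [0, 1] after unit conversion: {so2}")
        out["so2"] = so2
    return out


def compute_snapshot(
    arterial: BloodGasSample,
    venous: BloodGasSample,
    settings: PerfusionSettings,
    params: OxygenParameters,
) -> MetabolicSnapshot:
    """Derive the oxygen-handling state from one arterial/venous pair.

    Contents via the oxygen-content equation, consumption via Fick at the
    pump's actual flow setting; lactate is taken from the arterial sample.
    The snapshot is stamped at the pair's midpoint time.  Negative
    arteriovenous differences are preserved and flagged.
    """
    if arterial.site is not SampleSite.arterial or venous.site is not SampleSite.venous:
        raise InputError("compute_snapshot needs one arterial and one venous sample")
    cao2 = oxygen_content(arterial.hb, arterial.so2, arterial.po2, params)
    cvo2 = oxygen_content(venous.hb, venous.so2, venous.po2, params)
    flags: list[str] = []
    if cvo2 > cao2:
        flags.append("negative_extraction")
    cbf = settings.cbf_setting
    mvo2_value = mvo2_measured(cbf, cao2, cvo2) if cao2 > 0 else 0.0
    mdo2_value = mdo2(cbf, cao2)
    meo2_value = meo2(mvo2_value, mdo2_value) if mdo2_value > 0 else None
    dpo2 = delta_po2(arterial.po2, venous.po2)
    if dpo2 < 0 and "negative_extraction" not in flags:
        flags.append("negative_delta_po2")
    return MetabolicSnapshot(
        time=(arterial.time + venous.time) / 2.0,
        cao2=cao2,
        cvo2=cvo2,
        mdo2=mdo2_value,
        mvo2=mvo2_value,
        meo2=meo2_value,
        delta_po2=dpo2,
        cvr=cvr(settings.mean_aortic_pressure, cbf),
        lactate=arterial.lactate,
        cbf_setting=cbf,
        mean_aortic_pressure=settings.mean_aortic_pressure,
        flags=tuple(flags),
    )


def advise_electrolytes(
    sample: BloodGasSample,
    thresholds: AdvisoryThresholds = AdvisoryThresholds(),
) -> list[AdvisoryItem]:
    """Supplementation advisories for analytes outside their ranges.

    Ionized calcium below its floor, bicarbonate below its floor or an
    acidotic pH, and potassium outside its band each yield one advisory;
    analytes absent from the sample are skipped silently.
    """
    items: list[AdvisoryItem] = []
    if sample.ionized_ca is not None and sample.ionized_ca < thresholds.ionized_ca_low:
        items.append(
            AdvisoryItem(
                analyte=Analyte.ionized_calcium,
                measured=sample.ionized_ca,
                threshold_low=thresholds.ionized_ca_low,
                action="Ionized calcium low: consider calcium supplementation.",
            )
        )
    acidotic = sample.ph is not None and sample.ph < thresholds.ph_low
    if sample.hco3 is not None and (sample.hco3 < thresholds.hco3_low or acidotic):
        reason = "low bicarbonate" if sample.hco3 < thresholds.hco3_low else "acidotic pH"
        items.append(
            AdvisoryItem(
                analyte=Analyte.bicarbonate,
                measured=sample.hco3,
                threshold_low=thresholds.hco3_low,
                action=f"Consider bicarbonate supplementation ({reason}).",
            )
        )
    if sample.k is not None and not thresholds.k_low <= sample.k <= thresholds.k_high:
        direction = "low" if sample.k < thresholds.k_low else "high"
        items.append(
            AdvisoryItem(
                analyte=Analyte.potassium,
                measured=sample.k,
                threshold_low=thresholds.k_low,
                threshold_high=thresholds.k_high,
                action=f"Potassium {direction}: review potassium management.",
            )
        )
    return items


class PerfusionSession(BaseModel):
    """State of one perfusion run.

    Samples are kept strictly ordered by (time, site); each snapshot
    references exactly one arterial and one venous sample (recorded in
    ``pairs``).  ``recommendations`` holds the serial recalibrations, one per
    snapshot unless withheld (then a diagnostic is logged instead).
    """

    donor: DonorProfile
    params: OxygenParameters = OxygenParameters()
    constants: NormalizationConstants = NormalizationConstants()
    thresholds: AdvisoryThresholds = AdvisoryThresholds()
    unit_hints: UnitHints = UnitHints()
    pairing_tolerance: float = DEFAULT_PAIRING_TOLERANCE
    settings_history: list[tuple[float, PerfusionSettings]] = Field(default_factory=list)
    samples: list[BloodGasSample] = Field(default_factory=list)
    snapshots: list[MetabolicSnapshot] = Field(default_factory=list)
    recommendations: list[tuple[float, CBFRecommendation]] = Field(default_factory=list)
    pairs: list[tuple[float, float]] = Field(default_factory=list)
    advisories: list[tuple[float, AdvisoryItem]] = Field(default_factory=list)
    diagnostics: list[str] = Field(default_factory=list)

    # -- settings -----------------------------------------------------------

    def record_settings(self, time: float, settings: PerfusionSettings) -> None:
        self.settings_history.append((time, settings))
        self.settings_history.sort(key=lambda ts: ts[0])

    def active_settings(self, time: float) -> PerfusionSettings:
        """Pump settings last recorded at or before ``time`` (defaults if none)."""
        active = PerfusionSettings()
        for t, s in self.settings_history:
            if t <= time:
                active = s
            else:
                break
        return active

    # -- ingestion ----------------------------------------------------------

    def ingest_sample(self, raw: dict | BloodGasSample) -> Optional[MetabolicSnapshot]:
        """Normalize units, insert the sample in time order, and pair it.

        Returns the new snapshot when the sample completes an
        arterial/venous pair within the pairing tolerance, else None.
        Duplicate (time, site) keys are rejected.
        """
        if isinstance(raw, BloodGasSample):
            sample = raw
        else:
            sample = BloodGasSample(**normalize_units(raw, self.unit_hints))
        key = (sample.time, sample.site)
        if any((s.time, s.site) == key for s in self.samples):
            raise DuplicateSampleError(
                f"duplicate sample at t={sample.time} min, site={sample.site.value}"
            )
        self.samples.append(sample)
        self.samples.sort(key=lambda s: (s.time, s.site.value))
        advisories = advise_electrolytes(sample, self.thresholds)
        for item in advisories:
            self.advisories.append((sample.time, item))
        return self._try_pair(sample)

    def _paired_times(self, site: SampleSite) -> set[float]:
        idx = 0 if site is SampleSite.arterial else 1
        return {p[idx] for p in self.pairs}

    def _try_pair(self, sample: BloodGasSample) -> Optional[MetabolicSnapshot]:
        other_site = (
            SampleSite.venous if sample.site is SampleSite.arterial else SampleSite.arterial
        )
        used = self._paired_times(other_site)
        candidates = [
            s
            for s in self.samples
            if s.site is other_site
            and s.time not in used
            and abs(s.time - sample.time) <= self.pairing_tolerance
        ]
        if not candidates:
            return None
        mate = min(candidates, key=lambda s: (abs(s.time - sample.time), s.time))
        arterial, venous = (
            (sample, mate) if sample.site is SampleSite.arterial else (mate, sample)
        )
        midpoint = (arterial.time + venous.time) / 2.0
        snapshot = compute_snapshot(
            arterial, venous, self.active_settings(midpoint), self.params
        )
        self.pairs.append((arterial.time, venous.time))
        self.snapshots.append(snapshot)
        self.snapshots.sort(key=lambda s: s.time)
        try:
            rec = recalibrate_cbf(snapshot, self.donor, self.params, self.constants)
            self.recommendations.append((snapshot.time, rec))
        except RecommendationWithheld as exc:
            self.diagnostics.append(f"t={snapshot.time:g} min: recommendation withheld: {exc}")
        return snapshot

    # -- analytics ----------------------------------------------------------

    def lactate_trend(self, window: int = 5, site: SampleSite = SampleSite.arterial) -> TrendSeries:
        """Classify the lactate trend over the last ``window`` samples.

        Direction is rising/falling when the least-squares slope exceeds
        ±0.1 mmol/L per hour, stable in between, and absent with fewer than
        three lactate-bearing points.
        """
        pts = [
            (s.time, s.lactate)
            for s in self.samples
            if s.site is site and s.lactate is not None
        ][-window:]
        series = TrendSeries(metric="lactate", points=pts)
        if len(pts) >= 3:
            t_hours = np.array([p[0] for p in pts]) / 60.0
            values = np.array([p[1] for p in pts])
            slope = float(np.polyfit(t_hours, values, 1)[0])
            if slope > LACTATE_SLOPE_THRESHOLD:
                direction = TrendDirection.rising
            elif slope < -LACTATE_SLOPE_THRESHOLD:
                direction = TrendDirection.falling
            else:
                direction = TrendDirection.stable
            series = TrendSeries(
                metric="lactate", points=pts, direction=direction, slope_per_hour=slope
            )
        return series

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        """Deterministic single-document JSON serialization of the session."""
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PerfusionSession":
        return cls.model_validate(json.loads(text))
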