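"""Core oxygen-handling physiology for ex situ heart perfusion.

The donor heart on a machine-perfusion platform is kept beating in an
unloaded (Langendorff) state at 34 °C, so its oxygen consumption is driven
almost entirely by myocardial mass.  This module holds the domain types and
the elemental equations everything else is built from:

* arterial/venous oxygen content (Hüfner-bound plus dissolved oxygen),
* Fick-principle myocardial oxygen consumption (MVO2),
* oxygen delivery (MDO2), extraction (MEO2), coronary vascular resistance
  (CVR) and the arteriovenous oxygen-tension gradient (ΔPO2),
* heart-weight estimation from donor sex and body weight.

All functions are pure scalar computations; units are canonical throughout
(contents in ml O2/dL, flows in ml/min, tensions in mmHg, hemoglobin in
g/dL, saturations as fractions).  Contents are per deciliter while flows are
per milliliter, so every delivery/consumption formula carries an explicit
factor of 1/100.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator


class InputError(ValueError):
    """Raised when a physiologic input is missing, non-finite or out of range."""


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class SampleSite(str, enum.Enum):
    arterial = "arterial"
    venous = "venous"


# Heart-weight regressions on donor body weight (grams; BW in kg).
HEART_WEIGHT_SLOPE = {Sex.female: 2.153, Sex.male: 2.492}
HEART_WEIGHT_INTERCEPT = {Sex.female: 104.6, Sex.male: 141.2}


class OxygenParameters(BaseModel):
    """Constants of the oxygen-content and consumption model.

    ``huefner`` is the oxygen-binding capacity of hemoglobin (ml O2 per g Hb)
    and ``dissolved_coeff`` the solubility of oxygen in plasma (ml O2/dL per
    mmHg).  ``mvo2_per_gram`` is the expected myocardial oxygen consumption
    per gram of myocardium under subnormothermic unloaded conditions
    (physiologic range 0.08–0.13 ml/min/g) and ``oer_target`` the oxygen
    extraction ratio the flow recommendation drives toward (cardiomyocytes
    extract 70–80% of delivered oxygen).  The defaults satisfy
    100 x 0.10 / 0.80 = 12.5, the multiplier appearing in the personalized
    flow equations.
    """

    model_config = ConfigDict(frozen=True)

    huefner: float = Field(default=1.34, gt=0)
    dissolved_coeff: float = Field(default=0.0031, gt=0)
    mvo2_per_gram: float = Field(default=0.10, gt=0)
    oer_target: float = Field(default=0.80, gt=0, le=1.0)


#: Physiologic ranges used when validating configuration overrides.
MVO2_PER_GRAM_RANGE = (0.08, 0.13)
OER_TARGET_RANGE = (0.70, 0.80)

DEFAULT_OXYGEN_PARAMETERS = OxygenParameters()


class DonorProfile(BaseModel):
    """Donor characteristics driving heart-weight estimation.

    A measured heart weight, when available, overrides the sex/body-weight
    regression estimate everywhere downstream.
    """

    model_config = ConfigDict(frozen=True)

    sex: Sex
    body_weight: float = Field(gt=0, lt=400, description="kg")
    measured_heart_weight: Optional[float] = Field(default=None, gt=0, description="g")

    @field_validator("body_weight", "measured_heart_weight")
    @classmethod
    def _finite(cls, v):
        if v is not None and not math.isfinite(v):
            raise ValueError("must be finite")
        return v

    def heart_weight(self) -> float:
        """Heart weight in grams: measured if present, else estimated."""
        if self.measured_heart_weight is not None:
            return self.measured_heart_weight
        return estimate_heart_weight(self.sex, self.body_weight)


class BloodGasSample(BaseModel):
    """One timed arterial or venous perfusate blood-gas measurement.

    Canonical units are enforced on the stored fields: po2 in mmHg, so2 as a
    fraction in [0, 1], hb in g/dL.  Conversion from percent saturation or
    mmol/L hemoglobin happens at ingestion, never here.
    """

    model_config = ConfigDict(frozen=True)

    time: float = Field(ge=0, description="minutes since perfusion start")
    site: SampleSite
    po2: float = Field(gt=0, description="mmHg")
    so2: float = Field(ge=0, le=1, description="fraction")
    hb: float = Field(ge=0, description="g/dL")
    lactate: Optional[float] = Field(default=None, ge=0, description="mmol/L")
    ph: Optional[float] = None
    hco3: Optional[float] = Field(default=None, description="mmol/L")
    ionized_ca: Optional[float] = Field(default=None, description="mmol/L")
    k: Optional[float] = Field(default=None, description="mmol/L")

    @field_validator("time", "po2", "so2", "hb")
    @classmethod
    def _finite(cls, v):
        if not math.isfinite(v):
            raise ValueError("must be finite")
        return v


class PerfusionSettings(BaseModel):
    """Active pump settings.

    Defaults are the midpoints of the standard protocol windows: flow
    700–800 ml/min, aortic pressure 75–80 mmHg, temperature 34 °C.
    """

    model_config = ConfigDict(frozen=True)

    cbf_setting: float = Field(default=750.0, gt=0, description="ml/min")
    mean_aortic_pressure: float = Field(default=77.5, gt=0, description="mmHg")
    temperature: float = Field(default=34.0, description="degrees C")


class MetabolicSnapshot(BaseModel):
    """Derived oxygen-handling state at one timepoint.

    Built from one arterial/venous sample pair plus the active pump settings.
    ``flags`` records anomalies (e.g. negative extraction when the venous
    content exceeds arterial) rather than silently clipping them.
    """

    model_config = ConfigDict(frozen=True)

    time: float
    cao2: float
    cvo2: float
    mdo2: float
    mvo2: float
    meo2: Optional[float] = None
    delta_po2: float
    cvr: Optional[float] = None
    lactate: Optional[float] = None
    cbf_setting: float
    mean_aortic_pressure: float
    flags: tuple[str, ...] = ()


def estimate_heart_weight(sex: Sex, body_weight: float) -> float:
    """Estimate heart weight (g) from donor sex and body weight (kg).

    Sex-specific linear regressions: female 2.153·BW + 104.6,
    male 2.492·BW + 141.2.  Rejects negative or non-finite body weight;
    BW = 0 returns the regression intercept.
    """
    sex = Sex(sex)
    if not math.isfinite(body_weight) or body_weight < 0:
        raise InputError(f"body_weight must be finite and non-negative, got {body_weight}")
    return HEART_WEIGHT_SLOPE[sex] * body_weight + HEART_WEIGHT_INTERCEPT[sex]


def oxygen_content(
    hb: float,
    so2: float,
    po2: float,
    params: OxygenParameters = DEFAULT_OXYGEN_PARAMETERS,
) -> float:
    """Oxygen content of blood (ml O2/dL).

    Hüfner-bound term plus dissolved oxygen:
    ``huefner * hb * so2 + dissolved_coeff * po2``.
    """
    if not (math.isfinite(hb) and math.isfinite(so2) and math.isfinite(po2)):
        raise InputError("blood-gas values must be finite")
    if hb < 0 or po2 < 0:
        raise InputError("hb and po2 must be non-negative")
    if not 0.0 <= so2 <= 1.0:
        raise InputError(f"so2 must be a fraction in [0, 1], got {so2}")
    return params.huefner * hb * so2 + params.dissolved_coeff * po2


def mvo2_measured(cbf: float, cao2: float, cvo2: float) -> float:
    """Fick-principle myocardial oxygen consumption (ml O2/min).

    ``cbf * (cao2 - cvo2) / 100`` — the /100 bridges per-dL content to
    per-ml flow.  A negative result (venous content above arterial) is
    returned as-is; callers flag it rather than clip it.
    """
    if cbf <= 0:
        raise InputError(f"cbf must be positive, got {cbf}")
    if cao2 <= 0 or cvo2 < 0:
        raise InputError("cao2 must be positive and cvo2 non-negative")
    return cbf * (cao2 - cvo2) / 100.0


def mdo2(cbf: float, cao2: float) -> float:
    """Myocardial oxygen delivery (ml O2/min): ``cbf * cao2 / 100``."""
    if cbf <= 0:
        raise InputError(f"cbf must be positive, got {cbf}")
    if cao2 < 0:
        raise InputError("cao2 must be non-negative")
    return cbf * cao2 / 100.0


def meo2(mvo2: float, mdo2_value: float) -> float:
    """Myocardial oxygen extraction ratio (fraction): ``mvo2 / mdo2``.

    Equals the measured oxygen extraction ratio (CaO2 − CvO2)/CaO2 by
    construction.  Undefined at zero delivery.
    """
    if mdo2_value <= 0:
        raise InputError(f"mdo2 must be positive, got {mdo2_value}")
    return mvo2 / mdo2_value


def cvr(mean_aortic_pressure: float, cbf: float) -> float:
    """Coronary vascular resistance (mmHg·min/ml): aortic pressure / flow.

    The coronary venous (outflow) pressure is taken as zero in the drained,
    unloaded ex situ preparation, so the driving pressure is the mean aortic
    pressure alone.
    """
    if cbf <= 0:
        raise InputError(f"cbf must be positive, got {cbf}")
    if mean_aortic_pressure < 0:
        raise InputError("mean aortic pressure must be non-negative")
    return mean_aortic_pressure / cbf


def delta_po2(pao2: float, pvo2: float) -> float:
    """Arteriovenous oxygen-tension gradient (mmHg): arterial minus venous.

    Negative values (venous tension above arterial) are allowed and flagged
    by callers, as they usually mean swapped sampling sites.
    """
    if pao2 < 0 or pvo2 < 0:
        raise InputError("oxygen tensions must be non-negative")
    return pao2 - pvo2
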