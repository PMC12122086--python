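"""Personalized coronary blood flow recommendation.

The required coronary flow balances expected myocardial oxygen consumption
against perfusate oxygen content at a target extraction ratio:

    CBF_raw = HW · m / (CaO2/100 · OER_target)         [ml/min]

with HW the heart weight (g), m the expected consumption per gram
(ml O2/min/g) and CaO2 the arterial oxygen content (ml O2/dL).  At the
defaults (m = 0.10, OER = 0.80) this reduces to HW/CaO2 × 12.5.  The raw
value is then mapped onto the clinically admissible 500–800 ml/min window by
a sex-specific min-max normalization with clamping:

    CBF = 500 + 300 · clamp((CBF_raw − min_sex) / range_sex, 0, 1)

Serial recalibration replaces the mass-based consumption estimate with the
Fick-measured MVO2 of the most recent sample pair, keeping the target
extraction ratio in the denominator so the recommendation keeps driving
extraction toward the physiologic target.
"""

from __future__ import annotations

import enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .physiology import (
    DEFAULT_OXYGEN_PARAMETERS,
    DonorProfile,
    InputError,
    MetabolicSnapshot,
    OxygenParameters,
    Sex,
    oxygen_content,
)


class RecommendationWithheld(ValueError):
    """Raised when the input state is unfit for a flow recommendation
    (e.g. flagged negative measured consumption)."""


class RecommendationBasis(str, enum.Enum):
    estimated_mvo2 = "estimated_mvo2"
    measured_mvo2 = "measured_mvo2"


class NormalizationConstants(BaseModel):
    """Constants of the sex-specific min-max normalization.

    ``offset``/``scale`` define the output window (offset .. offset+scale,
    i.e. 500–800 ml/min by default); the per-sex ``min``/``range`` pairs are
    the extreme raw-flow values the window is anchored to, derived from
    perfusion experience.  Configurable because the anchors are empirical.
    """

    model_config = ConfigDict(frozen=True)

    scale: float = Field(default=300.0, gt=0)
    offset: float = Field(default=500.0, gt=0)
    female_min: float = Field(default=133.0)
    female_range: float = Field(default=333.0, gt=0)
    male_min: float = Field(default=178.0)
    male_range: float = Field(default=431.0, gt=0)

    def anchors(self, sex: Sex) -> tuple[float, float]:
        if Sex(sex) is Sex.female:
            return self.female_min, self.female_range
        return self.male_min, self.male_range


DEFAULT_NORMALIZATION = NormalizationConstants()


class CBFRecommendation(BaseModel):
    """A recommended pump flow with its normalization/clamp provenance."""

    model_config = ConfigDict(frozen=True)

    recommended_cbf: float
    unnormalized_cbf: float
    normalized_fraction: float
    clamped: bool
    basis: RecommendationBasis
    heart_weight_used: float
    inputs_echo: dict[str, float] = Field(default_factory=dict)


def cbf_unnormalized(
    heart_weight: float,
    cao2: float,
    params: OxygenParameters = DEFAULT_OXYGEN_PARAMETERS,
) -> float:
    """Raw required coronary flow (ml/min) before normalization.

    ``heart_weight * mvo2_per_gram * 100 / (cao2 * oer_target)``;
    equivalently ``heart_weight / cao2 * 12.5`` at the default parameters.
    """
    if heart_weight <= 0:
        raise InputError(f"heart_weight must be positive, got {heart_weight}")
    if cao2 <= 0:
        raise InputError(f"cao2 must be positive, got {cao2}")
    return heart_weight * params.mvo2_per_gram * 100.0 / (cao2 * params.oer_target)


def _normalize(x: float, sex: Sex, constants: NormalizationConstants) -> tuple[float, float, bool]:
    """Map a raw flow onto the output window; returns (cbf, fraction, clamped)."""
    lo, rng = constants.anchors(sex)
    f = (x - lo) / rng
    clamped = not 0.0 <= f <= 1.0
    f_clamped = min(1.0, max(0.0, f))
    return constants.offset + constants.scale * f_clamped, f, clamped


def personalize_cbf(
    donor: DonorProfile,
    hb: float,
    so2: float,
    po2: float,
    params: OxygenParameters = DEFAULT_OXYGEN_PARAMETERS,
    constants: NormalizationConstants = DEFAULT_NORMALIZATION,
) -> CBFRecommendation:
    """Baseline personalized flow from donor characteristics and the first
    arterial blood gas.

    Heart weight is the measured value when the donor profile carries one,
    otherwise the sex/body-weight regression estimate.
    """
    hw = donor.heart_weight()
    cao2 = oxygen_content(hb, so2, po2, params)
    x = cbf_unnormalized(hw, cao2, params)
    recommended, fraction, clamped = _normalize(x, donor.sex, constants)
    return CBFRecommendation(
        recommended_cbf=recommended,
        unnormalized_cbf=x,
        normalized_fraction=fraction,
        clamped=clamped,
        basis=RecommendationBasis.estimated_mvo2,
        heart_weight_used=hw,
        inputs_echo={"hb": hb, "so2": so2, "po2": po2, "cao2": cao2},
    )


def recalibrate_cbf(
    latest_snapshot: MetabolicSnapshot,
    donor: DonorProfile,
    params: OxygenParameters = DEFAULT_OXYGEN_PARAMETERS,
    constants: NormalizationConstants = DEFAULT_NORMALIZATION,
) -> CBFRecommendation:
    """Serial recommendation from the measured MVO2 of the latest snapshot.

    Substitutes the Fick-measured consumption for the mass-based estimate in
    the raw-flow equation (x = MVO2·100 / (CaO2·OER_target)) and applies the
    same sex-specific normalization.  Withheld when the snapshot carries a
    negative-extraction flag: a negative measured MVO2 indicates swapped or
    inconsistent samples, not a flow need.
    """
    if latest_snapshot.mvo2 < 0 or "negative_extraction" in latest_snapshot.flags:
        raise RecommendationWithheld(
            "measured MVO2 is negative (venous content exceeds arterial); "
            "check sample sites before acting on a recommendation"
        )
    if latest_snapshot.cao2 <= 0:
        raise InputError("snapshot cao2 must be positive")
    x = latest_snapshot.mvo2 * 100.0 / (latest_snapshot.cao2 * params.oer_target)
    recommended, fraction, clamped = _normalize(x, donor.sex, constants)
    return CBFRecommendation(
        recommended_cbf=recommended,
        unnormalized_cbf=x,
        normalized_fraction=fraction,
        clamped=clamped,
        basis=RecommendationBasis.measured_mvo2,
        heart_weight_used=donor.heart_weight(),
        inputs_echo={
            "mvo2": latest_snapshot.mvo2,
            "cao2": latest_snapshot.cao2,
            "time": latest_snapshot.time,
        },
    )


def recommendation_display(rec: CBFRecommendation | float) -> int:
    """Operator-display flow: rounded to the nearest 10 ml/min (half-even).

    The raw value stays on the recommendation record; only the display is
    rounded.
    """
    value = rec.recommended_cbf if isinstance(rec, CBFRecommendation) else float(rec)
    return int(round(value / 10.0) * 10)


def personalize_cbf_grid(
    sex: Sex,
    body_weight,
    hb,
    so2,
    po2,
    params: OxygenParameters = DEFAULT_OXYGEN_PARAMETERS,
    constants: NormalizationConstants = DEFAULT_NORMALIZATION,
) -> np.ndarray:
    """Vectorized baseline recommendation over broadcastable input arrays.

    Same computation as :func:`personalize_cbf` (regression heart weight
    only) for sweeping large donor/blood-gas grids; returns the recommended
    flow array.
    """
    sex = Sex(sex)
    bw = np.asarray(body_weight, dtype=float)
    from .physiology import HEART_WEIGHT_INTERCEPT, HEART_WEIGHT_SLOPE

    hw = HEART_WEIGHT_SLOPE[sex] * bw + HEART_WEIGHT_INTERCEPT[sex]
    cao2 = (
        params.huefner * np.asarray(hb, dtype=float) * np.asarray(so2, dtype=float)
        + params.dissolved_coeff * np.asarray(po2, dtype=float)
    )
    x = hw * params.mvo2_per_gram * 100.0 / (cao2 * params.oer_target)
    lo, rng = constants.anchors(sex)
    f = np.clip((x - lo) / rng, 0.0, 1.0)
    return constants.offset + constants.scale * f
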