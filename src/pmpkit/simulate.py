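"""Synthetic perfusion-run generator with known ground truth.

Emits blood-gas sample logs that emulate an ex situ heart perfusion session:
diluted perfusate hemoglobin (donor blood plus crystalloid prime and
albumin), hyperoxic arterial tensions from the high-oxygen gas mixture, and
venous values back-computed from the oxygen budget so that the Fick-implied
consumption at the pump flow equals a configured true MVO2.  Because the
venous side is derived from the budget rather than sampled independently,
the Fick identity holds exactly in the noise-free limit, which makes the
generator a round-trip oracle for the whole analysis pipeline.

Measurement noise model: ``measurement_noise_sd == 0`` is a fully
deterministic "exact" mode (analyzer scatter on arterial PO2 is off too, so
every snapshot reproduces the truth bit-for-bit).  With positive noise,
hemoglobin, saturation and tensions receive multiplicative analyzer error
after budget closure, and arterial PO2 additionally scatters around its mean
with the configured sd.  The latent arterial PO2 is constant over the run
(constant gas mixture).
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .physiology import (
    BloodGasSample,
    DonorProfile,
    InputError,
    OxygenParameters,
    PerfusionSettings,
    SampleSite,
    oxygen_content,
)


class ConfigurationError(ValueError):
    """The requested scenario is physically or structurally impossible."""


#: Latent arterial saturation: near-complete at hyperoxic tensions, kept just
#: below 1.0 so clipped analyzer noise stays nearly unbiased.
ARTERIAL_SO2_LATENT = 0.98

#: Monotone saturation -> oxygen tension lookup (fraction, mmHg) used to
#: assign a venous PO2 consistent with the back-computed venous saturation.
#: A coarse piecewise-linear table, not a dissociation-curve model.
SO2_TO_PO2_TABLE = (
    (0.00, 5.0),
    (0.20, 17.0),
    (0.40, 23.0),
    (0.50, 27.0),
    (0.60, 32.0),
    (0.75, 40.0),
    (0.85, 50.0),
    (0.90, 60.0),
    (0.95, 80.0),
    (0.98, 110.0),
    (1.00, 150.0),
)


def dilution_hb(
    donor_hb: float, blood_volume: float, crystalloid: float, albumin: float
) -> float:
    """Perfusate hemoglobin (g/dL) after diluting donor blood with prime.

    Simple conservation of hemoglobin mass over the combined volume:
    ``donor_hb * blood / (blood + crystalloid + albumin)``.
    """
    if blood_volume <= 0 or crystalloid < 0 or albumin < 0:
        raise InputError("blood volume must be positive, prime volumes non-negative")
    return donor_hb * blood_volume / (blood_volume + crystalloid + albumin)


#: Default perfusate hemoglobin: 14 g/dL donor blood diluted by the standard
#: minimum prime (1200 ml blood + 500 ml crystalloid + 100 ml albumin).
DEFAULT_PERFUSATE_HB = dilution_hb(14.0, 1200.0, 500.0, 100.0)


class SyntheticRunConfig(BaseModel):
    """Scenario parameters for a simulated perfusion session.

    The defaults describe a standard run: 4 hours sampled every 12 minutes,
    expected consumption 0.10 ml O2/min per gram myocardium, perfusate
    hemoglobin from the standard prime dilution, arterial PO2 around
    350 mmHg, 3% multiplicative analyzer noise.  ``scenario`` selects the
    lactate trajectory: 'viable' decays exponentially from 3.0 toward
    1.5 mmol/L, 'failing' rises linearly from 2.0 to 8.0 mmol/L.
    """

    model_config = ConfigDict(frozen=True)

    donor: DonorProfile
    duration: float = Field(default=240.0, gt=0, description="minutes")
    sampling_interval: float = Field(default=12.0, gt=0, description="minutes")
    true_mvo2_per_gram: float = Field(default=0.10, gt=0, description="ml O2/min/g")
    perfusate_hb: float = Field(default=DEFAULT_PERFUSATE_HB, gt=0, description="g/dL")
    arterial_po2_mean: float = Field(default=350.0, gt=0, description="mmHg")
    arterial_po2_sd: float = Field(default=30.0, ge=0, description="mmHg")
    measurement_noise_sd: float = Field(default=0.03, ge=0, description="fractional")
    scenario: str = Field(default="viable", pattern="^(viable|failing)$")
    seed: int = 0

    @model_validator(mode="after")
    def _duration_covers_two_samples(self):
        if self.duration < 2 * self.sampling_interval:
            raise ConfigurationError(
                f"duration ({self.duration} min) must be at least twice the "
                f"sampling interval ({self.sampling_interval} min)"
            )
        return self


def _venous_from_content(cvo2: float, hb: float, params: OxygenParameters) -> tuple[float, float]:
    """Solve (so2, po2) reproducing a venous oxygen content exactly.

    Two passes through the saturation->tension lookup (the dissolved term is
    a small correction), then a final saturation update against the settled
    tension so that re-evaluating the content equation returns ``cvo2`` to
    machine precision.
    """
    table = np.array(SO2_TO_PO2_TABLE)
    hb_capacity = params.huefner * hb
    so2 = cvo2 / hb_capacity
    for _ in range(2):
        po2 = float(np.interp(np.clip(so2, 0.0, 1.0), table[:, 0], table[:, 1]))
        so2 = (cvo2 - params.dissolved_coeff * po2) / hb_capacity
    if not 0.0 <= so2 <= 1.0:
        raise ConfigurationError(
            f"venous saturation {so2:.3f} outside [0, 1]; the oxygen budget "
            "is not representable at this hemoglobin"
        )
    return so2, po2


def _lactate(scenario: str, t: float, duration: float) -> float:
    if scenario == "viable":
        return 1.5 + 1.5 * math.exp(-t / 90.0)
    return 2.0 + 6.0 * t / duration


def ground_truth(
    config: SyntheticRunConfig,
    settings: PerfusionSettings = PerfusionSettings(),
    params: OxygenParameters = OxygenParameters(),
) -> dict:
    """Latent per-run quantities implied by a scenario (for sidecar logs)."""
    hw = config.donor.heart_weight()
    true_mvo2 = config.true_mvo2_per_gram * hw
    cao2 = oxygen_content(
        config.perfusate_hb, ARTERIAL_SO2_LATENT, config.arterial_po2_mean, params
    )
    cbf = settings.cbf_setting
    cvo2 = cao2 - true_mvo2 * 100.0 / cbf
    return {
        "heart_weight_g": hw,
        "true_mvo2_ml_min": true_mvo2,
        "cao2_ml_dl": cao2,
        "cvo2_ml_dl": cvo2,
        "mdo2_ml_min": cbf * cao2 / 100.0,
        "cbf_ml_min": cbf,
    }


def simulate_run(
    config: SyntheticRunConfig,
    settings: PerfusionSettings = PerfusionSettings(),
    params: OxygenParameters = OxygenParameters(),
) -> list[BloodGasSample]:
    """Generate the blood-gas sample log of one synthetic perfusion run.

    At each sampling time an arterial and a venous sample are emitted with
    the same timestamp.  Venous saturation and tension are derived from the
    oxygen budget so the Fick-implied consumption at the pump flow equals
    ``true_mvo2_per_gram x heart weight``; measurement noise (if any) is
    applied after budget closure.  Raises :class:`ConfigurationError` when
    the requested consumption exceeds what the flow can deliver.
    """
    truth = ground_truth(config, settings, params)
    if truth["cvo2_ml_dl"] <= 0:
        raise ConfigurationError(
            f"true MVO2 {truth['true_mvo2_ml_min']:.2f} ml/min exceeds the "
            f"oxygen delivery {truth['mdo2_ml_min']:.2f} ml/min at CBF "
            f"{settings.cbf_setting:.0f} ml/min; venous content would be negative"
        )
    so2_v, po2_v = _venous_from_content(truth["cvo2_ml_dl"], config.perfusate_hb, params)
    rng = np.random.default_rng(config.seed)
    nsd = config.measurement_noise_sd
    exact = nsd == 0.0
    times = np.arange(
        config.sampling_interval, config.duration + 1e-9, config.sampling_interval
    )
    samples: list[BloodGasSample] = []
    for t in times:
        t = float(t)
        if exact:
            hb_a, so2_a, po2_a = config.perfusate_hb, ARTERIAL_SO2_LATENT, config.arterial_po2_mean
            hb_v, so2_vm, po2_vm = config.perfusate_hb, so2_v, po2_v
        else:
            po2_scatter = rng.normal(0.0, config.arterial_po2_sd)
            noise = rng.normal(0.0, nsd, size=6)
            hb_a = config.perfusate_hb * (1.0 + noise[0])
            so2_a = float(np.clip(ARTERIAL_SO2_LATENT * (1.0 + noise[1]), 0.0, 1.0))
            po2_a = max((config.arterial_po2_mean + po2_scatter) * (1.0 + noise[2]), 1.0)
            hb_v = config.perfusate_hb * (1.0 + noise[3])
            so2_vm = float(np.clip(so2_v * (1.0 + noise[4]), 0.0, 1.0))
            po2_vm = max(po2_v * (1.0 + noise[5]), 1.0)
            # generator-side constraint: emitted venous content never exceeds
            # emitted arterial content, however the noise draws land
            cao2_m = oxygen_content(hb_a, so2_a, po2_a, params)
            cvo2_m = oxygen_content(hb_v, so2_vm, po2_vm, params)
            if cvo2_m > cao2_m:
                so2_vm = max(
                    0.0,
                    (cao2_m - params.dissolved_coeff * po2_vm) / (params.huefner * hb_v),
                )
        lactate = _lactate(config.scenario, t, config.duration)
        ica = float(rng.normal(1.18, 0.06))
        hco3 = float(rng.normal(23.5, 1.5))
        ph = float(rng.normal(7.38, 0.03))
        k = float(rng.normal(4.5, 0.35))
        samples.append(
            BloodGasSample(
                time=t, site=SampleSite.arterial, po2=po2_a, so2=so2_a, hb=hb_a,
                lactate=lactate, ph=ph, hco3=hco3, ionized_ca=ica, k=k,
            )
        )
        samples.append(
            BloodGasSample(time=t, site=SampleSite.venous, po2=po2_vm, so2=so2_vm, hb=hb_v)
        )
    return samples
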