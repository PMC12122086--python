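# Methods

## Physiologic model

The heart on an ex situ perfusion platform is unloaded (Langendorff mode),
beating at 65–80 bpm at 34 °C, so contractility and wall tension vary
little between donors and myocardial mass dominates oxygen consumption.
The model therefore reduces to three relations:

1. **Oxygen content** (ml O2/dL): `CaO2 = k·Hb·SO2 + α·PO2` with Hüfner
   constant k = 1.34 ml O2/g and plasma solubility α = 0.0031 ml O2/dL/mmHg.
   No temperature correction or hemoglobin P50/dissociation-curve modelling
   is applied (out of scope).
2. **Fick consumption**: `MVO2 = CBF·(CaO2 − CvO2)/100`. Contents are per
   deciliter while flows are per milliliter, so every delivery/consumption
   formula carries an explicit /100; this unit bridge is what makes the
   ×12.5 multiplier in the sex-specific flow equations exact
   (100 × 0.10 / 0.80 = 12.5).
3. **Heart-weight regressions** on body weight: female 2.153·BW + 104.6 g,
   male 2.492·BW + 141.2 g. A measured heart weight, when entered, overrides
   the estimate everywhere.

Derived monitoring quantities: delivery `MDO2 = CBF·CaO2/100`, extraction
`MEO2 = MVO2/MDO2` (identical to (CaO2−CvO2)/CaO2), tension gradient
`ΔPO2 = PaO2 − PvO2`, resistance `CVR = MAP/CBF`.

Two of these required a definitional choice the published panels do not
spell out:

* **CVR** is defined as mean aortic pressure divided by flow, taking the
  coronary venous pressure as zero — the ex situ preparation drains the
  right heart, so there is no meaningful back-pressure. Whether a venous
  pressure term belongs in the denominator on other rigs is configurable
  only by changing the pressure fed in.
* **ΔPO2** is the arterial-minus-venous tension at one timepoint (not a
  trend delta between timepoints). Negative values are preserved and
  flagged, never clipped — a venous tension above arterial almost always
  means swapped sampling sites, and clipping would hide the data-entry
  error.

## Flow recommendation

Baseline (no venous sample yet): expected consumption is
`HW × m` with m = 0.10 ml O2/min/g (physiologic range 0.08–0.13 under
subnormothermic resting conditions), and the raw required flow is

    CBF_raw = HW·m·100 / (CaO2 · OER_target),  OER_target = 0.80.

Raw values are then min–max normalized onto 500–800 ml/min with sex-specific
anchors (female min 133, range 333; male min 178, range 431) and clamped:
500 ml/min is the preclinical adequacy floor, 800 ml/min the protocol
ceiling; values outside the window are clamped, not extrapolated. The
anchors are empirical extremes from perfusion experience and are
configurable, never hard-coded at call sites.

**Serial recalibration** substitutes the measured Fick MVO2 of the latest
snapshot for `HW × m`, keeping `OER_target` (not the measured extraction)
in the denominator: the recommendation's purpose is to drive extraction
*toward* the physiologic target, and using measured extraction would make
the update a no-op. No temporal smoothing is applied across serial
recommendations — the latest snapshot wins; a smoothing policy would be a
clinical choice this package does not make. A recommendation is withheld
(with a diagnostic) when the measured MVO2 is negative.

Display values are rounded to the nearest 10 ml/min (half-even); the raw
value stays on the record.

## Session mechanics

* **Pairing**: arterial and venous samples within ±5 minutes form a
  snapshot stamped at the pair midpoint. The tolerance is a workflow
  choice (blood gases for one assessment are drawn together); it is
  configurable.
* **Active settings**: snapshots use the pump flow/pressure last recorded
  at or before the snapshot time (from the settings history or the CSV's
  settings columns), *not* the recommendation — the Fick computation needs
  the flow actually delivered.
* **Units**: canonical storage is g/dL, fraction, mmHg. Hemoglobin in
  mmol/L converts at 1.6113 g/dL per mmol/L (monomer convention; declared
  in config because lab conventions differ). Saturation values above 1 in
  'auto' mode are read as percent, except the ambiguous band (1, 5), which
  is rejected rather than guessed.
* **Lactate trend**: least-squares slope over the last 5 lactate-bearing
  arterial samples (arterial chosen, configurable), classified rising /
  falling / stable at ±0.1 mmol/L/h; at least 3 points required. The
  threshold is a sensitivity choice: analyzer repeatability on lactate is
  of order 0.1 mmol/L, so shallower slopes are indistinguishable from noise
  over a few hours.
* **Electrolyte advisories**: ionized calcium < 1.1 mmol/L; bicarbonate
  < 21 mmol/L or pH < 7.30; potassium outside 3.5–5.5 mmol/L — standard
  clinical reference ranges, fully overridable since the tool's published
  description prints no thresholds. Advisories are free-text actions; no
  dosing logic.

## Synthetic runs

The generator emulates a standard perfusion session: perfusate hemoglobin
from diluting 14 g/dL donor blood with the standard minimum prime
(1200 ml blood + 500 ml crystalloid + 100 ml albumin → 9.33 g/dL),
hyperoxic arterial tensions (mean 350 mmHg) from the high-O2 gas mixture,
latent arterial saturation 0.98, default 4 h duration sampled every 12 min
(20 pairs), default pump settings 750 ml/min at 77.5 mmHg.

Venous values are **derived from the oxygen budget**, not sampled
independently: venous content is set so the Fick-implied consumption at the
pump flow equals `true_mvo2_per_gram × HW`, and venous tension is assigned
from a fixed monotone piecewise-linear saturation→tension lookup (a coarse
documented table, deliberately not a dissociation-curve model), iterated so
the emitted (Hb, SO2, PO2) triple reproduces the venous content to machine
precision. The Fick identity therefore holds by construction and the
generator is a round-trip oracle for the analysis pipeline.

Noise model: with `measurement_noise_sd = 0` the run is fully deterministic
— analyzer scatter on arterial PO2 is off too — so noise-free runs
reproduce the true MVO2 bit-for-bit and the estimated and measured
recommendation pathways coincide. With positive noise (default 3%,
multiplicative, applied to Hb/SO2/PO2 after budget closure; arterial PO2
additionally scatters with sd 30 mmHg), saturations are clipped to [0, 1]
and the emitted venous content is capped at the emitted arterial content.
The latent arterial saturation sits at 0.98 rather than 1.00 so this
clipping stays nearly unbiased. Lactate follows the scenario
deterministically (viable: 1.5 + 1.5·exp(−t/90 min), decaying from 3.0
toward 1.5 mmol/L; failing: linear 2.0 → 8.0 mmol/L over the run);
electrolytes are drawn near clinical norms with occasional below-threshold
excursions. A single seed governs all draws.

What the generator does **not** emulate: edema formation and its effect on
resistance, temperature dynamics, hemolysis, real dissociation-curve
behavior, drifting pump settings, or irregular sampling. Passing the
round-trip and recovery tests shows the analysis pipeline is internally
consistent and unbiased under this noise model — not that the 0.10 ml/min/g
assumption or the normalization anchors are clinically correct for any
given heart.

## Numerical and interface choices

* Inputs are validated eagerly (pydantic); configuration overrides are
  additionally checked against the physiologic ranges (m ∈ [0.08, 0.13],
  OER ∈ [0.70, 0.80]).
* Degenerate inputs: zero delivery makes extraction undefined (reported
  missing, never 0/0); duplicate (time, site) samples are rejected so
  re-ingesting a log is idempotent; ties in pairing resolve to the nearest,
  then earliest, counterpart sample.
* The session serializes to a single self-contained JSON document (sorted
  keys), so a report is reproducible from the session file alone and
  serialization is bit-stable. Sample logs and reports are fixed-header
  CSVs; identical inputs and seeds yield byte-identical files.
* Problem sizes in the verification suite — the ~330k-point recommendation
  grid, 10k-sample oracle comparisons, 20-snapshot synthetic runs — were
  chosen to exercise every clamp branch and give sub-percent Monte-Carlo
  error on recovered MVO2 while keeping the whole suite fast on one CPU.

## Known limitations

* The heart-weight regressions and the 0.10 ml/min/g assumption inherit
  in-vivo physiology; true cardiac anatomy varies, and measured heart
  weight should be preferred when available.
* The normalization anchors are read from the published equation bodies;
  the original derivation table for these extremes is not public, so they
  may differ from the authors' source values. They are configuration, not
  constants.
* ΔPO2 and CVR conventions are this package's definitional choices (see
  above); other tools may define them differently.
* No rejection/acceptance decision logic, no pump control, no alarms.
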