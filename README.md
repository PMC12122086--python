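# pmpkit

Personalized coronary blood flow (CBF) settings and continuous metabolic
assessment for normothermic/subnormothermic **ex situ heart perfusion (ESHP)**.

Machine-perfusion platforms keep a donor heart beating outside the body
before transplantation, typically at a fixed pump flow of 700–800 ml/min.
That flow is 2–3× a resting heart's coronary flow, and excess flow drives
myocardial edema; too little flow starves the unloaded, 34 °C heart of
oxygen. `pmpkit` is for perfusionists and perfusion researchers: it computes
the pump flow that balances myocardial oxygen delivery (MDO2) against
consumption (MVO2) for an *individual* donor heart, and it tracks the
oxygen-handling state (MVO2, MDO2, MEO2, ΔPO2, CVR) and lactate trend over
a run, with electrolyte supplementation advisories.

## The model

Fick's principle ties consumption to flow and the arteriovenous content
difference:

    MVO2 = CBF · (CaO2 − CvO2) / 100        [ml O2/min; contents per dL]
    CaO2 = 1.34 · [Hb] · SaO2 + 0.0031 · PaO2   [ml O2/dL]

At baseline no venous sample exists yet, so MVO2 is estimated from
myocardial mass — heart weight HW (g) from sex-specific regressions on body
weight BW (kg):

    HW_female = 2.153 · BW + 104.6      HW_male = 2.492 · BW + 141.2

with an expected consumption of 0.10 ml O2/min per gram (range 0.08–0.13)
and a target extraction ratio OER = 0.80 (cardiomyocytes extract 70–80% of
delivered oxygen). Solving Fick for flow:

    CBF_raw = HW · 0.10 · 100 / (CaO2 · 0.80) = HW / CaO2 × 12.5   [ml/min]

This raw value (≈350 ml/min at typical inputs) is mapped onto the clinically
admissible window 500–800 ml/min by a sex-specific min–max normalization
with clamping (anchors: female 133/333, male 178/431):

    CBF = 500 + 300 · clamp((CBF_raw − min_sex) / range_sex, 0, 1)

Once arterial/venous sample pairs arrive, the recommendation is
recalibrated from the *measured* MVO2 in place of the mass-based estimate.

## Worked example

```
$ pmpkit recommend --sex male --weight 80 --hb 9 --so2 1.0 --po2 350
Heart weight used:    340.56 g
CaO2:                 13.145 ml O2/dL
Unnormalized CBF:     323.8 ml/min
Recommended CBF:      600 ml/min [raw 601.5]  basis=estimated_mvo2
```

An 80 kg male donor's heart is estimated at 340.56 g; with perfusate Hb
9 g/dL fully saturated at PaO2 350 mmHg the arterial content is
13.145 ml O2/dL, so the raw balanced flow is 323.8 ml/min — normalized into
the protocol window, the pump recommendation is 600 ml/min (raw 601.5),
well below the conventional 750 ml/min default.

A full monitored run, end to end:

```
$ pmpkit simulate --scenario viable --seed 42 --out log.csv
$ pmpkit recommend --sex male --weight 80 --hb 9 --so2 1.0 --po2 350 --session-out sess.json
$ pmpkit add-sample --session sess.json --csv log.csv
t=12 min  MVO2=39.66  MDO2=99.46 ml O2/min  MEO2=0.399  dPO2=332.1 mmHg  CVR=0.1033 mmHg.min/ml
  updated CBF recommendation: 640 ml/min [raw 636.3]
...
$ pmpkit report --session sess.json --out report.csv --plots plots/
```

Each snapshot line is one paired arterial/venous measurement: the measured
consumption (MVO2), delivery (MDO2), extraction fraction (MEO2), the
arteriovenous tension gradient and coronary vascular resistance, followed
by the flow recommendation recalibrated from that measured MVO2. The report
is a tidy CSV (one row per snapshot, plus lactate-trend labels) suitable
for spreadsheets or plotting.

The same API is available from Python (`pmpkit.personalize_cbf`,
`pmpkit.PerfusionSession`, `pmpkit.simulate_run`, ...); see
`docs/methods.md` for the model details and design choices.

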