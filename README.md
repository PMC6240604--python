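# ocorm

Analysis pipeline for the **optimized CO-rebreathing method (oCORM)**: total
hemoglobin mass (Hbmass) and intravascular volumes from capillary
carboxyhemoglobin (COHb) measurements, COHb washout-kinetics comparison
between heart-failure patients with severely reduced ejection fraction
(EFsev) and controls (CONT), and Monte Carlo quantification of the
systematic Hbmass error the conventional 6/8-min sampling protocol incurs
when vascular CO mixing is delayed.

It is written for clinical and exercise physiologists who run CO-rebreathing
exams, and for methodologists studying the measurement error of the
procedure. Because patient-level rebreathing data are not publicly
deposited, the package includes a first-class synthetic-cohort generator
calibrated to the published group characteristics, so every pipeline stage
is testable end to end.

## The calculations

An oCORM exam rebreathes a CO bolus for 2 min and samples capillary COHb
before and 3–15 min after the start. Hbmass follows from the CO mass
balance

```
Hbmass = K · MCO · 100 / (ΔCOHb% · 1.39)        [g]
```

with `K = (P_bar/760)·(1 + 0.003661·T)` the barometric/temperature gas
correction (an STPD-style division by the temperature term is available as
an option, and a session-supplied K is always used verbatim),
`MCO = CO_administered − CO_lost` the CO volume circulating (ml),
`ΔCOHb%` the mean of the 6- and 8-min COHb minus baseline, and 1.39 ml/g
Hüfner's number. Volumes derive as

```
RCV = Hbmass/MCHC · 100,   BV = RCV·100/(Hct·0.91),   PV = BV − RCV
```

where 0.91 converts capillary/venous hematocrit to whole-body hematocrit.

For kinetics, each complete series is normalized to its 15-min value
(×100) and a linear mixed model (random intercept per subject, time ×
group fixed effects with orthogonal polynomial contrasts) estimates
per-timepoint EFsev−CONT differences and the time×group interaction.

For error propagation, multiplicative Normal factors — mean +1.0% (SD
0.7%) at 6 min and +0.4% (SD 0.6%) at 8 min, the group-level inflation of
early COHb readings under delayed mixing — are drawn 100,000 times per
exam, Hbmass is recomputed per draw, and simulated − measured differences
are summarized (negative = underestimation by the conventional protocol).

## Worked example

```python
from ocorm import RebreathingSession, analyze_session, HematologyPanel

session = RebreathingSession(
    subject_id="exam_001",
    k_factor=0.923,                 # supplied by the rebreathing device
    co_administered=42.5,           # ml CO into the circuit
    co_lost=0.0,                    # losses already netted out
    cohb_baseline=0.90,             # % COHb before rebreathing
    cohb_series=((6.0, 5.30), (8.0, 5.10)),
)
panel = HematologyPanel(hb_conc=13.0, hct=39.0)
result = analyze_session(session, panel)
print(f"dCOHb   {result.delta_cohb:.2f} %-points")
print(f"Hbmass  {result.hbmass_g:.0f} g")
print(f"RCV     {result.rcv_ml:.0f} ml")
print(f"BV      {result.bv_ml:.0f} ml")
print(f"PV      {result.pv_ml:.0f} ml")
```

prints

```
dCOHb   4.30 %-points
Hbmass  656 g
RCV     1969 ml
BV      5548 ml
PV      3579 ml
```

i.e. the COHb rise of 4.30 points on a 42.5 ml circulating CO dose implies
656 g of hemoglobin; with this subject's Hb 13 g/dL and Hct 39 % that
corresponds to about 5.5 L of blood, of which 3.6 L is plasma.

The same calculation is available from the shell, along with cohort
simulation, kinetics contrasts, and the error simulation:

```
ocorm simulate --n-cont 25 --n-efsev 21 --seed 1 --out-dir cohort/
ocorm compute cohort/sessions.csv --out results.csv
ocorm kinetics cohort/kinetics_long.csv --out contrasts.csv --fig curves.png
ocorm mc-error src/ocorm/data/example_sessions.csv --seed 0 --out mc.csv
```

The last command prints `average CV: -0.85% over 3 subjects`: across the
three packaged example exams the delayed-mixing error model shifts the
measured Hbmass down by a little under one percent on average.

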