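# Methods

## Measurement model

oCORM determines total hemoglobin mass by CO dilution. The package treats
one exam as: environmental conditions (barometric pressure, temperature),
CO dose accounting (administered volume, losses to circuit/lung/exhalation),
a pre-rebreathing COHb baseline, and capillary COHb at up to six timepoints
(3, 6, 8, 10, 12, 15 min after the start of rebreathing). The mass balance

    Hbmass = K · MCO · 100 / (ΔCOHb% · 1.39)

assumes the CO tracer is fully mixed through the vascular compartment at the
sampling times and that 1 g Hb binds 1.39 ml CO (Hüfner's number). ΔCOHb is
the mean COHb at the configured sampling times (default 6 and 8 min) minus
baseline; pooling the COHb values before subtracting the baseline is
numerically identical to averaging per-time differences.

**K conventions.** The correction factor is implemented in two conventions
behind a flag: `as_printed`, `(P/760)·(1+0.003661·T)`, and `stpd`,
`(P/760)/(1+0.003661·T)`. They disagree about the direction of the
temperature term; device-reported K values near 0.93 at room conditions are
consistent only with the sub-unity (`stpd`) form, while published formula
text multiplies. The default is `as_printed`, and whenever a session record
carries its own K (as exported session tables do) that value is used
verbatim, which makes the choice moot for such records. CO losses are
required inputs (single figure or itemized components), never estimated
internally.

**Volumes.** RCV = Hbmass/MCHC·100; BV = RCV·100/(Hct·f) with the
whole-body hematocrit factor f = 0.91 (configurable); PV = BV − RCV. BV is
returned as RCV + PV so the conservation identity holds bit-exactly. When a
session lacks a hematology panel, Hbmass is still computed and the volumes
are reported as absent. MCHC, when not given, is derived from Hb and Hct; a
supplied MCHC deviating more than 15% from the Hb/Hct-implied value is
rejected as inconsistent.

**Safety flag.** Any COHb reading above 10% (configurable) sets a warning
flag on the result; it is never an error. Readings below baseline are
likewise flagged, not rejected.

## Kinetics analysis

COHb declines after the rebreathing period as CO redistributes and is
slowly eliminated; by 15 min the slow, near-linear washout phase is assumed
reached. Each complete series is therefore normalized to its 15-min value
(×100), which removes the subject's COHb level and isolates mixing shape.
Subjects missing any post-rebreathing timepoint are excluded listwise and
the count reported.

The model is a linear mixed model: random intercept per subject; fixed
effects for time, group, and time×group. Time enters as a categorical
factor re-expressed in orthonormal polynomial contrasts over the observed
timepoints — a saturated basis, so per-timepoint group contrasts are
unsmoothed cell-mean differences rather than projections onto a low-degree
trend — and the time×group interaction is reported per polynomial degree
(1–3 by default). Two numerical choices matter:

- The 15-min cell is excluded from the model response. After normalization
  it is identically 100 for every subject (zero variance); it serves only
  as the anchor. Its group difference is structurally zero.
- Contrast and interaction p-values use a t reference with
  df = n_subjects − 2, the between-subject degrees of freedom appropriate
  for a group contrast; the large-sample normal approximation is
  anti-conservative at the cohort sizes typical here (≈20/group).

The group main effect is included alongside the interactions, so reported
per-timepoint contrasts are total EFsev−CONT differences on the normalized
scale.

## Monte Carlo error propagation

Delayed vascular mixing inflates early COHb readings in the EFsev group.
The error model takes the group-level regression coefficients as given:
the 6-min COHb is multiplied by a factor drawn from Normal(1.010, 0.007)
and the 8-min value by Normal(1.004, 0.006), independently by default (a
common-draw mode is provided; the correlation between the two timepoints'
errors is unknown). Per draw, ΔCOHb and Hbmass are recomputed with the
session's K and MCO, and the difference simulated − measured is recorded;
100,000 repetitions by default. The difference is defined as simulated −
measured so that inflated COHb yields negative values (underestimation),
matching the sign convention of published per-subject results; descriptive
text sometimes states the subtraction the other way around, which conflicts
with those signs.

Summaries: mean difference, min/max over draws, central 90% interval,
relative error (CV = mean difference / measured × 100), and the unweighted
cohort average of per-subject CVs. Draws producing non-positive ΔCOHb are
discarded and counted; a discard fraction above 1% raises, as it indicates
an unphysical configuration. Published per-subject "ranges" (≈ ±1.7 SD
around the mean) are not consistent with a min/max over 100,000 draws, so
no range is asserted in tests; both summaries are reported.

Two caveats established during validation:

- Because the Hbmass formula is convex in ΔCOHb, the Monte Carlo mean
  exceeds the plug-in deterministic shift by a second-order (Jensen) term
  ≈ Hbmass·Var(ΔCOHb′)/ΔCOHb′², about 0.01–0.04 g at default parameters.
  The convergence test uses the second-order-corrected oracle.
- For the first packaged example subject, the stated procedure on its
  printed inputs yields ≈ −3.8 g where the published table prints −4.1 g
  (subjects 2 and 3 reproduce closely); possibly unrounded coefficients or
  inputs were used originally. Tests assert subjects 2–3 and the cohort
  average only.

## Synthetic cohort generator

The generator emulates a two-group study: 25 controls and 21 patients with
EF < 30% by default. Per subject it samples sex (female fraction 10/25 vs
6/21), height (175 ± 7 cm male, 165 ± 6 cm female — not published; package
defaults), BMI (22.7 ± 2.6 vs 27.6 ± 3.2 kg/m², giving body mass),
Hbmass per kg (12.0 ± 2.5 vs 10.6 ± 1.6 g/kg, so true Hbmass =
per-kg × mass), Hb (15.2 ± 1.4 vs 16.2 ± 1.7 g/dL) and Hct (41.9 ± 3.7 vs
44.2 ± 4.0%) drawn jointly with correlation 0.8 so the implied MCHC stays
physiologic (MCHC is then derived from Hb/Hct with 0.3 g/dL jitter, never
sampled independently), baseline COHb uniform on 0.8–1.4%, a target
6/8-min COHb rise (4.46 ± 0.85 points), a 2-min CO uptake fraction
(0.92 ± 0.03), and ambient conditions (755 ± 5 mmHg, 21 ± 2 °C). All
sampled quantities are truncated to physiologic ranges by resampling.

**Dosing.** The CO dose is chosen by inverting the mass balance:
MCO = Hbmass·1.39·ΔCOHb_target/(100·K), administered = MCO/uptake, residual
= administered − MCO. This makes the noiseless exam an exact round trip:
the deterministic analysis recovers the true Hbmass to floating-point
precision, for both groups.

**Time courses.** Each group has a normalized washout curve C(t) with
C(15) = 100: the reference curve r(t) plus, for EFsev, the excess
δ(t) = (2.8, 1.0, 0.4, 0.5, 0.3, 0) points at (3, 6, 8, 10, 12, 15) min —
the published normalized group differences. The subject's raw series is
COHb(t) = S·C(t)/100 with S chosen so that mean(COHb@6, COHb@8) − baseline
equals the Hbmass-implied target rise. Two properties follow by
construction: 15-min-normalized values equal C(t) exactly, so kinetics
contrasts recover δ without bias; and the 6/8-min anchor preserves the
round trip. Gaussian measurement noise (SD 0.05 points per capillary
sample, hemoximeter scale) and recording rounding (0.01 points) are applied
last; `CohortConfig.noiseless()` disables both.

The reference curve itself is not a published quantity. The default,
r = (110.0, 103.5, 102.3, 101.5, 100.7, 100), together with the target-rise
mean of 4.46 points, was calibrated analytically so that the pooled cohort
reproduces the published absolute COHb means of 6.0% at 3 min and 5.6% at
6 min given the baseline distribution and the EFsev offsets; both are
config-exposed and clearly non-published defaults.

**Missingness.** Optionally, exams lose one random post-rebreathing
timepoint with probability 0.114 (the published exclusion rate for
incomplete sampling) and are flagged as CO-leakage failures with
probability 0.143 (the published leakage failure rate). Leakage-flagged
exams are dropped from the kinetics table.

**What the generator does not emulate.** No mechanistic circulation or CO
transport model — EF is a group label, and the kinetics difference is
imposed, not emulated hemodynamically; no per-subject correlation between
Hbmass and the mixing delay; no venous-vs-capillary sampling differences;
per-timepoint raw-COHb dispersion beyond 3/6 min extrapolates the published
1.0-point SD. Passing recovery tests therefore show the pipeline's
statistics are unbiased under the stated data-generating process, not that
real patient curves follow it.

## Problem sizes and determinism

Default test/validation sizes: 1,000 subjects for round-trip and
calibration checks, 200 per group for contrast recovery, 500 cohorts of
15+15 for the type-I-error check, and 100,000 Monte Carlo repetitions per
exam (vectorized; runs in milliseconds). Every stochastic entry point takes
a seed (or NumPy `Generator`) and is bit-reproducible under it; the
acceptance script derives all sub-seeds from its single `--seed` argument.

## Known limitations

- The kinetics mixed model assumes a compound-symmetric within-subject
  covariance; the normalization denominator in fact induces a slightly
  heavier shared component. At the tested sizes the contrast estimates are
  unbiased and type-I error is nominal, but SEs are approximate.
- The error-factor model applies at 6/8-min sampling only; it says nothing
  about protocols sampling at 12/15 min, where the delayed-mixing error
  should largely vanish.
- The 2-min uptake fraction is a proxy proportional to pulmonary CO
  diffusion capacity, not an estimate of it.
- Group labels are limited to CONT/EFsev; moderately reduced EF is out of
  scope.
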