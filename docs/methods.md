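# Methods

`tbmdose` designs weight-band tablet regimens for the 6-month intensive
paediatric TB-meningitis regimen (daily rifampicin R, isoniazid H,
pyrazinamide Z and ethionamide Eto) by Monte Carlo simulation of
steady-state exposure in a virtual paediatric population.  This note
documents the models, the numerical choices, and what the packaged
parameter sets do and do not represent.

## Virtual population

Weights are uniform per 1-kg band (the study design: equal information per
band, not a demographic weight distribution), default 3–35 kg.  The sex
split per band is deterministic — `ceil(n·female_fraction)` females — so a
50 % specification is met exactly.

Age is sampled conditional on weight by inverting a packaged sex-specific
weight-for-age reference (`data/growth_reference.yaml`): a log-normal
deviation from the median curve is drawn, truncated to the admissible age
window, and the monotone median curve is inverted at `weight/exp(dev)`.
Height then follows from a height-for-age reference at the drawn age with
its own log-normal spread.  The medians are an approximate compilation in
the style of the WHO growth standards/reference and are deliberately
editable config.  The weight-for-age log-SD (0.15) is wider than a healthy
reference: children treated for TB in high-burden settings are often
underweight-for-age, and the published tables dose 3–4 kg children older
than 3 months, who only exist under a wide weight-for-age spread.  Subjects
heavier than 6 kg are never assigned an age below 3 months (truncation in
the sampler), and the under/over-3-month strata of the dosing tables are
drawn by conditioning the same sampler on the age window.

Postmenstrual age is `40 weeks + age`; term birth is assumed because no
gestational-age distribution is modelled.  Fat-free mass uses the
maturation-adjusted BMI-based equation (adult limit: the familiar
sex-specific 9270·W/(6680+216·BMI) form), clamped strictly below total
weight; it is a pluggable function and tests assert only its structural
properties.  NAT2 acetylator classes are independent draws at 44 % slow,
42 % intermediate, 14 % fast.

What the generator does *not* emulate: malnutrition as a covariate of PK
(only as weight-for-age spread), HIV status, prematurity, or any
disease-severity covariates.  Tests passing on this population show the
machinery is correct under these demographics, not that exposures are
accurate for, say, premature neonates.

## Drug models

Each drug is a one-compartment oral model reduced to what steady-state
AUC0–24 needs:

* clearance: `CL = CL_typ · (size/ref)^0.75 · maturation(PMA) · NAT2 · DDI ·
  exp(η)`, volume scaled with exponent 1 (allometric exponents fixed);
* maturation: Hill sigmoid of postmenstrual age,
  `PMA^h / (TM50^h + PMA^h)`;
* bioavailability: for R and H, a linear rise with age from
  `fraction_at_birth·F_typ` at birth to `F_typ` at a plateau age (2 y / 1 y);
* NAT2 (isoniazid): slow = 0.5 × fast by construction (validated at load);
  intermediate defaults to the geometric mean of slow and fast;
* DDI (ethionamide): a clearance multiplier applied when rifampicin is
  co-administered (always true in this regimen);
* rifampicin: Michaelis–Menten hepatic elimination (Vmax, Km) on the
  central compartment, with the covariate chain applied to Vmax.

Between-subject variability is log-normal.  In the reference set it is
placed on CL only (apparent-clearance convention): for AUC, variability in
F and CL are indistinguishable, and keeping F deterministic preserves the
0 < F ≤ 1 invariant without truncation.  Since only medians and percentile
spreads are reported — and medians of log-normal effects equal the typical
value — this choice does not move any reported central value.

For linear elimination, steady-state AUC0–24 is exactly `F·dose/CL`,
independent of absorption, so no integration is performed.  Absorption
detail (transit compartments, lag times) is therefore omitted everywhere;
for rifampicin, where the concentration profile matters, first-order
absorption (ka) is retained.

### Parameter provenance and calibration

The packaged **reference** set (`data/drug_models_reference.yaml`) is *not*
a transcription of any single published analysis.  Structure follows the
model features described above; magnitudes (V, ka, BSV) are
literature-typical; and two groups of values are **calibrated against the
published outputs packaged with this library**:

1. *Shape* — maturation (TM50, hill) per drug and the infant
   bioavailability fraction for R and H are least-squares fitted to the
   per-band median AUCs of the published child-friendly dosing table
   (34 bands, overall scale profiled out).  Residual: ≈ 4 % RMS, 14 % worst
   band.
2. *Scale* — typical clearances (Vmax/Km for rifampicin) are solved so that
   the derived exposure-target windows reproduce the published panel
   targets (54.5–78.2, 47.6–59.4, 389–535, 21.9–30.1 mg·h/L) on a
   1000-per-band population.

`scripts/calibrate_reference.py` reproduces both steps.  Consequences to
keep in mind: agreement of derived targets and band medians with the
published values is a *calibration check* (it validates the pipeline's
self-consistency), not an independent prediction; and the **toy** set with
round numbers exists so that every structural unit test is independent of
this calibration.  One structural remark: the published isoniazid window
(47.6–59.4 at 15–20 mg/kg) is sub-proportional in dose, which no
linear-elimination model can match at both ends; the calibrated model
brackets it symmetrically (derived ≈ 46.0–61.4).

## Exposure computation

* Linear drugs: closed form, exact.
* Rifampicin: repeated daily dosing integrated until the per-interval AUC
  changes by < 0.1 % between successive intervals (steady state by
  convergence, robust across saturation regimes), error after 96 intervals.
  Two integrators: a scalar reference (`solve_ivp`, LSODA, rtol 1e-8,
  atol 1e-10) and a vectorized fixed-step RK4 (dt = 0.1 h) used at
  population scale; they agree to ≲0.01 % and both match the closed form in
  the linear limit (Km → ∞) to < 0.1 %, which the test suite asserts.
* A steady state only exists while `F·dose < 24·Vmax` for a subject; the
  band search caps enumerated doses at 80 % of the band's smallest daily
  elimination capacity so the integrator always converges quickly.
* Percentiles (5/25/50/75/95) use linear interpolation between order
  statistics (`numpy.percentile` default).

## Exposure targets

The acceptable AUC0–24 window per drug is operational, not PK-PD based:
the median simulated exposure in children ≤ 25 kg (infants < 3 months
excluded by default) at the lower and upper bound of the endorsed mg/kg
range — R 22.5–30, H 15–20, Z 32–44, Eto 16–22 mg/kg.  mg/kg doses are
exact in this step, not rounded to tablets.  The same realized random
effects are reused at both bounds (common random numbers), so for linear
drugs the window scales exactly with the dose bounds.  The published
window values are also packaged verbatim (`data/panel_targets.json`) and
are the default for table building.

## Regimen search

Per 1-kg band and drug, the median-AUC-versus-dose map is exact for linear
drugs (`dose · median(F/CL)`) and cached-by-dose for rifampicin.  Counts
are enumerated per formulation in steps of 0.5 for dispersible (scored)
tablets and 1 for adult tablets; quarter tablets are unrepresentable by
construction.  Formulations sharing a drug (e.g. an FDC and its top-up)
form one search component; disjoint components are searched independently.

The published strategy was chosen by an expert panel balancing target
attainment, tablet burden and band count qualitatively.  The optimizer
formalizes this as a greedy maximal-run rule: at each band, prefer the
count vector whose simulated medians stay within every drug's window for
the longest stretch of consecutive bands (ties: whole tablets over halves,
lower physical-tablet burden, lexicographic counts).  Where no vector is
on-target — e.g. adult RH 150/75, whose 2:1 ratio cannot satisfy both R and
H — it falls back to minimax |deviation|, with two refinements: an optional
per-drug `forbid_above` rule (used for rifampicin with adult formulations,
encoding the panel's preference for isoniazid-below over rifampicin-above)
and a merge-slack (default 8 percentage points) that lets a fallback
vector keep covering neighbouring bands to limit band count, but never
across a band that some other vector could dose on-target.  Bands with the
same counts are merged for display; merging is pure grouping and changes no
dose.  An infeasible band (even the smallest counts overshoot) receives the
smallest administrable counts and is flagged off-target rather than
dropped.

Because the objective is a formalization and the reference models are
calibrated rather than transcribed, the optimizer reproduces the published
tables' *behaviour* (infant strata dosed separately, halves below ~10 kg,
isoniazid below range above 25 kg with adult FDCs, burden ≈ 19–20 with
child-friendly formulations at 25 kg+) but not necessarily the panel's
exact counts row by row.

Deviation from the window is 0 inside, else the signed percent distance to
the nearer bound (relative to that bound), computed on unrounded AUCs and
rounded to one decimal only for display.  Colour semantics: green within,
yellow below, purple above.  Tablet burden counts physical tablets
handled: per-formulation counts rounded up, then summed (1.5 + 0.5 + 0.5 →
2 + 1 + 1 = 4).  Display rounding: AUC one decimal, pyrazinamide three
significant figures, deviations one decimal.

## Audits of the published tables

The packaged CSV transcriptions of the three published dosing tables are
inputs, and `recheck_printed_tables` re-derives every cell's deviation and
burden from printed AUCs/counts plus the packaged windows.  209/216
deviation cells and all burdens reproduce exactly; the seven mismatches are
one-decimal artefacts of recomputing from AUCs printed at one decimal
(three significant figures for pyrazinamide), and the audit lists them
rather than hiding them.

## Problem sizes and determinism

Default sizes: 5,000 subjects per band (160,000 total) for population-level
checks; 1,000 per band for target derivation; 400–500 per band for table
building — at 400+, band medians are stable to well under one display
decimal.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns keyed by stage and band, so results are
independent of which other bands are built and full pipeline runs are
byte-identical under seed replay (asserted in the tests via manifest
SHA-256).

## Known limitations

* No Cmax, time-above-MIC, CSF-penetration or protein-binding metrics;
  AUC0–24 is the only exposure index.
* The reference parameter set is calibrated to published summary outputs,
  not fitted to concentration data; individual-level dispersion (BSV
  magnitudes) is literature-typical, so percentile whiskers are indicative
  only.
* The growth reference is an approximate compilation; for regulatory use,
  swap in an authoritative table (the YAML schema is the interface).
* The optimizer's tie-breaks are a formalization of qualitative expert
  trade-offs; alternative regimens with equal worst-case deviation exist
  and can be explored through `SearchOptions`.
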