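# Methods

## Scope and model

The package evaluates transwell BBB models from compartment-concentration
timecourses alone. The physical picture is a two-compartment system —
luminal (apical, A) and abluminal (basolateral, B) media separated by a
porous membrane carrying the cell layer — exchanging solute by passive
diffusion, optionally with a polarized active component. No intracellular
compartment, metabolism, protein binding or unstirred-layer term is
modeled: assays run on a rocking shaker, and the estimator only ever sees
the two bulk concentrations.

## The clearance estimator

`cleared_volume` converts each timepoint to the donor-equivalent volume
transferred, `V(t) = C_r V_r / C_d` (μL). `fit_ps` takes the OLS slope of
V against time **with a free intercept** — an early-time lag then shifts
the intercept (reported as a diagnostic) instead of biasing the slope.
A non-positive slope marks the fit unusable; downstream stages refuse
unusable fits rather than silently clamping. `correct_for_membrane`
applies the series-barrier identity `1/PS_e = 1/PS_total − 1/PS_mem` and
raises when `PS_total ≥ PS_mem` (a cell layer cannot make the insert
leakier than the blank; such replicates are excluded, not clamped).
`pe_from_ps` divides by the membrane area and converts
(μL/min)/cm² → 10⁻⁶ cm/s via the factor 1000/60.

Donor handling: with per-timepoint donor measurements the measured value
is used (`donor_mode="measured"`, default); otherwise the nominal dosing
concentration (sink approximation). Under < 10 % donor depletion the two
agree within a few percent.

Units: concentrations are carried as amount per μL in whatever amount unit
the file uses — cleared volume is a concentration *ratio*, so Pe is
invariant to rescaling all concentrations (property-tested). Times are
minutes everywhere; seconds appear only in the final Pe conversion.

## Validity envelope (measured, not assumed)

The slope estimator assumes sink conditions in **every fitted insert,
blank included**. This matters more than is usually acknowledged: a blank
insert 10× as permeable as a Pe ≈ 20×10⁻⁶ cm/s cell layer depletes its
donor by ~90 % over a 60-min, 4-point sampling window in 24-well geometry.
The fitted PS_mem then under-reads badly (−31 % in the B2A orientation,
whose receiver is the small luminal compartment), and because the
membrane correction subtracts `1/PS_mem`, the recovered ER inflates by
~8 % at that scale. Against the simulator's ground truth the pipeline
recovers:

- configured Pe and ER within 2 % (ER = 1 within 1 %) whenever all inserts
  stay below 10 % donor depletion over the window — e.g. Pe 2 vs
  4×10⁻⁶ cm/s with a 10×-permeable blank, the validation scenario used by
  the tests and the acceptance script;
- a systematic *upward* ER bias growing with PS·t·(1/V_d + 1/V_r) outside
  that envelope.

Blank matching is configurable: the default corrects each direction with
blanks run in that direction (`per_direction`), which empirically cancels
the orientation-specific biases at ER = 1; `luminal` estimates PS_mem from
A2B-orientation blanks only (an inert membrane's PS is
orientation-independent, and that orientation stays linear longest) and is
preferable for strongly polarized layers measured outside the sink regime.

## Statistics

Directional significance is a two-sample, two-tailed, equal-variance
Student's t-test on replicate-level values (the "Student" form is used
deliberately, not Welch), marked `**` for p < 0.01 and `*` for p < 0.05.
Per-substrate ER summaries use the arithmetic mean and the *sample* SD
(n−1); with one experiment the SD is absent rather than zero. Degenerate
zero-variance groups return p = 1 when means agree and p = 0 otherwise.

The efflux decision rule (`classify_transporter`) calls a transporter
functional when mean ER > 1 **and** at least half the experiments show
significantly higher B→A than A→B permeability; both thresholds sit in
`EffluxPolicy`. The rule is intentionally conservative: a large mean ER
driven by one noisy experiment does not pass. For the Glut1 scorecard item
— an influx carrier, where directional transport may show as ER < 1 — the
same rule is additionally applied to the direction-mirrored data, so
reproducible asymmetry in either direction counts.

The facility-agreement rule is: mean ± SD intervals overlap, and, when both
facilities provide per-experiment data, equal classifications. It is a
deliberate, printed convention (the underlying question — "are two
summaries of 3–4 experiments compatible?" — has no canonical test at these
sample sizes), and summary-only results fall back to the interval rule.

## RMT analysis

`saturation_check` compares least-squares slopes of the dose–response
below and at/above a breakpoint (default 2400 pmol, where uptake flattens
in this assay format) and calls the curve saturable when the relative
slope drop exceeds 0.2 — a surfaced default chosen because receptor-scale
capacity produces drops far above it while linear leak produces ~0; no
binding model is fitted and no Kd estimated. `competition_test` requires
*both* a with-competitor/without ratio < 1 and a significant t-test at the
configured alpha, so increased-or-equal transport can never be called
receptor-consistent regardless of p-value.

## The simulator

`simulate_assay` integrates mass-conserving exchange
`dA_r/dt = PS_fwd C_d − PS_bwd C_r`. An apically polarized efflux pump is a
lumped directional PS increment (± `ps_active`), the minimum mechanism that
produces ER > 1 under this estimator; optionally it saturates with the
instantaneous donor concentration as `ps_active·km/(km + C_d)`. Cell
inserts combine the cell layer and membrane in series per flux direction;
blank inserts use `ps_membrane_blank` alone. Linear kinetics are solved in
closed form (single-exponential relaxation), the saturable case with LSODA
at rtol 1e-9; mass conservation holds to < 10⁻⁶ relative either way.
Noise is multiplicative lognormal with unit mean and configured CV,
applied independently to every sampled concentration (concentrations are
positive and plate-reader error is proportional); all randomness flows
from one seed, and `save_simulation` embeds config + seed in a JSON
sidecar next to every written dataset.

Defaults are the study conditions the package is built around: sample
times 15/30/45/60 min; 24-well hanging-insert geometry (0.33 cm², 400 μL
luminal / 600 μL abluminal — typical working volumes, configurable, not
asserted for any vendor); 4 replicates per insert and condition; noise CV
0.1 (a typical fluorescence-quantification CV); blank 10× the passive PS.
The competition simulator transports `capacity·L/(Kd + L + U) + leak·L`
with capacity 10 a.u., Kd 200 pmol (equal to the standard 200-pmol labeled
dose, so the equimolar competitor reduces the receptor component by
exactly (Kd+L)/(Kd+2L) = 2/3), and a small passive leak (0.002 a.u./pmol)
— a receptor-dominated positive control; the wet protocol's 15-min
competitor preincubation is represented by the competitor simply entering
the occupancy denominator from t = 0.

What the simulator does *not* emulate: inter-replicate biological
variability (monolayer patchiness, edge effects), receiver-medium
sampling/refresh, solute adsorption or recovery losses, and temperature or
pH drift. Passing recovery tests therefore demonstrate correctness of the
estimator under its stated assumptions, not robustness to every failure
mode of real inserts.

## Validation problem sizes

The noisy parameter-recovery study runs 100 seeded studies of 4
independent experiments × 4 replicates × both directions × both insert
conditions (the reference design: substrate summaries are means over four
independent experiments), and reports the median absolute error of the
study-level mean ER (measured ≈ 4–5 % at CV 0.1; per-experiment ER error
is ~10 %, since the measured-donor clearance ratio carries noise from both
compartments). Competition-verdict accuracy is measured over 100 seeds per
mode (≥ 95 % in both). These sizes keep the whole suite in single-digit
seconds while leaving Monte-Carlo margins well clear of the thresholds.

## Known limitations

- Pe values estimated outside the sink envelope carry the documented
  upward bias; the package reports fit diagnostics (r², intercept) but
  does not extrapolate a nonlinear estimator — by design, the slope method
  is the method.
- Benchmark expression/localization items are declared evidence with
  provenance text, not computed from images or blots.
- No TEER pass threshold is applied and no cross-item score is produced;
  the scorecard reports items independently.
- The bundled reference dataset stores per-experiment Pe pairs and
  significance marks; the replicate-level values behind those marks are
  not available, so fixture checks compare ER values and classifications,
  and marks are only *generated* (and checked) on simulated data.
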