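# Methods

## The energy model

The package treats a pen of finishing steers as an energy balance over the
feeding period. Daily maintenance energy (Mcal/d) is

    EM = 0.077 · W^0.75

and daily retained energy in gain is

    EG = ADG^1.097 · 0.0493 · W^0.75

with W the *median feeding shrunk BW*, defined as the mean of the 4%-shrunk
initial BW and the carcass-adjusted final BW (HCW ÷ common dressed yield).
The coefficient 0.0493 is implemented exactly as used by the trial this
package reproduces; published variants of the retained-energy equation
differ in the constant, and swapping one in would change the solved NE
values.

Dry-matter intake allocates between maintenance and gain at the diet's two
energy densities:

    DMI = EM/NE_m + EG/NE_g,   NE_g = 0.877·NE_m − 0.41.

Substituting the linear NE_g relation yields a quadratic in NE_m with
coefficients a = −0.41·EM, b = 0.877·EM + 0.41·DMI + EG, c = −0.877·DMI.
Two notes on this solve:

* **Root selection.** The root (−b − √(b²−4ac))/(2c) is taken. On the
  physical branch NE_m > 0.41/0.877 (where NE_g > 0) the intake function
  EM/x + EG/(0.877x−0.41) falls monotonically from +∞ to 0, so exactly one
  root lies on that branch; the chosen expression is that root, verified
  against the worked control example (NE_m = 2.113 → 2.11). For EG ≥ 0 the
  discriminant is non-negative by AM–GM (b² ≥ 1.438·EM·DMI = 4ac), so the
  only infeasibility mode is the root collapsing onto the NE_g = 0 floor,
  which happens in the degenerate zero-gain case; it raises
  `InfeasiblePerformanceError` with a diagnostic.
* **A simplified prose statement** of the intake relation
  (DMI = EG/(0.877·NE_m − 0.41)) circulates that omits the maintenance
  term. The quadratic coefficients encode the full two-term identity, and
  only the full identity reproduces the reported NE values; the
  implementation follows the coefficients.

`predict_adg` is the exact algebraic inverse (intake above maintenance
retains energy at density NE_g; the EG equation is inverted for ADG) and
exists so the synthetic generator is the forward model of the analysis;
the round-trip is tested to 1e-9.

### Replacement technique

Ingredient NE = (test diet NE − control diet NE)/inclusion + NE of the
displaced corn. The displaced DRC:HMC blend is valued at 2.24 Mcal NE_m/kg
and 1.52 Mcal NE_g/kg. The source report states these two numbers in the
opposite order in one place; only the 2.24-maintenance / 1.52-gain reading
is consistent with its own results, and that reading is used. At treatment
level the calculation defaults to the 2-dp-rounded treatment-mean diet NE
values (`printed_precision=True`), because that is how the reported
ingredient values (2.14/1.42 and 2.09/1.37) were evidently produced;
full-precision mode is a flag away.

## Performance assembly

* Initial BW carries a fixed 4% pencil shrink (configurable) for gut fill.
* Carcass-adjusted final BW is HCW ÷ common dressed yield with **no
  further shrink**; the common yield (0.6433 in the reference trial) is
  either supplied or computed as the simple mean of per-steer
  HCW/(0.96 · final live BW) over all finishers.
* Pen aggregates are means over finishers only (deads- and
  removals-excluded basis).
* **Intake accounting.** Hospital-pen deliveries are credited to the home
  pen when the steer returned and excluded entirely when it did not — the
  retroactive "debit back to the hospitalization date". Head-days for a
  steer that died or was removed run through its disposition day (the day
  it left the home pen); the source report does not state its head-day
  convention, so this is a documented assumption, chosen because it makes
  the crediting rule and the denominator consistent.
* Two weigh groups started a day apart and were fed 146 vs 145 days;
  days-on-feed is per pen and treatment means may be fractional (145.5).

## Carcass equations

The yield-grade, retail-yield and EBF regressions are not printed in the
trial report; they are pinned constant sets (swappable via config):

* **Calculated YG** = 2.50 + 2.5·RF(in) + 0.2·KPH(%) + 0.0038·HCW(lb)
  − 0.32·REA(in²), conversions 2.54 cm/in, 2.20462 lb/kg, 6.4516 cm²/in².
  Validated by exact reproduction of the control value 2.78.
* **Retail yield** = 51.34 − 5.784·RF(in) − 0.462·KPH + 0.740·REA(in²)
  − 0.0093·HCW(lb). At the control trait means this gives 50.22 vs the
  reported pen-mean 50.97; the plant may have used a variant constant set,
  which cannot be determined from the report. Tests treat this as a
  near-agreement property with a ±1.0 point tolerance.
* **EBF%** = 17.76207 + 4.68142·RF(cm) + 0.01945·HCW(kg) + 0.81855·QG
  − 0.06754·REA(cm²), with QG a numeric quality-grade code. The report
  gives no coding; the default table (Select=4, Low Choice=5, Average
  Choice=6, High Choice=7, Prime=8) is flagged in config. At the control
  means with the code implied by the reported grade distribution this
  lands within 0.6 points of the reported 30.16 — per-steer computation
  before averaging, plus the unknown coding, explains the residual.
* **AFBW** = carcass-adjusted final shrunk BW − 14.26·(EBF − 28); a
  carcass at exactly 28% EBF keeps its final BW. Reproduces the control
  609 kg; the reported values for the other two treatments are not
  mutually consistent with any single adjustment applied at treatment
  means, consistent with per-steer averaging.
* Marbling bands: Select < 400 ≤ Low Choice < 500 ≤ Average Choice < 600
  ≤ High Choice < 700 ≤ Prime (400 = Small00). Yield-grade classes are the
  floor of calculated YG bounded to 1–5.
* Dressing % treats final BW as the 4%-shrunk live weight, which unifies
  the two statements of the formula in the source report.

## Diet accounting

Composition operators are linear on the inclusion simplex. Cumulative
diets default to feed-DM weighting across periods (NE exposure is
intake-weighted); day weighting is available for sensitivity and is what
the bundled reference formulations use (101 and 44.5 days).

The ingredient tabular-NE table mixes sourced and calibrated entries:
dry-rolled corn and both coproducts at 2.20/1.50 (the coproducts are
deliberately booked at corn values, which is what makes the
observed:expected ratio informative), the liquid supplement at its label
values (1.06/0.73). High-moisture corn (2.3155/1.5577) is solved from the
stated displaced-corn blend value (2.24/1.52) and the cumulative DRC:HMC
split; the meal supplements and grass hay are solved so each cumulative
diet reproduces the reported diet-level tabular NE (2.09/1.40, 2.09/1.40,
2.08/1.40). These entries are labeled *calibrated* in the source: they are
consistent values, not assayed facts. Likewise the non-test-ingredient
nutrient profiles are assembled defaults; reconstruction of the reported
diet NDF/ADF agrees to within ~1 percentage point and the residual is
documented rather than forced to zero.

## RCBD statistics

The continuous model is value ~ treatment + block (no interaction) by
OLS, with the type-II F-test for treatment; pen is the experimental unit.
Block is fixed by default (matching the stated model); a REML
random-block option exists because the trial's abstract describes block as
random — in the balanced complete-block case the treatment F-test is the
same, which the tests assert, and reports state which mode was used. SEM
is √(MSE/b), the residual-only convention that matches the reported SEMs
(treatment means in a weight-blocked design would otherwise carry the
huge block variance). With zero residual variance P is defined as 1 when
treatment means coincide, 0 otherwise.

Grade distributions are pen-level binomial counts, fit with a logit-link
GLM (treatment + block) and a likelihood-ratio treatment test; treatment
LS means are the block-averaged linear predictors, back-transformed.
Quasi-separation (a category empty in some cell) is flagged on the result;
a category empty everywhere returns boundary means and P = 1.

Letter displays use unadjusted pairwise t-tests at α = 0.10 (the trial's
superscript convention; it states no multiplicity adjustment) and a
standard insert-and-absorb compact letter display, letters assigned from
the highest mean down. Significance classes: P ≤ 0.05 significant,
0.05 < P ≤ 0.10 tendency.

## Synthetic-study generator

The generator's defaults are the study conditions: 10 weight blocks × 3
treatments × 8 steers, 146/145 days by weigh group, initial BW
401 ± 43.2 kg, dressed yield 0.6433, true diet NE_m and DMI at the
reported treatment means (2.11/2.09/2.08 Mcal/kg; 10.69/10.76/10.67
kg/d), removal probability 4/240.

Pen ADG is generated through the energy model itself: the median-W/ADG
circularity is resolved by fixed-point iteration from W₀ = initial shrunk
BW (tolerance 1e-8, convergence enforced), then a pen-level residual is
added. Dispersion defaults (DMI block SD 0.30 kg/d, pen CV 2%, ADG
residual SD 0.09 kg/d, steer gain SD 20 kg, dressed-yield SD 0.012) were
chosen once so pen-level SEMs land near the reported ones — e.g. the
ADG-residual SD maps through the solve's local sensitivity (≈0.7 Mcal/kg
per kg/d) to an NE_m pen SD near the reported 0.066. Because ADG responds
to the *realized* DMI through the model, DMI noise does not bias solved
NE_m; only the additive noise terms propagate, and the recovery tests
measure the resulting bias (< 0.01 Mcal/kg over hundreds of studies).

Carcass traits are conditionally Gaussian given final BW with pinned
coefficients; quality classes are drawn from configured probabilities with
marbling uniform inside the class band. Hospital episodes exercise both
branches of the crediting rule and are constructed so intake accounting is
exact. What the generator does **not** emulate: within-period intake
dynamics, seasonal effects, disease beyond a removal coin-flip, or any
trait correlation structure beyond linear-in-BW — so passing recovery
tests demonstrate correctness of the estimator under the model's own
assumptions, not robustness to real-world model misspecification.

## Numerical choices and problem sizes

* Display rounding is round-half-even at the shortest decimal
  representation (`Decimal(repr(x))`), at the reporting precisions (BW
  integer, ADG/NE 2 dp, G:F 3 dp, percentages 2 dp); CSV outputs keep full
  precision.
* The quadratic round-trip is asserted to 1e-9 relative; zero-noise
  generator recovery to 1e-6.
* Simulation-based tests use 200 studies for parameter recovery and 2,000
  replicates for null calibration of the F-test (three-sigma binomial
  envelopes), sizes chosen to make the Monte Carlo error comfortably
  smaller than the tolerances being checked.

## Known limitations

* The retained-energy and maintenance equations are for the
  medium-frame-steer case used by the trial; no frame/sex adjustments or
  full nutrient-requirement-model equivalents (equivalent shrunk BW, diet
  NE from chemical composition) are implemented.
* Retail-yield and EBF constant sets reproduce the reported values only
  approximately (see above); alternates can be pinned via config but none
  printed in the report can resolve the ambiguity.
* The binomial analysis uses pen-level counts with a chi-square LR test;
  small-sample denominator-degree-of-freedom emulation of specific
  commercial software is out of scope.
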