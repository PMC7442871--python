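# Methods

## Model overview

`rpe65cea` is an individual-patient-sampling (microsimulation) cost-utility
model comparing one-time bilateral gene-augmentation therapy with voretigene
neparvovec (VN) against standard of care (SoC — annual checks plus supportive
care) in biallelic RPE65-mediated inherited retinal degeneration (IRD).

Each simulated patient is tracked through annual cycles over a lifetime
horizon inside a two-state Markov frame: the only stochastic transition is
alive → dead, drawn each cycle from an age- and sex-specific period life
table. Among survivors the model tracks two continuous visual-function
endpoints:

* **BCVA** — best-corrected visual acuity in logMAR (higher is worse;
  decimal acuity = 10^(−logMAR));
* **VF** — kinetic visual field as Goldmann III4e sum total degrees
  (higher is better).

Per cycle, the order of operations is: death draw (a patient dying in a
cycle accrues nothing in it), state update, accrual of discounted utility
and discounted costs, age increment. The horizon is min(death, age 100);
the life table's terminal age is absorbing.

## Cohort

Cohorts of 70 patients (35 per arm, arms assigned by random permutation)
mirror the pivotal-trial population: age ~ Normal(15.1, 10.9²) truncated by
rejection to [4, 44] years; 58% female; arm-specific baseline distributions
BCVA ~ N(1.137, 0.369²) / VF ~ N(332.9, 413.3²) for VN and
N(0.987, 0.306²) / N(427.1, 372.0²) for SoC, clamped to
[−0.3, 2.3] logMAR and [0, ∞) degrees. Clamping (rather than rejection) is
deliberate for VF: with an SD larger than the mean, rejection at zero would
badly distort the arm means. Each patient carries an individual
progression-onset age uniform on [15, 20] years; a patient older than their
onset age declines from the first natural-history cycle.

## Natural history and treatment effect

Natural history is piecewise linear: BCVA is constant before the onset age,
then worsens by 0.0436 logMAR/year up to a cap of 2.3; VF declines by
25 deg/year (sensitivity: 24.3) to a floor of zero.

Both arms receive an arm-specific first-cycle change drawn per patient from
the trial's change-from-baseline distributions (VN: −0.163 ± 0.336 logMAR,
+302.1 ± 289.6 deg; SoC: −0.312 ± 0.097 logMAR, −76.7 ± 258.7 deg). The
printed SoC acuity change is an *improvement* larger than the VN arm's; the
model applies it as printed and makes no silent correction. From cycle 2 the
SoC arm progresses naturally (no double-counting of the year-1 change).

Two effect-duration scenarios govern the treated arm after cycle 1:

* **lifetime** (base case): the post-treatment state is maintained for life
  — no further progression in the treated arm;
* **waning**: the treated state is held for a 10-year plateau, then the
  residual effect fraction decays exponentially over a further 10 years,
  r(t) = exp(−k·(t − 10)) with k = −ln(0.05)/10 (so 5% remains at year 20),
  snapping to 0 afterwards. The patient's state is the convex blend
  shadow + r·(frozen − shadow), where the *shadow* is the patient's own
  counterfactual SoC trajectory (its own baseline, given the SoC first-cycle
  draw, then natural steps). The decay constant is a modelling choice: the
  shape (exponential) and duration (10 y) are published, the rate is not;
  the 5% residual floor is configurable.

## Utility

Utility is linear in two normalised scores,

    u = u_min + (u_max − u_min) · (w_va·s_va + (1 − w_va)·s_vf),
    s_va = clamp((2.3 − bcva)/2.3, 0, 1),   s_vf = clamp(vf/1000, 0, 1),

with default anchors u_min = 0.40 (blind), u_max = 0.85 (normal acuity,
full field) and w_va = 0.5. No published coefficients exist for this
mapping, which is the model's single largest data gap; it is therefore
quarantined in configuration and handled by **calibration**: one scalar —
the field weight w_vf by default, the spread u_max − u_min as a fallback —
is tuned by bisection until the base case reproduces a known incremental-
QALY anchor (default 4.82) within 1%.

Because utility parameters affect no random draw and no state transition,
the calibration evaluates candidates on a per-replicate decomposition
(QALY = u_min·DL + spread·(w_va·SVA + w_vf·SVF), with DL/SVA/SVF the
discounted alive-time and score sums stored on every replicate) computed
from a single base-case run. This is exactly equivalent to re-running the
Monte Carlo with common random numbers at every candidate, and a test
asserts that equivalence.

## Costs

Direct costs (EUR, German payer): VN year 1 accrues the bilateral bundle
2·(410,550 + 2,000 + 2,840) + 4·220 = 831,660; every other arm-year (and
every SoC year) accrues one annual check of €220. The ongoing €220 equals
one quarterly outpatient fee — the published year-n figure — read as one
reimbursed visit per year.

Indirect costs (societal perspective) attach to decimal-acuity bands:
A (< 0.02), B ([0.02, 0.05)), C ([0.05, 0.3)); decimal ≥ 0.3 accrues
nothing, as no band above 0.3 is published. Band values are per 6 months,
so the annual accrual is twice the band sum of medical, non-medical, and
general components: €39,864 (A), €22,432 (B), €13,336 (C). The default
mode uses these means deterministically. A sampled mode (off by default)
draws each component from a zero-clipped normal; it is off because the
published SDs (up to €115,022 on a mean of €10,868) make any zero-bounded
sampling scheme inflate the expectation substantially.

Costs and QALYs accrue at end of cycle with no half-cycle correction
(annual cycles are the published resolution); both are discounted at 3%
per year, year 1 undiscounted.

## Mortality

Mortality is general-population only — no excess mortality from visual
impairment in either arm. The packaged default is a deterministic
Gompertz–Makeham table, q(x) = 1 − exp(−(A + B·e^{Cx})) with A = 2.2·10⁻⁴,
B = 2.7·10⁻⁵, C = 0.098 (female) and the female hazard scaled by 1.6 for
males (a typical modern male/female hazard ratio). This yields life
expectancies at birth of 77.6 (f) / 72.5 (m) years — a plausible modern
European schedule. Any real national period life table drops in via a CSV
(`age,qx_female,qx_male`, consecutive integer ages from 0); results are
only weakly sensitive to the vintage because most incremental QALYs and
costs accrue before age 60 under 3% discounting.

## Monte Carlo design and randomness

A run is 1000 replicates × 70 patients. Every replicate resamples
everything at patient level (baselines, first-cycle effects, mortality);
band-level indirect-cost means stay fixed in the base case. Randomness is
structured as one master seed → per-replicate child seed sequences → four
substreams per replicate (cohort, effects, mortality, indirect-cost
sampling), so toggling one randomness source leaves the others unchanged.
VN patients always consume four effect draws (own deltas plus shadow SoC
deltas) even when the shadow is unused, keeping streams aligned across
effect-duration scenarios. Sensitivity scenarios reuse the base run's
master seed (common random numbers), so scenario deltas isolate the
parameter changes.

## Aggregation and outputs

Per replicate: arm means of discounted QALYs and costs, ΔQALY and ΔCost
(VN − SoC), and the replicate ICUR. The headline ICUR is the ratio of
ensemble means (mean ΔCost / mean ΔQALY); the mean of per-replicate ratios
is reported alongside because the two differ on skewed ensembles. The CEAC
uses net monetary benefit (λ·ΔQALY − ΔCost ≥ 0), which is monotone in λ and
well-defined in all quadrants; the literal "replicate ICUR below λ" rule is
available as an option and coincides with NMB in the north-east quadrant
where nearly all base-case replicates fall.

The sensitivity suite comprises the base case plus: 10-year effect with
waning; 0% discounting of costs and QALYs; direct costs ×1.1 and ×0.9; and
VF slope −24.3 deg/year.

## Numerical and degenerate-input choices

* Band intervals are half-open, lower-closed on the decimal scale; the hot
  loop compares on the logMAR scale against precomputed −log10 thresholds
  (equivalent by monotonicity).
* Mortality lookups use floor(age); ages above the terminal age return
  q = 1; the table constructor forces the terminal q to 1.
* Truncated-normal age sampling uses rejection; a zero-SD spec degenerates
  to the mean (error if outside the range).
* A patient starting at the terminal age lives exactly zero accrual cycles.
* ICUR is flagged undefined (NaN) when ΔQALY is exactly 0 rather than
  dividing.
* The engine's totals-only fast path and the record-producing
  `simulate_patient` share one cycle routine; tests pin their agreement to
  1e−12 and pin both against an independently written straight-line
  reference to 1e−9.

## What the synthetic data does and does not emulate

The cohort generator reproduces the *marginal* baseline distributions and
arm balance of the pivotal trial; it does not model genotype
heterogeneity, per-eye asymmetry, correlation between baseline BCVA and VF,
or enrollment processes. The synthetic life table reproduces the level and
age-shape of modern German mortality but not cohort effects or mortality
improvement. Passing tests therefore demonstrate internal correctness of
the model mechanics and reproduction of the published aggregate economics
under these stylised conditions — not patient-level predictive validity.

## Known limitations

* The utility mapping is calibrated, not estimated from preference data;
  only one scalar is identified by the single QALY anchor, so the
  calibrated weights are not unique.
* Functional-vision endpoints (multi-luminance mobility, full-field light
  sensitivity) are not modelled — no long-term data or quality-of-life link
  exists — so treated-arm benefits are likely conservative.
* The printed SoC first-cycle acuity *improvement* (−0.312 logMAR) exceeds
  the VN arm's; it is applied as printed.
* Adverse-event discontinuation defaults to 0 (a configuration hook
  exists); no rate is published.
* Indirect-cost bands are defined on acuity only; field loss affects costs
  only through utility, not through the band assignment.
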