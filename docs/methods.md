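# Methods

## Estimation chain

The pipeline estimates, year by year over 1960–2008, the physical-activity
energy expenditure attributable to the mix of occupations in the U.S.
workforce, and then asks how much of the observed rise in mean body weight
a sustained expenditure decline of that size would produce.

1. **Sector prevalence.** Employment counts (thousands of persons) for 11
   broad sectors — farm jobs, three goods-producing sectors, seven
   service-providing sectors — are pooled (private nonagricultural plus
   agricultural employment) and converted to shares `pₛ(t)` summing to 1.
   Cells absent from an input file are zero employment with a logged
   warning, since agricultural detail is sparse in early years; a year with
   no positive employment is an error. The analysis works in prevalences,
   not absolute job counts, so the overall growth of the labor force
   cancels.
2. **Intensity assignment.** Each sector carries a median, minimum and
   maximum MET from a published occupational classification; categories are
   assigned from the median alone with half-open cuts: [0,2) sedentary,
   [2,3) light, [3,6) moderate. The cuts are half-open so 2.9999 is light
   and 3.0 moderate, making classification total on (0,6); medians at or
   above 6 are rejected rather than silently bucketed, since the scheme has
   no vigorous category (table maxima reach 8.0 but categories never use
   them). All goods-producing sectors and farm jobs are moderate; services
   are sedentary or light.
3. **Mean METs and daily expenditure.** `MET̄(t) = Σₛ pₛ(t)·med_METₛ`; daily
   occupational expenditure is `EE = h·MET̄·W_ref` with h = 8 h/workday and
   reference weights fixed at the 1960–62 survey means (76.9 kg men,
   64.9 kg women) for every year. Holding the weight fixed isolates the
   occupational-mix shift; weight feedback lives only in the energy-balance
   model.
4. **Trend tests.** Secular-trend reports in this literature usually state
   a "p for trend" without committing to a test; this package uses OLS of
   the yearly statistic on calendar year with a two-sided t test on the
   slope — the simplest defensible choice — and labels the method in its
   report so a rank-based test could be slotted in. Exact fits are resolved in the limit: zero residual
   variance gives p = 1 for a zero slope and p = 0 otherwise.
5. **Energy balance.** The per-gender steady-state sensitivities adopted
   here — 0.090 kg (men) and 0.092 kg (women) of weight gain per kcal/day
   of sustained expenditure reduction — come from a validated
   energy-balance model in the literature. This package implements the
   minimal model consistent with those constants and with a first-law,
   weight-dependent-expenditure derivation: a single linear compartment

       dW/dt = (−ΔEE − γ(W − W₀)) / ρ

   with weight-dependent expenditure slope γ (kcal·kg⁻¹·day⁻¹) and tissue
   energy density ρ = 7700 kcal/kg. The steady state W* = W₀ − ΔEE/γ is
   independent of ρ, which sets only the relaxation timescale ρ/γ (about
   1.9 years here; simulated runs settle in 17–19 years at the 10⁻⁶ kg/day
   stopping rule). γ is the reciprocal of the published steady-state
   sensitivity (0.090 kg per kcal/day men, 0.092 women), and the
   calibration procedure — simulate 50/100/150 kcal/day reductions to
   steady state, average the three weight-change ratios — reproduces those
   constants by construction *and* by simulation; in a linear model the
   three ratios coincide, so the averaging is a consistency check rather
   than an estimator.
6. **Trajectory and anchors.** Period expenditure is the mean of yearly EE
   over each NHANES examination period's calendar years — there is no
   canonical mapping of multi-year survey periods onto yearly employment
   data, and the mean is the natural choice.
   Deltas relative to the 1960–62 baseline are scaled by 5/7 when the
   workweek flag is on — a 5-day week averaged over calendar days — and fed
   through W*. The headline worked example (142 kcal/day → 89.7 kg) is only
   reproducible *without* the workweek factor, while the trajectory figures
   assume it; both behaviours sit behind an explicit `apply_workweek` flag
   and the report records which was used. The predicted-versus-observed gap
   is printed without any closeness claim or inference; only three observed
   cells (1960–62 both genders, 2003–06 men) are published anchors, and all
   other fixture cells are absent and flagged unreported.

## Numerical choices

- The ODE is integrated with adaptive RK45 on the deviation from baseline,
  so absolute solver tolerance (atol ≤ 10⁻¹²) rather than relative
  tolerance on a ~100 kg state controls the small terminal rates the
  stopping rule watches. Termination is |dW/dt| < tolerance (default
  10⁻⁶ kg/day, horizon 30 years), which brackets the terminal weight within
  tolerance·ρ/γ of the analytic steady state; the event fires marginally
  (0.1%) inside the band so the bracket is strict. Exceeding the horizon is
  reported as non-convergence, not raised.
- Steady-state predictions use the closed form; simulation and closed form
  are held together by a property test against the exponential solution.
- Display rounding: kg to 1 decimal, kcal to 0 decimals, sensitivities to 3
  decimals; machine-readable outputs keep full precision, and CSV writers
  use `repr` floats so write→load round-trips are bit-exact.

## Synthetic employment generator

The generator stands in for five decades of employment extracts that
cannot be shipped. Each year's prevalence vector linearly interpolates
between a 1960 and a 2008 anchor vector and is renormalized to the simplex,
optionally after mean-one multiplicative log-normal noise per
(year, sector) — multiplicative so counts stay positive, log-normal so the
simplex renormalization is well behaved. Totals interpolate linearly from
54.0M to 137.0M; the absolute scale cancels in every prevalence-based
statistic. The anchors pin every published share — moderate-intensity mass
0.48→0.20, manufacturing 0.30→0.12, professional/business +
education/health + leisure/hospitality 0.20→0.43 — and the unpinned sectors
take round constants chosen to match the qualitative published trends
(construction roughly flat at 0.08→0.06, information declining 0.035→0.025,
farm declining 0.08→0.015). Linear interpolation is used because no
functional form is claimed for the drift.

What this emulates — and does not. The generator reproduces the endpoint
composition and a monotone drift; it has no business cycles, no survey
noise structure, no within-sector technological change, and its yearly
path between the anchors is a modelling convenience. Consequently the
pipeline's endpoint quantities (category shares, 1960→2008 expenditure
decline) are meaningful reconstructions, while its year-by-year curves are
approximate by design. On the noiseless series the expenditure decline is
166 kcal/workday (men) and 140 (women) — consistent with the published
"more than 100 kcal" bound and close to, but not equal to, the published
140/124 kcal figures, which depend on the unpublished yearly extracts.
Passing tests therefore demonstrate correctness of the estimation chain
and agreement at the anchored endpoints, not recovery of the original
yearly series.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| hours_per_workday | 8 | h | expenditure formula |
| reference_weight_kg | 76.9 / 64.9 | kg | fixed 1960–62 means, men/women |
| workweek_factor | 5/7 | — | workday→calendar-day delta scaling |
| γ | 1/0.090, 1/0.092 | kcal·kg⁻¹·d⁻¹ | steady-state sensitivity, men/women |
| ρ | 7700 | kcal·kg⁻¹ | tissue energy density; timescale only |
| tolerance | 10⁻⁶ | kg/day | steady-state stopping rule |
| noise_sd | 0 | relative | generator perturbation |

## Known limitations

- Sector-level medians ignore within-sector heterogeneity and five decades
  of mechanization; the intensity assignment is deliberately conservative.
- The linear energy-balance model has a constant sensitivity; richer
  two-compartment formulations with mildly weight-dependent sensitivity
  would bend the trajectory slightly. The model form and constants are
  surfaced in configuration so such a variant can be substituted.
- No intake-side modelling, no survey weighting, no inference on the
  predicted-versus-observed gap.
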