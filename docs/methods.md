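# Methods

## Model structure and assumptions

The analysis is a three-state partitioned-survival model (PSM): progression-
free (PFS), progressed disease (PD), and death. State occupancy is read
directly off the two survival curves rather than from transition
probabilities, so PFS and OS are treated marginally — no individual-level
correlation between progression and death is modelled, and a fitted PFS
curve that crosses above OS (possible with independently fitted parametric
curves) is clipped so PD occupancy stays non-negative (clip events are
counted on the trace).

Settings and their defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| cycle length | 21 | days | one chemotherapy cycle |
| horizon | 10 | years | effectively lifetime for ES-SCLC |
| discount rate | 5 | %/year | Chinese pharmacoeconomic guideline |
| half-cycle correction | off | — | cycle-start evaluation; switchable |
| WTP threshold | 287,391 | CNY/QALY | 3 × 2024 per-capita GDP (95,797) |

Time is in months with 1 month = 30.4375 days; a 10-year horizon gives
floor(3652.5/21) = 173 steps plus cycle 0, i.e. 174 rows. Discounting is
anchored in continuous time, d(t) = 1.05^(−t/12) at cycle start, with cycle 0
a full cycle at discount 1. The source analysis also once states a WTP of
¥268,074; the 3×GDP arithmetic (287,391) is used throughout.

## Survival extrapolation

Families and parameterisations (all parameters positive except the lognormal
location; the Gompertz shape is constrained positive so S → 0):

exponential S = e^(−λt); Weibull S = exp(−(t/b)^a); Gompertz
S = exp(−(b/a)(e^(at) − 1)); log-logistic S = 1/(1 + (t/b)^a); lognormal
S = 1 − Φ((ln t − μ)/σ). Under the log-logistic convention the median equals
the scale; the shipped scale of the treatment-arm OS curve (13.97 months)
sits next to the trial's reported median OS (13.90 months), which is also
the evidence that the table of fitted parameters is in months — the time
unit is not stated alongside them.

Fitting maximises the right-censored log-likelihood with L-BFGS-B on
log-transformed parameters and three seeded starts (a moments-based start
plus Gaussian perturbations, SD 0.3 on the log scale) to guard against local
optima. Observed zero times are floored at 1e−6 months before likelihood
evaluation (the log-time families are undefined at 0). Model selection is
minimum AIC, ties broken by minimum BIC, then by family order. The
evaluation of S, f and quantiles is delegated to the corresponding
scipy.stats distributions (fisk, weibull_min, gompertz, expon, lognorm);
lifelines fitters serve as an independent cross-check in the test suite,
never as the implementation.

## Kaplan–Meier reconstruction

`reconstruct_ipd` inverts the product-limit estimator over the digitised
points: at each drop, the event count is the rounded solution of
d = n·(1 − s/S_prev). With a numbers-at-risk table, censoring inside each
risk interval is placed uniformly and iterated until the end-of-interval
at-risk count matches the table (the standard reconstruction approach for
published curves). Without a risk table — the shipped analysis has none —
censoring is assumed to occur only after the last digitised point. That
assumption reads the curve tail as event-driven, which biases late-time
extrapolation pessimistically if real censoring was interleaved; it is the
documented default, not a claim about the trial. Digitiser jitter that makes
the curve rise by ≤ 0.005 is snapped flat; larger rises are rejected as
corrupt input. The arm sample size is a required input; it cannot be
recovered from the curve.

## Costing conventions

* Doses: socazolimab 5 mg/kg (295 mg at 59 kg), etoposide 100 mg/m² × 3 days
  (516 mg at 1.72 m²), carboplatin AUC 5 via the Calvert formula
  (5 × (90 + 25) = 575 mg at CCR 90). Per-mg prices, no vial rounding.
* Chemotherapy drug costs ride on PFS occupancy in cycles 1–4.
* Monitoring (laboratory 166 + radiology 300 per cycle) accrues in every
  alive cycle, both states; best supportive care (3,115/cycle) in PD cycles.
* Adverse events (grade ≥ 3, incidence ≥ 5%): a single up-front cost,
  Σ incidence × unit management cost per arm — incidences are
  whole-treatment probabilities, not per-cycle rates.
* The published control-arm bounds for thrombocytopenia (16.48/24.72 against
  a base of 27.9) duplicate the anemia row and are inconsistent; the shipped
  table repairs them to ±20% of base and flags the row.

**Socazolimab accrual (the central design decision).** Protocol mode charges
295 mg × 115 CNY/mg ≈ 33,925 CNY per PFS cycle up to the 2-year cap, which
accumulates to roughly 360,000 CNY of discounted drug spend — an order of
magnitude more than the published incremental cost can contain. The
published price-simulation table, however, is exactly affine in the retained
price fraction, and its slope (least squares across all rows, 43,232.73 CNY,
consistent pairwise to within ±1) *is* the total discounted socazolimab
expenditure embedded in the published analysis; it corresponds to only ~1.27
dosing cycles. Calibrated mode books that total as a one-off discounted
expenditure and is the default. In sensitivity analyses the calibrated total
is scaled proportionally to (unit price × body weight) relative to its
115 CNY/mg × 59 kg anchor, since it is a price-per-mg times milligram
quantity. The contradiction between the protocol rule and the implied spend
is documented, not resolved.

## What the model does and does not reproduce

Computed by this package under the conventions above (and printed by
`examples/03_base_case.py` and the tests):

| quantity | published | this model |
|---|---|---|
| control cost (CNY) | 67,092.98 | 60,382.31 (−10.0%) |
| treatment cost, calibrated (CNY) | 141,709.54 | 104,996.50 |
| ΔC (CNY) | 74,616.56 | 44,614.20 |
| effect, treatment | 0.87 | QALY 0.810 / LY 1.418 |
| effect, control | 0.66 | QALY 0.694 / LY 1.248 |
| ΔE | 0.21 | QALY 0.116 / LY 0.170 |
| ICER (CNY/QALY) | 355,316.95 | 384,316 |

The convention grid {half-cycle on/off} × {QALY vs life-year accrual}
(`convention_grid`) contains **no cell** matching the published per-arm
effects: the published increment (0.21) is close to the discounted
*life-year* increment, while the published per-arm values match neither the
QALY nor the LY totals under any cell. On the cost side, a broader grid
(discounting on/off/annual-step, cycle-start/end/half evaluation, monitoring
in both states vs PFS only, chemo weighted vs unweighted, three month-length
conventions) has no cell within 5% of the published control total; the
documented convention (monitoring in both states) is the closest discounted
one at −10%. The corresponding comparisons in `tests/test_acceptance.py`
assert the published values at face value and fail; that failure is the
finding, and nothing was re-tuned to mask it.

The arithmetic layer, by contrast, reproduces the publication exactly: the
ICER identity 74,616.56/0.21 = 355,316.95, every price-ladder ICER to within
0.1%, and the ~77 CNY/mg threshold price all follow from the published
decomposition plus the calibrated total.

Consequences for the probabilistic analysis: with this model's smaller ΔE
and higher ICER, the acceptance probability at 3×GDP comes out near 5%
(published: 21.9%) and near 0% at 2×GDP (published: 2.8%), while the CEAC
crossing (~381,000 CNY/QALY) is close to the published ~397,500. The tornado
ranking also differs: here PFS utility, socazolimab price and body weight
dominate (PD utility matters little because the two arms' discounted PD
durations are nearly equal under the fitted curves), whereas the publication
reports PD utility first.

## Sensitivity-analysis machinery

One-way analysis moves each parameter to its published low/high bound
(discount rate 0–8%) with all else at base and reports the ICER span,
sorted descending; zero-width bounds give zero span by construction.

PSA reads every min/max as a 95% interval, SD = (max − min)/3.92, and
moment-matches: Gamma (shape = (m/s)², scale = s²/m) for costs, Beta
(ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν) for incidences and utilities, Normal
for weight and BSA. Support violations raise an error naming the parameter.
The discount rate is held at 5% in PSA (its Beta tag in the source table has
the wrong support for a rate) but varied one-way. Utilities are sampled
independently; in the ~1% of draws where the PD utility exceeds the PFS
utility it is clamped down to preserve the state ordering. Costs and
utilities are shared between arms within a draw; adverse-event incidences
are arm-specific and sampled independently. Draws are generated from a
single seeded generator; the default CEAC grid is 0–600,000 CNY in 2,500
steps, and the crossing is linearly interpolated where the treatment curve
first reaches 0.5 (ties in net monetary benefit go to control, conservative
for the new drug).

## Synthetic data

The simulator draws event times by inverse-CDF from any supported family,
with administrative or random-exponential censoring, and digitises curves by
sampling S(t) on a grid plus truncated-Gaussian jitter (clipped to [0, 1],
then re-monotonised). It emulates what the pipeline consumes — not real
trial data: there is no per-patient PFS/OS correlation, no dropout process,
and digitiser error is idealised as independent jitter. Passing round-trip
tests therefore show the *machinery* is correct (reconstruction inverts
estimation, fitting recovers generating parameters), not that any real
curve was digitised accurately.

## Numerical choices and limitations

Restricted means use adaptive quadrature (`scipy.integrate.quad`, relative
tolerance ~1e−6). Trace occupancies conserve mass to 1e−12 by construction.
The discrete QALY sum differs from the continuous integral by at most one
cycle's contribution and converges as the cycle shrinks (verified against
quadrature). Reconstruction quantises survival in steps of 1/n, so a
noise-free round trip is exact only to 1/(2n). Problem sizes in the tests
(n = 2000 for parameter recovery, 50 replicates for selection sanity,
10,000 PSA draws in the headline run, 50,000 for the mean-convergence
check) were chosen as the smallest that make the statistical assertions
stable across seeds. Known limitations: no EVPI/EVPPI, no subgroup or
budget-impact analysis, no vial-sharing or dose-intensity adjustment, and
the calibrated accrual mode deliberately reproduces a published spending
level rather than deriving it from the protocol.
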