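# Methods

`tkicea` implements a cost-effectiveness comparison of four first-line EGFR
tyrosine-kinase inhibitors (gefitinib, erlotinib, afatinib, osimertinib) in
EGFR-mutated advanced NSCLC, from a Dutch societal perspective. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Evidence synthesis (`netmeta`)

Trial evidence enters as contrasts: a log hazard ratio of arm b vs arm a with
a standard error recovered from the 95% CI as
`se = (ln U − ln L) / (2·1.959964)`. The fixed-effect consistency model

    log_hr(a, b) ~ Normal(d_b − d_a, se²)

is estimated two ways: a closed-form generalized-least-squares solution over
the basic parameters d_t (log-HR of treatment t vs the chemotherapy
reference), and a component-wise random-walk Metropolis sampler with vague
Normal(0, 100²) priors that mimics the Bayesian estimation convention for
such networks and yields credible intervals from draws. GLS is the default
because it is deterministic and exact; the two agree within Monte-Carlo
error by construction and this is asserted in the test suite. League-table
entries are `exp(d_b − d_a)`; under GLS the point estimates are exactly
reciprocal, under MCMC the table reports posterior means of the HR itself,
which are only approximately reciprocal — matching how published league
tables behave.

Design choices:

* A trial reporting one HR against a pooled "standard TKI" comparator can be
  expanded into one contrast per component drug (`duplicate_shared_comparator`).
  The default replicates the SE in both copies, reproducing the common
  assumption that the effect applies to each comparator; an optional policy
  inflates both SEs by √2 because plain duplication double-counts the trial's
  information.
* Within-trial correlation of multi-arm trials is ignored (contrast-level
  data only). This is a known approximation; with one shared-comparator trial
  in the intended network its effect is limited to that trial's weight.
* Connectivity is checked per endpoint; a disconnected network is an error
  naming the isolated component rather than a silently dropped treatment.

## IPD reconstruction (`km_reconstruct`)

Published KM figures provide survival probabilities at read-off times plus
numbers at risk on a coarser grid. Within each risk-table interval the
censoring total is treated as unknown, censorings are assumed uniform over
the sub-intervals, events at each digitized drop follow from the KM ratio
given the running risk set, and the censoring total is solved (Brent root
finding) so the implied risk set at the end of the interval matches the next
reported number. Beyond the last risk-table time only events are allocated
and the residual cohort is censored at the final digitized time.

Fractional implied counts are converted to integers by largest-remainder
allocation within each interval, so `events + censorings = n` holds exactly —
conservation is non-negotiable because the records feed likelihood fitting.
Digitized points between risk-table times are honoured individually (one
event batch per drop) rather than pooled per interval, which keeps the
roundtrip error small: reconstructing a simulated 500-patient cohort from a
4-monthly risk table and refitting recovers the directly fitted Weibull
parameters to within about 2%, and the KM curve of the reconstructed records
matches the input curve to within 0.02 at n = 200.

## Parametric survival (`survfit`)

Time is in months everywhere. Supported laws:

| family | survival function | parameters |
|---|---|---|
| Weibull | `S(t) = exp(−λ·t^γ)` | scale λ (month^−γ), shape γ |
| exponential | `S(t) = exp(−rate·t)` | rate, or AFT intercept with `rate = exp(−intercept)` |
| log-logistic | `S(t) = 1 / (1 + (λt)^γ)` | scale λ, shape γ |

Right-censored maximum likelihood is optimized on (ln λ, ln γ) from several
moment-style starts (deterministic given the data); the exponential MLE is
closed form. The covariance of (ln λ, ln γ) comes from the numerically
differentiated observed information and is retained for probabilistic
sensitivity analysis. Fits are ranked by AIC (BIC reported alongside), ties
broken toward fewer parameters.

Treatment-specific parameters derive from the chemotherapy reference fit by
hazard-ratio scaling: `λ' = λ·HR`, shape kept. For Weibull and exponential
hazards this is exact proportional hazards (`h'(t)/h(t) = HR` for all t);
for the log-logistic family it is not, so scaling a log-logistic reference
is an error rather than an approximation.

The second-line "intercept" parameterization is the AFT convention
`rate = exp(−intercept)` with t in months. This is inferred, not stated, in
the source material; it reproduces plausible second-line medians (e.g.
pemetrexed–cisplatin PFS median `ln 2 · exp(1.885) ≈ 4.6` months), which is
the consistency check we rely on.

## Cohort model (`cohort_model`)

A partitioned-survival model with 30-day cycles. Occupancy is read directly
off the curves at cycle boundaries: progression-free `pf1(k) = S_PFS(t_k)`,
dead `1 − S_OS(t_k)`, progressed the remainder, so rows sum to one by
construction. Cycle k corresponds to `t = k·(30/30.4375)` months; the
30-day-cycle to month conversion matters at the ~1% level and is explicit in
`ModelSettings`.

The progressed compartment is split into second-line progression-free and
second-line progressed. New progressors in cycle j (the drop in `pf1`) are
split by the second-line mix — 50% second-line osimertinib / 50%
pemetrexed–cisplatin after a standard TKI, 100% pemetrexed–cisplatin after
first-line osimertinib — and each entry cohort contributes
`S_2L,PFS(t_k − t_j)` to second-line progression-free occupancy (a discrete
convolution over entry pulses). The split is rescaled wherever it would
exceed the progressed total, because death is governed solely by the
first-line OS curve (a pure partitioned-survival reading); the printed
second-line OS parameters are carried in `ArmConfig` for diagnostics but do
not drive the trace, since giving them a second mortality channel would
double-count deaths.

Horizon: the trace runs until cohort survival falls below 0.001 or 300
cycles (~24.6 years), whichever comes first; hitting the cap with more than
1% alive records a warning in the trace metadata. Under the base-case
parameters all four strategies are extinct between cycles 131 and 200, well
inside the cap, and each arm's trace builds in milliseconds.

Life-years and QALYs integrate occupancy with half-cycle correction
implemented as trapezoid averaging of consecutive cycle-boundary occupancies,
discounted at the mid-cycle time: effects at 1.5% per year, costs at 4% per
year (the Dutch guideline rates). QALYs weight occupancy by state utilities
(0.71 progression-free, 0.67 after first-line progression, 0.62 after
second-line progression). Severe-adverse-event disutilities (grade ≥ 3,
incidence ≥ 1.5%) are one-off QALY decrements lasting one cycle, applied at
each treatment line's entry — the whole cohort at model start, progression
inflows for second line — and discounted at entry time. The packaged
parameter book ships the AE disutility and unit-cost tables but a zero
incidence schema (per-arm incidences are not part of the book), so AE terms
default to zero unless the user supplies trial-extracted incidences.

Trace accuracy: discounted life-years from the trace agree with dense
quadrature of the discounted OS curve to within 0.5% on all four arms
(asserted in tests).

## Costing (`economics`)

Societal perspective, 2018 euros. Occupancy-attached costs per cycle:

* first-line drug acquisition while progression-free (per-cycle prices per
  TKI; pemetrexed–cisplatin additionally carries a per-cycle administration
  fee in second line);
* a monitoring bundle while on first- or second-line treatment — by default
  1 outpatient visit + 1 laboratory panel per cycle, a tumour assessment
  amortized over every 3 cycles, and 1 travel event per visit;
* best supportive care per cycle after second-line progression;
* home-care and informal-care hours per state (default 0 h);
* indirect medical costs: the lifetime average (€10,602) spread per
  life-year lived.

Flow-triggered one-offs: T790M mutation testing at first-line progression
(standard TKIs only — on first-line osimertinib the test has no treatment
consequence), CNS-progression management at first-line progression (€535
osimertinib-class, €1,250 standard-TKI class, scaled by a configurable CNS
event fraction, default 1), end-of-life care at death entry, and a
friction-cost productivity loss (€4,068) as a one-off at model entry. The
"first-line cost" subtotal comprises first-line drug, first-line-attributed
monitoring and the productivity one-off (configurable).

The visit/assessment schedule, care hours, and the allocation rules for
productivity and indirect medical costs were not published; they are a
declared calibration surface exposed in the parameter book
(`resource_schedule`) with the documented defaults above. **Known
limitation:** with these defaults the model reproduces the published
orderings, the dominance pattern and the position of both frontier ICERs
relative to the €80,000/QALY threshold, but not the absolute cost totals —
the incremental cost of osimertinib vs afatinib computes to ≈ €44k against
a published ≈ €63k, because occupancy-based second-line drug costing spends
more in the comparator arms than the published totals imply. Consequently
the osimertinib price reduction required at €80,000/QALY computes to ≈ 13%
(published ≈ 30%), and on the acceptability curve at €80,000 osimertinib,
not afatinib, ranks first. These cost-side quantities should be read as
properties of this model's documented schedule, not as reproductions.

Incremental analysis sorts strategies by effect, removes strictly dominated
strategies (another strategy at least as effective and no more costly, one
strictly), then iteratively removes extended dominance (a strategy whose
frontier ICER exceeds the next one up), leaving ICERs that strictly increase
along the efficient frontier. The price threshold bisects a multiplier on
the drug's acquisition price — applied to both first-line use and second-line
use in the comparator arms — until the strategy's frontier ICER reaches the
willingness-to-pay; it returns 0 when already cost-effective and `None` when
a full waiver would not suffice.

## Uncertainty (`uncertainty`)

**One-way DSA.** Each parameter is set to its published range where one is
printed and brackets the base case, otherwise ±20% of the mean; two printed
ranges (mutation test, tumour assessment) do not bracket their base values
and fall back to ±20%. Bars are ranked by the width of the induced ICER
interval.

**PSA.** 1000 draws by default, seeded. Moment matching: gamma for costs
(shape = (m/se)², scale = se²/m), beta for utilities and for disutility
magnitudes (α = m·c, β = (1−m)·c with c = m(1−m)/se² − 1), normal for
survival parameters; zero SE degenerates to a point mass. SEs default to 20%
of the mean for costs and 10% for utilities/probabilities.

Comparative survival uncertainty is propagated structurally by default
(`survival_mode="hr_scaled"`): per endpoint, the chemotherapy (λ, γ) pair is
drawn jointly (normal, 10% CV, zero correlation — no fitted covariance is
published), each treatment's HR is drawn lognormally from its pooled 95% CI,
and treatment λs follow by the scaling rule with the shared γ. This mirrors
how the deterministic parameters are constructed and keeps the comparisons
coherent: a literal independent perturbation of every arm's (λ, γ)
(available as `survival_mode="independent"`) lets shape uncertainty swamp
the increments — `∂ ln(mean survival)/∂γ ≈ −3.3` at the base-case OS shape —
and would contradict the tight comparative uncertainty the trial network
implies. Draws implying curve inconsistency (PFS above OS on the grid, or
non-positive parameters) are resampled with a capped retry budget and a
logged count; with the base-case parameters the fitted PFS and OS curves
cross just before the first cycle boundary, so roughly 4 in 10 raw draws
are rejected — the PSA distribution is therefore conditioned on curve
consistency.

CE planes report quadrant shares with ties on an axis assigned by the
strictly-positive convention so shares always sum to 1. CEACs are computed
multi-way: at each willingness-to-pay the probability that a strategy
maximizes net monetary benefit `NMB = λ·QALY − cost` across all four
strategies, ties split equally, so the curves sum to 1 at every threshold.

## Synthetic data (`synthetic_data`)

The generators exist so every pipeline stage is testable without any
download. `simulate_ipd` draws event times by inverse CDF from the
configured law with administrative cutoff plus independent exponential
dropout; `km_with_risk_table` produces the published-figure surrogate (exact
product-limit curve at the event times plus numbers at risk, default
4-monthly); `simulate_network` draws trial contrasts around known basic
parameters with `se ≈ 2/√events`. All generators are deterministic under
their seed.

What they do not emulate: digitization error (coordinates are exact, so
reconstruction tests isolate the method's own error), informative censoring,
within-trial correlation in multi-arm designs, and real heterogeneity across
trials (the network generator is consistent by construction, matching the
fixed-effect model). Passing tests therefore demonstrate correctness of the
algorithms under their stated assumptions, not robustness to violations of
those assumptions in real figures and trials.

## Numerical conventions

* Discounting: annual rates, factor `(1+r)^(−t_years)` at mid-cycle time.
* Half-cycle correction: trapezoid of cycle-boundary occupancies (equivalent
  to mid-cycle evaluation to first order).
* Model-size defaults: ≤300 cycles, survival floor 1e−3; base-case traces
  end at 131–200 cycles.
* MLE: Nelder-Mead on log-parameters, four fixed starts, tolerances 1e−10/1e−12;
  ranking ties broken by parameter count.
* Root finding: Brent for censoring totals; bisection (default tol 1e−3 on
  the multiplier) for the price threshold.
* Largest-remainder rounding wherever fractional counts must become integers.
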