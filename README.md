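# tkicea

Cost-effectiveness modelling of first-line EGFR tyrosine-kinase inhibitors
(gefitinib, erlotinib, afatinib, osimertinib) in EGFR-mutated advanced
non-small-cell lung cancer, from a societal perspective.

Head-to-head trials do not exist for every pair of these drugs, and health
technology assessment needs absolute lifetime estimates, not trial-horizon
hazard ratios. `tkicea` provides the full pipeline that bridges that gap,
as a tested, reusable library with a thin CLI:

* **`netmeta`** — fixed-effect network meta-analysis of PFS/OS hazard ratios
  on the log scale (`log_hr(a,b) ~ N(d_b − d_a, se²)`), with a closed-form
  GLS solver and a Metropolis sampler with vague priors, producing full
  league tables of pairwise HRs.
* **`km_reconstruct`** — recreation of individual patient data from digitized
  Kaplan–Meier coordinates and numbers-at-risk tables (censoring solved per
  risk interval so the implied risk sets match; counts conserved exactly).
* **`survfit`** — right-censored MLE for Weibull `S(t)=exp(−λt^γ)`,
  exponential and log-logistic laws, AIC/BIC ranking, and hazard-ratio
  scaling `λ' = λ·HR` (shape kept) to derive each treatment's curve from the
  chemotherapy reference fit.
* **`cohort_model`** — a partitioned-survival cohort trace on 30-day cycles
  (progression-free / progressed, split into second-line progression-free
  and progressed / dead), half-cycle-corrected discounted life-years and
  QALYs (effects 1.5%/year, costs 4%/year).
* **`economics`** — societal costing (drug acquisition, monitoring bundle,
  best supportive care, one-offs for mutation testing, CNS progression,
  end of life, productivity loss, indirect medical costs), incremental
  analysis with strict and extended dominance, ICERs along the efficient
  frontier, and a drug price-reduction threshold search.
* **`uncertainty`** — one-way DSA with tornado ranking, seeded Monte-Carlo
  PSA (gamma/beta/normal with moment matching), cost-effectiveness planes
  and acceptability curves via net monetary benefit.
* **`synthetic_data`** — seeded generators for censored survival cohorts,
  KM-figure surrogates and consistent multi-trial HR networks with known
  truth, plus the packaged parameter book (`table2_fixture()`) holding all
  published model inputs.

## Worked example

```python
import tkicea as tk

book = tk.table2_fixture()                 # published model inputs
results = tk.evaluate_strategies(book)     # trace + costing per strategy
ce = tk.incremental_analysis(results)
print(ce.incremental[["strategy", "cost", "ly", "qaly", "status", "icer_qaly"]])
```

```
   strategy          cost       ly     qaly                 status    icer_qaly
  gefitinib 114957.585280 1.972640 1.344339 dominated by erlotinib          NaN
  erlotinib 114151.561608 2.056345 1.404212                                 NaN
   afatinib 120864.706728 2.249830 1.524038                         56023.933772
osimertinib 164996.435247 2.976772 1.998230                         93067.300509
```

Reading the table: discounted life expectancy ranges from 1.97 years
(gefitinib) to 2.98 years (osimertinib), QALYs from 1.34 to 2.00. Erlotinib
is slightly more effective *and* cheaper than gefitinib, so gefitinib is
dominated and drops off the efficient frontier. Moving up the frontier,
afatinib costs €56,024 per QALY gained over erlotinib — below a Dutch
willingness-to-pay of €80,000/QALY — while osimertinib costs €93,067 per
QALY gained over afatinib, above it. The price-reduction search

```python
tk.price_threshold(book, wtp=80_000)   # -> 0.131
```

finds that a 13% cut to osimertinib's acquisition price (applied to both
first- and second-line use) would bring it onto the cost-effective frontier
at that threshold.

Life-years and QALYs reproduce the published base case to within ~2%
(published: 2.01/2.04/2.24/2.92 LYs and 1.36/1.39/1.52/2.01 QALYs). Cost
totals depend on a resource-use schedule that was never published; the
defaults shipped here reproduce the published orderings, dominance pattern
and the position of both frontier ICERs relative to €80,000/QALY, but not
the absolute totals — see `docs/methods.md` for the full account.

A probabilistic sensitivity analysis with plots:

```sh
tkicea psa --draws 1000 --seed 42 --out out/psa
```

writes the per-draw results, the osimertinib-vs-afatinib CE plane
(97.5% of draws in the upper-right quadrant: more QALYs at extra cost) and
the four acceptability curves. Other subcommands (`tkicea nma`,
`reconstruct`, `fit`, `run`, `evaluate`, `dsa`, `simulate`) expose the rest
of the pipeline on delimited text files; `tkicea --help` lists them.

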