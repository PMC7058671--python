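# Model input parameter book: Dutch societal-perspective cost-effectiveness of
# first-line EGFR-TKIs in EGFR-mutated NSCLC. Costs in 2018 euros; survival
# time unit is months. Each entry carries the distribution used in the
# probabilistic sensitivity analysis and, where published, a one-way DSA range
# (otherwise +/-20% of the mean is applied at run time).

currency: EUR
perspective: societal

costs:
  drug_per_cycle:
    gefitinib: 2526
    erlotinib: 2260
    afatinib: 2414
    osimertinib: 6106
    pemetrexed_cisplatin: 3029   # 500 mg/m2 pemetrexed + 75 mg/m2 cisplatin at BSA 1.70 m2
  bsc_per_cycle: 1775
  mutation_test: 929
  tumour_assessment: 405         # CT + MRI per assessment
  outpatient_visit: 83
  laboratory: 77                 # haematology, sputum, biochemistry per panel
  drug_administration: 271       # per infusion cycle (pemetrexed-cisplatin)
  cns_progression:
    osimertinib: 535
    standard_tki: 1250
  end_of_life: 2196
  home_care_per_hour: 11
  indirect_medical_lifetime: 10602   # lifetime average, spread per life-year
  informal_care_per_hour: 14
  travel_per_visit: 6            # 14 km at 0.19/km plus 3 euro parking
  productivity_loss: 4068        # friction-cost one-off at model entry

ae_unit_costs:
  alt_ast_increase: 464
  anaemia: 1953
  anorexia: 797
  asthenia: 813
  decreased_appetite: 826
  decreased_white_blood_cells: 1405
  diarrhoea: 2359
  dyspnoea: 467
  fatigue: 813
  febrile_neutropenia: 3033
  leukopenia: 1942
  nausea: 728
  neuropathy: 795
  neutropenia: 1405
  paronychia: 2359
  rash: 2359
  stomatitis: 4229
  vomiting: 728

utilities:
  progression_free: 0.71
  progressed: 0.67
  progressed_second_line: 0.62

ae_disutilities:
  alt_ast_increase: 0.0
  anaemia: -0.125
  anorexia: -0.142
  asthenia: -0.074
  decreased_appetite: -0.048
  decreased_white_blood_cells: -0.090
  diarrhoea: -0.047
  dyspnoea: -0.256
  fatigue: -0.074
  febrile_neutropenia: -0.090
  leukopenia: -0.090
  nausea: -0.048
  neuropathy: -0.048
  neutropenia: -0.090
  paronychia: -0.033
  rash: -0.033
  stomatitis: -0.151
  vomiting: -0.048

body_surface_area: 1.70

survival:
  # S(t) = exp(-lambda * t^gamma), t in months. Treatment lambdas equal the
  # chemotherapy lambda scaled by the pooled NMA hazard ratio; gamma shared.
  os:
    chemotherapy: {family: weibull, lam: 0.019, gamma: 1.203}
    gefitinib:    {family: weibull, lam: 0.020, gamma: 1.203}
    erlotinib:    {family: weibull, lam: 0.019, gamma: 1.203}
    afatinib:     {family: weibull, lam: 0.017, gamma: 1.203}
    osimertinib:  {family: weibull, lam: 0.012, gamma: 1.203}
  pfs:
    chemotherapy: {family: weibull, lam: 0.073, gamma: 1.478}
    gefitinib:    {family: weibull, lam: 0.031, gamma: 1.478}
    erlotinib:    {family: weibull, lam: 0.026, gamma: 1.478}
    afatinib:     {family: weibull, lam: 0.027, gamma: 1.478}
    osimertinib:  {family: weibull, lam: 0.013, gamma: 1.478}
  second_line:
    # exponential AFT intercepts: rate per month = exp(-intercept)
    pfs:
      osimertinib_2l:       {family: exponential, intercept: 2.985}
      pemetrexed_cisplatin: {family: exponential, intercept: 1.885}
    os:
      osimertinib_2l:       {family: exponential, intercept: 4.069}
      pemetrexed_cisplatin: {family: exponential, intercept: 2.861}

# Pooled NMA hazard ratios of each TKI versus chemotherapy (95% CI), used to
# derive treatment lambdas and to propagate comparative uncertainty in the PSA.
nma_hr_vs_chemotherapy:
  pfs:
    gefitinib:   {hr: 0.43, lower: 0.37, upper: 0.49}
    erlotinib:   {hr: 0.36, lower: 0.30, upper: 0.44}
    afatinib:    {hr: 0.37, lower: 0.31, upper: 0.44}
    osimertinib: {hr: 0.18, lower: 0.14, upper: 0.22}
  os:
    gefitinib:   {hr: 1.03, lower: 0.89, upper: 1.19}
    erlotinib:   {hr: 1.01, lower: 0.84, upper: 1.21}
    afatinib:    {hr: 0.90, lower: 0.76, upper: 1.06}
    osimertinib: {hr: 0.65, lower: 0.49, upper: 0.84}

second_line_mix:
  # T790M-positive progressors on a standard TKI receive second-line
  # osimertinib; the rest (and all first-line osimertinib progressors)
  # receive pemetrexed-cisplatin.
  gefitinib:   {osimertinib_2l: 0.5, pemetrexed_cisplatin: 0.5}
  erlotinib:   {osimertinib_2l: 0.5, pemetrexed_cisplatin: 0.5}
  afatinib:    {osimertinib_2l: 0.5, pemetrexed_cisplatin: 0.5}
  osimertinib: {pemetrexed_cisplatin: 1.0}

# Grade >=3 adverse-event incidence per arm. The source tables for these
# incidences are not part of the parameter book; this block is a schema
# placeholder shipped with zeros so that AE one-off terms default to zero
# unless the user supplies trial-extracted incidences.
ae_incidence:
  gefitinib: {}
  erlotinib: {}
  afatinib: {}
  osimertinib: {}
  osimertinib_2l: {}
  pemetrexed_cisplatin: {}

resource_schedule:
  # Declared calibration surface: per-cycle resource use while on first- or
  # second-line treatment, plus allocation rules for societal components.
  outpatient_visits_per_cycle: 1
  lab_panels_per_cycle: 1
  tumour_assessment_interval_cycles: 3
  travel_events_per_visit: 1
  home_care_hours_per_cycle: {pf1: 0, pf2: 0, pd2: 0}
  informal_care_hours_per_cycle: {pf1: 0, pf2: 0, pd2: 0}
  productivity_loss_allocation: one_off_at_entry
  indirect_medical_allocation: per_life_year
  cns_event_fraction: 1.0
  monitoring_states: [pf1, pf2]
  first_line_cost_components: [drug, monitoring, productivity_loss]

# Published one-way DSA ranges (low; high). Entries without a printed range
# are varied +/-20% of the mean.
dsa_ranges:
  costs.bsc_per_cycle: [1377, 2065]
  costs.outpatient_visit: [65, 97]
  costs.laboratory: [60, 89]
  costs.drug_administration: [210, 315]
  costs.cns_progression.osimertinib: [428, 642]
  costs.cns_progression.standard_tki: [1000, 1500]
  costs.end_of_life: [1703, 2555]
  costs.home_care_per_hour: [9, 13]
  costs.indirect_medical_lifetime: [4578, 26326]
  costs.informal_care_per_hour: [11, 17]
  costs.travel_per_visit: [5, 7]
  costs.productivity_loss: [3155, 4733]
  utilities.progression_free: [0.67, 0.80]
  utilities.progressed: [0.59, 0.75]
  utilities.progressed_second_line: [0.49, 0.74]
  ae_disutilities.anaemia: [-0.15, -0.10]
  ae_disutilities.anorexia: [-0.170, -0.114]
  ae_disutilities.asthenia: [-0.110, -0.037]
  ae_disutilities.decreased_appetite: [-0.080, -0.016]
  ae_disutilities.decreased_white_blood_cells: [-0.120, -0.060]
  ae_disutilities.diarrhoea: [-0.078, -0.016]
  ae_disutilities.dyspnoea: [-0.307, -0.204]
  ae_disutilities.fatigue: [-0.110, -0.037]
  ae_disutilities.febrile_neutropenia: [-0.122, -0.058]
  ae_disutilities.leukopenia: [-0.120, -0.059]
  ae_disutilities.nausea: [-0.080, -0.016]
  ae_disutilities.neuropathy: [-0.080, -0.016]
  ae_disutilities.neutropenia: [-0.120, -0.060]
  ae_disutilities.paronychia: [-0.056, -0.009]
  ae_disutilities.rash: [-0.056, -0.009]
  ae_disutilities.stomatitis: [-0.181, -0.121]
  ae_disutilities.vomiting: [-0.080, -0.016]
  body_surface_area: [1.36, 2.04]

distributions:
  costs: gamma
  utilities: beta
  disutilities: beta
  survival: normal
  body_surface_area: normal
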