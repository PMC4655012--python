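# Tiered calibration targets for the default city profile.
#
# Reference values are repo-chosen plausible magnitudes for the simulated
# metropolitan SPMI population (per 1,000 patients, annualized); they are NOT
# measurements of any real city.  Tier 1 is the high-confidence aggregate
# (total mental-health crises per year); tier 2 covers the key crisis
# outcomes; tier 3 the behavioural drivers.  Tolerances are relative.
targets:
  - {metric: annual_crises, reference: 320.0, tolerance: 0.20, tier: 1}
  - {metric: annual_arrests, reference: 115.0, tolerance: 0.25, tier: 2}
  - {metric: annual_hospitalizations, reference: 125.0, tolerance: 0.25, tier: 2}
  - {metric: annual_suicides, reference: 3.5, tolerance: 0.40, tier: 2}
  - {metric: attendance_rate, reference: 42.0, tolerance: 0.15, tier: 3}
  - {metric: on_medication_share, reference: 62.0, tolerance: 0.15, tier: 3}

tunables:
  - {path: "scale:patients.crisis_onset_probability", low: 0.4, high: 2.5, tier: 1}
  - {path: "scale:patients.propensity_to_commit_crime", low: 0.3, high: 3.0, tier: 2}
  - {path: "justice.cit_officer_probability", low: 0.05, high: 0.5, tier: 2}
  - {path: "economics.access_strain_high", low: 0.30, high: 0.80, tier: 3}
  - {path: "adherence_chart.start_threshold", low: -0.30, high: 0.30, tier: 3}
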