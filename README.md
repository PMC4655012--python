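# spmi-ecosim

An agent-based, weekly-tick microsimulation of a metropolitan care ecosystem
for people with **serious and persistent mental illness (SPMI)** —
schizophrenia, schizoaffective disorder, severe bipolar disorder.  It is
built for health-system analysts who want to ask *what happens to the whole
system* — hospitalizations, arrests, homelessness, suicides, costs — when a
care-coordination process changes, without disrupting a real city.

Each of the ~1,000 simulated patients carries an individual mental-health
score on a GAF-style 1–100 scale (with a per-patient floor that untreated
illness declines to), a physical-health score, a medication-adherence state
chart, a treatment plan, finances, a living environment and a criminal
history.  Every week each patient makes a sequence of stochastic decisions —
crisis onset, appointment attendance, refills, environment transitions —
against shared, capacity-limited providers and a criminal-justice pathway
(CIT diversion, jail diversion, sentencing, release).  Two system levers
model care-coordination technology:

* **Handoff Success Rate** — the probability that a patient referred or
  discharged between providers is engaged rather than *lost to the system*
  (no appointments, no refills, until a crisis or outreach re-engages them);
* **Patient Appointment Compliance Rate** — the probability a scheduled
  appointment is attended (baseline below 50%, as observed for this
  population).

The package reproduces the two published intervention analyses: sweeping the
handoff rate by 1-point steps over −15..+20 and the compliance rate over
−10..+20, with common random numbers, and summarising outcomes over the
expert-panel bands (+5..+15 and +3..+12 points respectively).

## Worked example

```python
from spmi_ecosim import EcosystemModel

model = EcosystemModel.default_city()   # the shipped calibrated profile
results = model.simulate(seed=42)
print(results.summary())
```

prints (abridged):

```
Simulation run summary
======================
seed        : 42
weeks       : 260
patients    : 1000

annual_crises                                 294.000
annual_hospitalizations                       119.000
annual_arrests                                114.000
annual_suicides                                 2.800
on_medication_share                            63.827
lost_share                                     11.527
attendance_rate                                41.522
recidivism_rate                                37.143
cost_hospitalization                      6133050.000
cost_incarceration                        1490450.000
mean_env_private_residence_final_year         697.192
```

Reading it: over five simulated years this city of 1,000 SPMI patients
experiences ~294 mental-health crises a year; ~64% of living patients are on
medication in the final year while ~11.5% are lost to the system after
failed referral handoffs; only 41% of scheduled appointments are kept.
Costs are in an abstract currency unit — analyses report percent changes
against a baseline, never absolute amounts.

Running an intervention experiment:

```python
sweep = model.sweep("handoff_success_rate", replications=8)
from spmi_ecosim.experiments import handoff_outcomes
print(handoff_outcomes(sweep, band=(5, 15)))
```

returns the min/max over the +5..+15 band of the three handoff measures
(on-medication percentage-point change, incarceration and hospitalization
cost reductions).  `model.fit(...)` runs the tiered calibration against a
targets file (see `spmi_ecosim/profiles/calibration_targets.yaml`), and
`spmi-ecosim --help` exposes the same operations as a CLI
(`validate`, `run`, `calibrate`, `sweep`).

The default profile's parameter values are this repository's own calibrated
choices for a plausible large metropolitan area (documented in
`docs/methods.md`); no real patient data is used or shipped.

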