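# Model and methods

`spmi-ecosim` is a discrete-time, agent-based microsimulation of a
metropolitan care ecosystem for people with serious and persistent mental
illness (SPMI).  Each patient is an agent with an individual internal state;
the shared environment supplies capacity-limited care providers, housing
environments, and a criminal-justice pathway.  Time advances in weekly ticks;
default runs cover five years (260 ticks) to capture long-term system
behaviour.

## Patient state

Each patient carries:

* a **mental-health score** on a 1–100 scale patterned after the Global
  Assessment of Functioning (GAF), with a per-patient **floor** representing
  the level an untreated illness declines to;
* a **physical-health score** (1–100) with a per-patient weekly drift;
* a medication-adherence state (on/off medication) driven by a scored state
  chart;
* a living environment (private residence, assisted living, homeless,
  hospital inpatient, correctional facility), with episodic stays governed by
  length-of-stay countdowns;
* a treatment plan (medicine, appointment cadence per provider type,
  designated environment);
* financial resources, employment, substance-abuse status, family support,
  stress, criminal history;
* a **lost-to-system** flag: set when a referral handoff fails, cleared only
  when a crisis resolution or outreach re-engages the patient.  Lost patients
  keep no appointments and cannot refill prescriptions.

## The weekly update

Each living patient updates once per tick in a fixed order (patients are
processed in a freshly shuffled order each week because shared capacities
make order matter):

1. **Critical outcomes** — at most one of: crisis onset (weekly probability
   by coarse mental-health category: severe ≤30 < serious ≤50 < moderate ≤70
   < mild), a crime outside crisis (category-specific propensity),
   substance-abuse start/stop, employment gain/loss.  Priority: crisis >
   crime > substance abuse > employment.  Recent provider contact (within the
   adherence chart's 4-week recency window) multiplies the crisis probability
   by `1 − crisis_protection_contact`: active treatment intercepts
   decompensation before it becomes a crisis.
2. **Crisis resolution** — outcome drawn from a categorical mix over
   {hospitalization, arrest, homelessness, stabilized, suicide}, conditioned
   on engagement status: a lost patient's crisis is arrest-heavier and
   stabilization-lighter because no provider is positioned to step in.  A
   full inpatient unit converts a hospitalization into a crisis-stabilization
   contact.  Every crisis shocks the mental-health score downward (clamped at
   the floor).
3. **Adherence state chart** — the adherence score is a signed weighted sum
   of stress (−), substance abuse (−), medicine side-effect severity (−),
   medicine cost-to-patient factor (−), family support (+), an active
   long-acting injectable (+), and recent provider contact (+).  An
   on-medication patient stops when the score falls strictly below the stop
   threshold (suppressed while an injectable is active); an off-medication
   patient restarts when it rises strictly above the start threshold
   (hysteresis: stop ≤ start).
4. **Appointments** — each plan appointment fires on its own staggered
   cadence (patients and appointment types are phase-shifted so a plan's
   contacts spread over the interval).  Attendance requires the compliance
   draw to pass (`compliance rate × access factor`) and the provider to have
   weekly capacity left; an attended visit consumes capacity, counts as
   provider contact, accrues costs, and can switch the medicine to a
   long-acting injectable at facilities that use them.
5. **Refills** — on-medication patients refill on the medicine's cadence;
   the refill succeeds with the medicine's access factor and always fails
   for lost patients (the prescription lapses).  Weekly medication costs
   accrue while on medication.
6. **Environment progression** — episodic stays count down; at zero the
   patient is discharged (hospital) or released (jail): a new plan is
   assigned, medication restarts (with a configured probability on release),
   and the receiving provider must be engaged through a referral handoff.
   Community patients face a plan-review referral hazard (a provider-side
   plan change that also requires a handoff) and then a mental-health-
   dependent transition among community environments, with capacity overflow
   redirection.
7. **Health-score updates** —
   `mh' = clamp(mh + medication_effect·on_med + (contact_effect + visit
   bonuses)·contact + env_mh − untreated_decline·(off_med ∧ no contact) −
   stress_weight·stress + support_weight·support +
   coupling_mh·(ph − mh)/100 + noise, floor, 100)` and
   `ph' = clamp(ph + drift + env_ph − side_effect_scale·severity·on_med +
   coupling_ph·(mh − ph)/100, 1, 100)`.  The noise term is a centred
   uniform step with configurable standard deviation, representing
   week-to-week fluctuation.
8. **Finances** — employment income is credited; costs were debited when
   posted, with a floor at zero.  Low resources raise the access "strain",
   reducing the probability of accessing costed services
   (`access = 1 − (factor/5)·strain(resources)`, strain decaying
   exponentially from `strain_high` at zero resources to `strain_low`).

### Referral handoffs

Any care transition between providers (hospital discharge, jail release,
plan review, stabilization-unit re-engagement) succeeds with probability
`handoff_success_rate × P(locate patient | environment)`.  Facilities hand
off patients "in hand" (locate probability 1); community referrals use the
environment's locate probability (lowest for homelessness).  A failed
handoff marks the patient lost to the system.

### Criminal-justice pathway

Arrest (from a crisis or a crime): with the CIT probability a Crisis
Intervention Team officer redirects to crisis stabilization; otherwise a
crime degree is drawn, eligible degrees may enter the Jail Diversion Program
(supervised treatment plan, no incarceration), and the rest serve a sentence
drawn from the degree's distribution in a correctional facility.  Release
assigns a discharge location, a plan, and a handoff.  Recidivism is
re-arrest after any release.

## Randomness and common random numbers

Every patient owns a dedicated `random.Random` substream keyed by
`(run seed, patient id)` and consumes exactly 16 uniforms per week from a
fixed slot layout, whether or not a branch needs them.  This makes runs
bit-reproducible and gives strong common-random-number pairing: changing a
system lever perturbs only the decisions it actually gates, so paired
contrasts across lever values are far tighter than independent runs.
System-level randomness (the weekly shuffle) uses a separate substream.

## Costs

Costs are tracked in an abstract currency unit, split exactly into
patient-borne and third-party shares, per week and per category (medication,
outpatient, hospitalization, incarceration, housing, stabilization,
diversion).  Hospital and jail weeks additionally carry a crisis-origin flag
so crisis-attributable costs can be separated from, e.g., incarceration for
crimes committed outside a crisis.  All headline cost results are percent
changes against a baseline run, so the unit never enters a result.

## Calibration

Calibration is tiered: tier 1 matches the annual number of mental-health
crises (±20%), tier 2 the crisis outcomes (hospitalizations, arrests,
suicides), tier 3 behavioural drivers (attendance, adherence).  Because
moving one input usually moves several outputs, a tier's objective always
re-includes all earlier tiers' targets, normalized by their tolerances; an
accepted step can never push an already-calibrated metric out of band.  The
search is coordinate descent with a bounded golden-section line search per
parameter, evaluated on replication means with fixed common random numbers.
Reference values shipped in `profiles/calibration_targets.yaml` are
repo-chosen plausible magnitudes for the simulated city, not measurements of
a real one.  An internal-dynamics check reports the per-patient temporal
standard deviation of the mental-health score by initial severity class and
flags classes exceeding configured bounds.

## The default city profile

No parameter magnitudes are published for any real deployment of this kind
of model, so the shipped `profiles/default_city.yaml` is this package's own
calibrated city: 1,000 SPMI patients, ~320 crises per year, appointment
attendance ≈ 42% (well below 50%, as expected for this population),
on-medication share ≈ 62%, and roughly one patient in eight lost to the
system at any time at the baseline handoff success rate of 0.95.  Weekly
facility costs dominate outpatient visit costs (a profile lint rule).  The
two baseline lever values are deliberate: per-referral handoff failures of
5% still accumulate into a double-digit lost-to-system share because
re-engagement is slow, and a +5-point improvement saturates the rate at 1.0
(rates are clamped to [0, 1]), which is why the handoff experiment's
response is flat across the +5..+15 expert band.  Outpatient capacity is set
slightly above baseline attendance demand, so the compliance lever's
response flattens once capacity binds a few points above baseline.

## The intervention experiments

* **Handoff sweep**: −15..+20 percentage points by 1 (36 points).  Measures:
  percentage-point change of the on-medication share (final-year mean, % of
  living patients), percent reductions of 5-year incarceration and
  hospitalization costs.  Band summaries take min/max over the +5..+15
  expert band.
* **Compliance sweep**: −10..+20 points by 1 (31 points).  Measures: percent
  change of private-residence occupancy (final-year mean count), percent
  reductions of crisis-attributable incarceration and hospitalization costs.
  Band: +3..+12.

Both sweeps use common random numbers (identical replication seeds at every
delta), and percent-change curves pass through zero at delta 0 exactly.
Deltas that clamp to the same effective rate reuse the same runs (they are
identical by determinism).

## Problem sizes

Defaults target a single CPU.  `scripts/acceptance.py` runs both full delta
grids at the profile's 1,000 patients × 260 weeks with replications
allocated where the band summaries are computed: 8 per point inside the
handoff band, 24 inside the compliance band and at the baselines, 3–4
elsewhere.  The test suite exercises the same code paths at reduced
population/week counts and on reduced delta grids; the spec'd 30-replication
design is available by setting `SweepSpec(replications=30)`.

## What the synthetic generator does and does not capture

The generator draws patient fields independently (apart from the floor ≤
initial-score constraint and the diagnosis-conditioned plan); real
populations correlate severity with housing, employment and justice history.
There is no real demographic microdata, no geography, no household structure
beyond a scalar family-support level, no insurance-plan detail, and no
within-week event ordering.  Passing tests therefore demonstrate internal
consistency of the mechanism and calibration machinery, not predictive
validity for any real metropolitan area.

## Numerical choices and edge cases

* Scores clamp to [floor, 100] and [1, 100]; clamping is idempotent.
* Adherence transitions use strict inequalities at both thresholds.
* Truncated-normal initial scores are sampled by clipping one Gaussian draw.
* Categorical draws use a single uniform against cumulative thresholds, with
  the last bin absorbing rounding residue.
* A full destination environment redirects to its configured overflow
  (default: homelessness); a full hospital converts an admission into a
  stabilization contact.
* Funding support scales provider counts linearly (floored) and shifts
  cost-to-patient factors by `round(log2(level))`, clamped to 0–5.
* The decision order within a week is fixed as documented above; changing it
  is a breaking, config-versioned change.

## Known limitations

* The lost-to-system share and the crisis-outcome mixes are the load-bearing
  mechanism for the handoff experiment; they are calibrated, not estimated
  from data.
* Crisis-attributable incarceration cost is a rare-event total (a few
  hundred jail entries per run), the noisiest headline output; band
  summaries for it carry the widest replication error.
* Patients update sequentially within a week; capacity contention is
  resolved in shuffled order rather than by clinical priority.
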