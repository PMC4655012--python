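"""Shared ecosystem state and the patient <-> system interactions.

This module owns the weekly shared resources (provider capacity, environment
occupancy) and the operations where a patient meets the wider system:
appointment attendance, referral handoffs, crisis resolution, and the
criminal-justice pathway (arrest, sentencing, jail diversion, release).

All randomness flows through explicit uniforms: every operation accepts the
uniform draws it needs (``u_*`` keyword arguments) and falls back to drawing
from a supplied ``rng``.  The weekly engine passes draws from each patient's
fixed per-week draw layout, which keeps replicate runs bit-reproducible and
makes common-random-number pairing across lever settings tight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config import ConfigError, ModelConfig
from .economics import CostLedger, access_factor

__all__ = ["RunContext", "EcosystemState", "CrisisResolution",
           "attempt_appointment", "refer_patient", "resolve_crisis",
           "process_arrest", "release_from_jail", "get_context"]


def _cum(probs: dict) -> list:
    """Cumulative-threshold list for single-uniform categorical draws."""
    out, acc = [], 0.0
    for label, p in probs.items():
        acc += p
        out.append((acc, label))
    if out:
        out[-1] = (float("inf"), out[-1][1])  # guard against rounding
    return out


def _pick(cum: list, u: float):
    for threshold, label in cum:
        if u < threshold:
            return label
    return cum[-1][1]


class RunContext:
    """Precomputed lookup tables for one run of a validated config."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.dyn = cfg.dynamics
        self.econ = cfg.economics
        lev = cfg.levers
        self.handoff = lev.handoff_success_rate
        self.compliance = lev.patient_appointment_compliance_rate
        self.outreach = lev.outreach_reengagement_rate

        chart = cfg.adherence_chart
        w = chart.factor_weights
        self.w_stress = w.get("stress", 0.0)
        self.w_substance = w.get("substance_abuse", 0.0)
        self.w_side = w.get("side_effect_severity", 0.0)
        self.w_cost = w.get("cost_to_patient_factor", 0.0)
        self.w_support = w.get("family_support", 0.0)
        self.w_lai = w.get("lai_active", 0.0)
        self.w_contact = w.get("recent_provider_contact", 0.0)
        self.stop_threshold = chart.stop_threshold
        self.start_threshold = chart.start_threshold
        self.contact_window = chart.contact_recent_weeks

        self.crisis_protect_mult = 1.0 - self.dyn.crisis_protection_contact

        pats = cfg.patients
        self.crisis_p = [pats.crisis_onset_probability[c]
                         for c in ("severe", "serious", "moderate", "mild")]
        self.crime_p = [pats.propensity_to_commit_crime[c]
                        for c in ("severe", "serious", "moderate", "mild")]
        self.outcome_cum = {
            status: _cum(mix)
            for status, mix in pats.crisis_outcome_probabilities.items()
        }
        self.p_sub_start = pats.substance_start_probability
        self.p_sub_stop = pats.substance_stop_probability
        self.p_emp_gain = pats.employment_gain_probability
        self.p_emp_loss = pats.employment_loss_probability

        self.envs = {e.id: e for e in cfg.environments}
        self.located = {e.id: e.probability_of_being_located for e in cfg.environments}
        self.env_ids = list(self.envs)
        self.transition_cum = {}
        for e in cfg.environments:
            if e.transition_matrix is not None:
                for ci, cat in enumerate(("severe", "serious", "moderate", "mild")):
                    self.transition_cum[(e.id, ci)] = _cum(e.transition_matrix[cat])
        self.hospital_id = next(
            (e.id for e in cfg.environments if e.cost_category == "hospitalization"), None)
        self.jail_id = next(
            (e.id for e in cfg.environments if e.cost_category == "incarceration"), None)
        self.homeless_id = "homeless" if "homeless" in self.envs else None
        hosp = self.envs.get(self.hospital_id)
        self.hospital_discharge_cum = (
            _cum(hosp.discharge_location) if hosp is not None and
            hosp.discharge_location else None)

        self.plans = {p.id: p for p in cfg.treatment_plans}
        self.plan_appts = {
            p.id: tuple(
                (a.provider_type, a.interval_weeks,
                 a.phase_offset_weeks % a.interval_weeks)
                for a in p.appointments)
            for p in cfg.treatment_plans
        }
        self.meds = {m.id: m for m in cfg.medicines}
        self.lai_med_id = next(
            (m.id for m in cfg.medicines if m.is_long_acting_injectable), None)
        self.providers = {p.provider_type: p for p in cfg.providers}
        self.weekly_capacity = {
            p.provider_type: p.count * p.capacity_per_week for p in cfg.providers
        }
        self.diversion_plan_id = "diversion" if "diversion" in self.plans else None
        # static part of the adherence score per medicine (side effects, cost)
        self.med_adherence_static = {
            m.id: (self.w_side * m.short_term_side_effect_severity
                   + self.w_cost * m.cost_to_patient_factor)
            for m in cfg.medicines
        }

        jus = cfg.justice
        self.cit_p = jus.cit_officer_probability
        self.degree_cum = _cum(jus.crime_degree_distribution.probs)
        self.sentences = jus.sentence_weeks_by_degree
        self.diversion_p = jus.jail_diversion_entry_probability
        self.diversion_eligible = set(jus.diversion_eligible_degrees)
        self.release_cum = _cum(jus.discharge_location_distribution.probs)
        self.discharge_plan_rule = jus.discharge_plan_rule
        self.release_med_p = jus.release_on_medication_probability
        self.initial_plan = pats.initial_treatment_plan

    def plan_for(self, diagnosis: str, rule: dict) -> str:
        pid = rule.get(diagnosis)
        if pid is None:
            pid = rule.get("default")
        if pid is None or pid not in self.plans:
            pid = self.initial_plan.get(
                diagnosis, next(iter(self.initial_plan.values())))
        return pid


_CTX_CACHE: dict = {}


def get_context(cfg) -> RunContext:
    """Return a RunContext for ``cfg`` (pass-through if already a context)."""
    if type(cfg) is RunContext:
        return cfg
    key = id(cfg)
    hit = _CTX_CACHE.get(key)
    if hit is not None and hit[0] is cfg:
        return hit[1]
    ctx = RunContext(cfg)
    _CTX_CACHE[key] = (cfg, ctx)
    if len(_CTX_CACHE) > 64:  # bounded scratch cache
        _CTX_CACHE.pop(next(iter(_CTX_CACHE)))
    return ctx


class EcosystemState:
    """Mutable shared state for one run: capacities, occupancy, counters."""

    def __init__(self, ctx: RunContext, population, n_weeks: int,
                 record_events: bool = False):
        self.ctx = ctx
        self.week = 0
        self.ledger = CostLedger(n_weeks)
        self.capacity_left = dict(ctx.weekly_capacity)
        self.occupancy = {eid: 0 for eid in ctx.envs}
        for p in population:
            if p.alive:
                self.occupancy[p.environment_id] += 1
        self.events = [] if record_events else None
        self.wk: dict = {}
        self.releases = 0
        self.recidivist_arrests = 0
        self.reset_week(0)

    def reset_week(self, week: int) -> None:
        self.week = week
        self.capacity_left = dict(self.ctx.weekly_capacity)
        self.wk = {
            "crises": 0, "hospitalizations": 0, "arrests": 0,
            "recidivist_arrests": 0, "suicides": 0, "homeless_entries": 0,
            "crimes": 0, "scheduled": 0, "kept": 0, "releases": 0,
            "diversions": 0, "referrals": 0, "handoff_failures": 0,
            "reengagements": 0, "med_starts": 0, "med_stops": 0,
        }

    # -- event/cost plumbing ------------------------------------------------

    def log(self, patient_id: int, kind: str, detail: str = "",
            patient_amt: float = 0.0, third_amt: float = 0.0) -> None:
        if self.events is not None:
            self.events.append(
                (self.week, patient_id, kind, detail, patient_amt, third_amt))

    def post_cost(self, patient_id: int, kind: str, detail: str, category: str,
                  patient_amt: float, third_amt: float,
                  crisis_origin: bool = False) -> float:
        """Post to the ledger, mirror into the event log, return patient share."""
        self.ledger.post(self.week, category, patient_amt, third_amt, crisis_origin)
        if self.events is not None:
            self.events.append(
                (self.week, patient_id, kind, detail, patient_amt, third_amt))
        return patient_amt

    # -- occupancy ----------------------------------------------------------

    def move(self, patient, dest_id: str) -> str:
        """Move a patient, honouring capacity with the overflow rule.

        Returns the environment actually entered (the configured overflow
        destination when the requested one is full).
        """
        ctx = self.ctx
        if dest_id != patient.environment_id:
            dest = ctx.envs[dest_id]
            if dest.capacity is not None and self.occupancy[dest_id] >= dest.capacity:
                fallback = dest.overflow_environment_id or ctx.homeless_id
                if fallback is None or fallback == dest_id:
                    return patient.environment_id  # nowhere to go: stay
                dest_id = fallback
        if dest_id == patient.environment_id:
            return dest_id
        self.occupancy[patient.environment_id] -= 1
        self.occupancy[dest_id] += 1
        patient.environment_id = dest_id
        return dest_id

    def remove(self, patient) -> None:
        self.occupancy[patient.environment_id] -= 1
        patient.alive = False


@dataclass(frozen=True)
class CrisisResolution:
    """How one mental-health crisis resolved."""

    outcome: str  # hospitalization | arrest | homelessness | suicide | stabilized
    destination_environment_id: Optional[str]
    new_plan_id: Optional[str]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def attempt_appointment(patient, provider_type: str, cfg, state: EcosystemState,
                        rng=None, *, u_attend=None, u_lai=None) -> bool:
    """One scheduled appointment: does the patient show up, and with what effects.

    Attendance requires the compliance draw to succeed (compliance rate times
    the cost-driven access factor) and the provider to have weekly capacity
    left.  An attended visit consumes one capacity unit, counts as provider
    contact (feeding the mental-health update and the adherence chart),
    accrues visit costs, and may switch the plan's medicine to a long-acting
    injectable at facilities that use them.
    """
    ctx = get_context(cfg)
    prov = ctx.providers.get(provider_type)
    if prov is None:
        raise ConfigError(f"unknown provider type {provider_type!r}")
    if u_attend is None:
        u_attend = rng.random()
    if u_lai is None:
        u_lai = rng.random()
    state.wk["scheduled"] += 1
    p_attend = ctx.compliance * access_factor(
        prov.cost_to_patient_factor, patient.financial_resources, ctx.econ)
    if u_attend >= p_attend or state.capacity_left[provider_type] <= 0:
        state.log(patient.id, "appointment_missed", provider_type)
        return False
    state.capacity_left[provider_type] -= 1
    state.wk["kept"] += 1
    patient.weeks_since_contact = 0
    outlay = state.post_cost(patient.id, "visit", provider_type, "outpatient",
                             prov.patient_cost_per_visit,
                             prov.third_party_cost_per_visit)
    patient.financial_resources = max(patient.financial_resources - outlay, 0.0)
    patient.visit_mh_bonus += prov.mh_effect_per_visit
    # long-acting injectable management at the facility
    if patient.on_medication and ctx.lai_med_id is not None:
        if patient.medicine_id == ctx.lai_med_id:
            patient.lai_weeks_remaining = ctx.meds[ctx.lai_med_id].lai_interval_weeks
        elif prov.lai_probability > 0.0 and u_lai < prov.lai_probability:
            patient.medicine_id = ctx.lai_med_id
            patient.lai_weeks_remaining = ctx.meds[ctx.lai_med_id].lai_interval_weeks
            state.log(patient.id, "lai_switch", ctx.lai_med_id)
    return True


def refer_patient(patient, from_provider: str, to_provider: str, cfg,
                  rng=None, *, u=None, located_override=None) -> bool:
    """A care transition that requires a handoff between providers.

    Succeeds with probability ``handoff_success_rate`` times the probability
    of locating the patient in their current environment; on failure the
    patient is lost to the system (no appointments, no refills) until
    re-engaged through a crisis resolution or outreach.
    """
    ctx = get_context(cfg)
    if u is None:
        u = rng.random()
    located = (located_override if located_override is not None
               else ctx.located.get(patient.environment_id, 1.0))
    success = u < ctx.handoff * located
    if success:
        patient.lost_to_system = False
    else:
        patient.lost_to_system = True
        patient.in_jail_diversion = False
    return success


def _stabilize(patient, ctx: RunContext, state: EcosystemState,
               u_reengage, crisis_origin=True) -> None:
    """Crisis stabilization unit contact: costed, counts as provider contact,
    and offers a lost patient a referral back into care."""
    patient.weeks_since_contact = 0
    csu = ctx.providers.get("crisis_stabilization_unit")
    outlay = state.post_cost(patient.id, "stabilization", "crisis_stabilization_unit",
                             "stabilization", ctx.econ.stabilization_cost_patient,
                             ctx.econ.stabilization_cost_third_party)
    patient.financial_resources = max(patient.financial_resources - outlay, 0.0)
    if csu is not None:
        patient.visit_mh_bonus += csu.mh_effect_per_visit
    if patient.lost_to_system:
        state.wk["referrals"] += 1
        ok = refer_patient(patient, "crisis_stabilization_unit",
                           "community_mental_health_center", ctx, u=u_reengage)
        if ok:
            state.wk["reengagements"] += 1
            patient.plan_id = ctx.plan_for(patient.diagnosis, ctx.initial_plan)
            patient.medicine_id = ctx.plans[patient.plan_id].medicine_id
        else:
            state.wk["handoff_failures"] += 1


def process_arrest(patient, cfg, state: EcosystemState, rng=None, *,
                   u_cit=None, u_degree=None, u_div=None, u_sentence=None,
                   crisis_origin: bool = False) -> str:
    """Law-enforcement contact: CIT diversion, jail diversion, or incarceration.

    Returns the disposition: ``"cit_redirect"``, ``"diversion"`` or
    ``"incarcerated"``.
    """
    ctx = get_context(cfg)
    if u_cit is None:
        u_cit = rng.random()
    if u_degree is None:
        u_degree = rng.random()
    if u_div is None:
        u_div = rng.random()
    if u_sentence is None:
        u_sentence = rng.random()
    state.wk["arrests"] += 1
    if patient.released_before:
        state.wk["recidivist_arrests"] += 1
        state.recidivist_arrests += 1
    state.log(patient.id, "arrest", "crisis" if crisis_origin else "crime")
    if u_cit < ctx.cit_p:
        # Crisis Intervention Team officer at the scene: redirect to treatment
        _stabilize(patient, ctx, state, u_div, crisis_origin)
        state.log(patient.id, "cit_redirect")
        return "cit_redirect"
    degree = _pick(ctx.degree_cum, u_degree)
    if degree == "misdemeanor":
        if patient.criminal_history == "none":
            patient.criminal_history = "minor"
    else:
        patient.criminal_history = "major"
    if degree in ctx.diversion_eligible and u_div < ctx.diversion_p:
        state.wk["diversions"] += 1
        patient.in_jail_diversion = True
        patient.lost_to_system = False
        patient.weeks_since_contact = 0
        if ctx.diversion_plan_id is not None:
            patient.plan_id = ctx.diversion_plan_id
            patient.medicine_id = ctx.plans[ctx.diversion_plan_id].medicine_id
        state.log(patient.id, "jail_diversion", degree)
        return "diversion"
    sentence = int(ctx.sentences[degree].sample_u(u_sentence))
    sentence = max(sentence, 1)
    if ctx.jail_id is not None:
        entered = state.move(patient, ctx.jail_id)
        if entered == ctx.jail_id:
            patient.environment_weeks_remaining = sentence
            patient.crisis_origin_stay = crisis_origin
    patient.employed = False
    patient.in_jail_diversion = False
    state.log(patient.id, "incarceration", f"{degree}:{sentence}w")
    return "incarcerated"


def resolve_crisis(patient, cfg, state: EcosystemState, rng=None, *,
                   u_outcome=None, u_aux=None, u_degree=None, u_div=None,
                   u_los=None) -> CrisisResolution:
    """Resolve a mental-health crisis that fired this week.

    The outcome is drawn from the profile's crisis-outcome mix, conditioned on
    whether the patient is engaged with care or lost to the system (a lost
    patient's crisis is arrest-heavier: no provider is positioned to step in).
    A full inpatient unit converts a hospitalization into a crisis-
    stabilization contact.  The crisis itself shocks the mental-health score
    downward (clamped at the patient's floor).
    """
    ctx = get_context(cfg)
    if u_outcome is None:
        u_outcome = rng.random()
    if u_aux is None:
        u_aux = rng.random()
    if u_degree is None:
        u_degree = rng.random()
    if u_div is None:
        u_div = rng.random()
    if u_los is None:
        u_los = rng.random()
    state.wk["crises"] += 1
    status = "lost" if patient.lost_to_system else "engaged"
    outcome = _pick(ctx.outcome_cum[status], u_outcome)
    patient.mental_health = max(patient.mental_health - ctx.dyn.crisis_mh_shock,
                                patient.mh_floor)
    state.log(patient.id, "crisis", outcome)

    if outcome == "hospitalization":
        hid = ctx.hospital_id
        hosp = ctx.envs.get(hid)
        full = (hosp is not None and hosp.capacity is not None
                and state.occupancy[hid] >= hosp.capacity
                and patient.environment_id != hid)
        if hid is None or full:
            outcome = "stabilized"  # no bed: stabilize in place
        else:
            state.move(patient, hid)
            los = max(int(hosp.length_of_stay.sample_u(u_los)), 1)
            patient.environment_weeks_remaining = los
            patient.crisis_origin_stay = True
            patient.on_medication = patient.medicine_id is not None
            patient.employed = False
            state.wk["hospitalizations"] += 1
            state.log(patient.id, "hospital_admission", f"{los}w")
            return CrisisResolution(outcome, hid, None)
    if outcome == "arrest":
        process_arrest(patient, ctx, state, u_cit=u_aux, u_degree=u_degree,
                       u_div=u_div, u_sentence=u_los, crisis_origin=True)
        return CrisisResolution(outcome, patient.environment_id, None)
    if outcome == "homelessness":
        if ctx.homeless_id is not None:
            state.move(patient, ctx.homeless_id)
            state.wk["homeless_entries"] += 1
        return CrisisResolution(outcome, patient.environment_id, None)
    if outcome == "suicide":
        if patient.on_medication:
            # close out the adherence tracking before removal
            patient.on_medication = False
            state.wk["med_stops"] += 1
            state.log(patient.id, "medication_stop")
        state.wk["suicides"] += 1
        state.remove(patient)
        state.log(patient.id, "suicide")
        return CrisisResolution(outcome, None, None)
    # stabilized
    _stabilize(patient, ctx, state, u_aux)
    new_plan = patient.plan_id if not patient.lost_to_system else None
    return CrisisResolution("stabilized", patient.environment_id, new_plan)


def release_from_jail(patient, cfg, state: EcosystemState, rng=None, *,
                      u_location=None, u_handoff=None, u_med=None):
    """Discharge at sentence end: location, treatment plan, and the handoff.

    Continuity of care is subject to :func:`refer_patient`; a failed handoff
    on release leaves the patient lost to the system.
    """
    ctx = get_context(cfg)
    if u_location is None:
        u_location = rng.random()
    if u_handoff is None:
        u_handoff = rng.random()
    if u_med is None:
        u_med = rng.random()
    state.wk["releases"] += 1
    state.releases += 1
    patient.released_before = True
    patient.crisis_origin_stay = False
    patient.environment_weeks_remaining = None
    patient.plan_id = ctx.plan_for(patient.diagnosis, ctx.discharge_plan_rule)
    patient.medicine_id = ctx.plans[patient.plan_id].medicine_id
    patient.on_medication = (patient.medicine_id is not None
                             and u_med < ctx.release_med_p)
    state.wk["referrals"] += 1
    # the releasing facility refers while the patient is still in hand
    ok = refer_patient(patient, "correctional_facility",
                       "community_mental_health_center", ctx,
                       u=u_handoff, located_override=1.0)
    if not ok:
        state.wk["handoff_failures"] += 1
    dest = _pick(ctx.release_cum, u_location)
    state.move(patient, dest)
    state.log(patient.id, "jail_release", dest)
    return patient
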