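"""The weekly per-patient update.

Each living patient is updated once per weekly tick, in a fixed documented
order:

1. critical outcomes (crisis / crime / substance abuse / employment; at most
   one applies, in that priority order);
2. crisis resolution through the ecosystem, if a crisis fired;
3. the medication-adherence state chart;
4. scheduled appointment attendance (shared provider capacity);
5. the medication refill decision (and weekly medication costs);
6. environment progression: episodic length-of-stay countdown with discharge
   or release (each a referral handoff), plan-review referrals, outreach to
   lost patients, and the mental-health-dependent environment transition;
7. mental- and physical-health score updates;
8. the finance update (income; costs are debited as they are posted).

Every patient consumes exactly ``N_DRAWS`` uniforms from their own substream
per week, whether or not a branch needs them.  The fixed draw layout keeps
substreams aligned across lever settings, so paired (common-random-number)
runs differ only where a lever actually changes a decision.

The crisis shock and the weekly score formulas clamp the mental-health score
to ``[mh_floor, 100]`` and the physical score to ``[1, 100]``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AdherenceChartConfig, ConfigError
from .economics import access_factor
from .ecosystem import (EcosystemState, _pick, attempt_appointment,
                        get_context, process_arrest, refer_patient,
                        release_from_jail, resolve_crisis)
from .population import coarse_index

__all__ = ["CriticalOutcome", "N_DRAWS", "weekly_update",
           "draw_critical_outcomes", "adherence_step", "update_mental_health",
           "update_physical_health", "transition_environment"]

#: uniforms consumed per patient per week (fixed layout; see weekly_update)
N_DRAWS = 16

_U12 = 3.4641016151377544  # sqrt(12): scales a centred uniform to unit sd


@dataclass(frozen=True)
class CriticalOutcome:
    """The single highest-priority major state change drawn for the week."""

    kind: str  # crisis | crime | substance_abuse_start | substance_abuse_stop |
    #          # employment_found | employment_lost | none
    detail: str = ""


def _critical_kind(patient, ctx, u_main, u_substance, u_employment) -> str:
    """Shared critical-outcome logic (priority: crisis > crime > substance >
    employment; at most one applies)."""
    cat = coarse_index(patient.mental_health)
    p_crisis = ctx.crisis_p[cat]
    if patient.weeks_since_contact <= ctx.contact_window:
        p_crisis *= ctx.crisis_protect_mult  # active treatment intercepts
    if u_main < p_crisis:
        return "crisis"
    if u_main < p_crisis + ctx.crime_p[cat]:
        return "crime"
    if not patient.substance_abuse:
        if u_substance < ctx.p_sub_start:
            return "substance_abuse_start"
    elif u_substance < ctx.p_sub_stop:
        return "substance_abuse_stop"
    if not patient.employed:
        if u_employment < ctx.p_emp_gain and patient.mental_health > 50.0:
            return "employment_found"
    elif u_employment < ctx.p_emp_loss:
        return "employment_lost"
    return "none"


def draw_critical_outcomes(patient, cfg, rng=None, *, u_main=None,
                           u_substance=None, u_employment=None) -> CriticalOutcome:
    """Draw the week's critical outcome for a community patient.

    A crisis fires with the configured weekly probability for the patient's
    mental-health category; a crime (outside crisis) with the category's
    propensity; substance-abuse start/stop and employment gain/loss with
    their state-conditioned weekly probabilities.  When several fire, only
    the highest-priority one applies.
    """
    ctx = get_context(cfg)
    if u_main is None:
        u_main = rng.random()
    if u_substance is None:
        u_substance = rng.random()
    if u_employment is None:
        u_employment = rng.random()
    return CriticalOutcome(_critical_kind(patient, ctx, u_main, u_substance,
                                          u_employment))


def adherence_step(patient, chart: AdherenceChartConfig, context: dict):
    """One step of the medication-adherence state chart.

    ``context`` supplies the factor values the patient cannot carry alone:
    ``side_effect_severity`` and ``cost_to_patient_factor`` of the current
    medicine, ``lai_active`` and ``recent_provider_contact`` booleans.  The
    adherence score is the weighted sum of all chart factors; transitions use
    strict inequalities, and an active long-acting injectable suppresses the
    off-transition.  Returns the patient (mutated in place).
    """
    w = chart.factor_weights
    score = (w.get("stress", 0.0) * patient.stress
             + w.get("substance_abuse", 0.0) * (1.0 if patient.substance_abuse else 0.0)
             + w.get("side_effect_severity", 0.0) * context.get("side_effect_severity", 0.0)
             + w.get("cost_to_patient_factor", 0.0) * context.get("cost_to_patient_factor", 0)
             + w.get("family_support", 0.0) * patient.family_support
             + w.get("lai_active", 0.0) * (1.0 if context.get("lai_active") else 0.0)
             + w.get("recent_provider_contact", 0.0)
             * (1.0 if context.get("recent_provider_contact") else 0.0))
    patient.adherence_score = score
    if patient.on_medication:
        if score < chart.stop_threshold and not context.get("lai_active"):
            patient.on_medication = False
    elif score > chart.start_threshold:
        patient.on_medication = True
    return patient


def _mh_next(patient, dyn, env_mh_effect: float, contact: bool,
             noise: float) -> float:
    """Next mental-health score (scalar core of :func:`update_mental_health`)."""
    delta = env_mh_effect + noise
    if patient.on_medication:
        delta += dyn.medication_effect
    if contact:
        delta += dyn.contact_effect + patient.visit_mh_bonus
    elif not patient.on_medication:
        delta -= dyn.untreated_decline
    delta -= dyn.stress_weight * patient.stress
    delta += dyn.support_weight * patient.family_support
    delta += dyn.coupling_mh * (patient.physical_health - patient.mental_health) / 100.0
    score = patient.mental_health + delta
    if score < patient.mh_floor:
        return patient.mh_floor
    return 100.0 if score > 100.0 else score


def _ph_next(patient, dyn, env_ph_effect: float, side_severity: float) -> float:
    """Next physical-health score (scalar core of :func:`update_physical_health`)."""
    delta = patient.ph_decline_factor + env_ph_effect
    delta -= dyn.side_effect_ph_scale * side_severity
    delta += dyn.coupling_ph * (patient.mental_health - patient.physical_health) / 100.0
    score = patient.physical_health + delta
    if score < 1.0:
        return 1.0
    return 100.0 if score > 100.0 else score


def update_mental_health(patient, cfg, events, noise: float = 0.0) -> float:
    """New mental-health score from this week's influences (not yet stored).

    ``events`` is an iterable of event kinds; ``"provider_contact"`` marks a
    kept appointment or stabilization contact this week.  Untreated decline
    applies only when the patient is both off medication and had no provider
    contact.  The result is clamped to ``[mh_floor, 100]``.
    """
    ctx = get_context(cfg)
    env = ctx.envs[patient.environment_id]
    return _mh_next(patient, ctx.dyn, env.weekly_mh_effect,
                    "provider_contact" in events, noise)


def update_physical_health(patient, cfg, events) -> float:
    """New physical-health score: own drift, environment, medication side
    effects, and the pull toward the mental-health score.  Clamped to [1, 100]."""
    ctx = get_context(cfg)
    env = ctx.envs[patient.environment_id]
    severity = 0.0
    if patient.on_medication and patient.medicine_id is not None:
        severity = ctx.meds[patient.medicine_id].long_term_side_effect_severity
    return _ph_next(patient, ctx.dyn, env.weekly_ph_effect, severity)


def transition_environment(patient, cfg, rng=None, state: EcosystemState = None,
                           *, u=None) -> str:
    """Draw this week's environment transition for a community patient.

    The destination comes from the transition row for (current environment,
    mental-health category).  With shared state, a full destination redirects
    to its configured overflow environment; without state, the drawn
    destination is taken as-is.  Patients mid-stay in an episodic environment
    do not transition here (length-of-stay countdown governs).
    """
    ctx = get_context(cfg)
    if patient.environment_weeks_remaining is not None:
        return patient.environment_id
    if u is None:
        u = rng.random()
    cat = coarse_index(patient.mental_health)
    row = ctx.transition_cum.get((patient.environment_id, cat))
    if row is None:
        raise ConfigError(
            f"no transition row for environment {patient.environment_id!r}, "
            f"category index {cat}")
    dest = _pick(row, u)
    if dest == patient.environment_id:
        return dest
    if state is not None:
        return state.move(patient, dest)
    patient.environment_id = dest
    return dest


# ---------------------------------------------------------------------------
# The weekly update
# ---------------------------------------------------------------------------


def weekly_update(patient, cfg, services: EcosystemState, rng=None):
    """Apply one weekly tick to one patient; returns (patient, events).

    ``services`` is the shared :class:`EcosystemState` (capacities, occupancy,
    ledger, counters).  All randomness comes from ``rng`` (defaulting to the
    patient's own substream); exactly :data:`N_DRAWS` uniforms are consumed.
    """
    if not patient.alive:
        return patient, []
    ctx = get_context(cfg)
    state = services
    rr = (rng if rng is not None else patient.rng).random
    u = [rr() for _ in range(N_DRAWS)]
    events = []
    dyn = ctx.dyn
    patient.weeks_since_contact += 1
    patient.visit_mh_bonus = 0.0
    was_episodic = patient.environment_weeks_remaining is not None
    on_med_before = patient.on_medication

    # (1)+(2) critical outcomes; crisis resolved through the ecosystem
    if not was_episodic:
        kind = _critical_kind(patient, ctx, u[0], u[6], u[7])
        if kind == "crisis":
            res = resolve_crisis(patient, ctx, state, u_outcome=u[1], u_aux=u[2],
                                 u_degree=u[3], u_div=u[4], u_los=u[5])
            events.append(("crisis", res.outcome))
            if not patient.alive:
                return patient, events
        elif kind == "crime":
            state.wk["crimes"] += 1
            disp = process_arrest(patient, ctx, state, u_cit=u[2], u_degree=u[3],
                                  u_div=u[4], u_sentence=u[5], crisis_origin=False)
            events.append(("crime", disp))
        elif kind != "none":
            if kind == "substance_abuse_start":
                patient.substance_abuse = True
            elif kind == "substance_abuse_stop":
                patient.substance_abuse = False
            elif kind == "employment_found":
                patient.employed = True
            else:
                patient.employed = False
            events.append((kind, ""))

    in_facility = patient.environment_weeks_remaining is not None
    med_id = patient.medicine_id

    # (3) adherence state chart (community patients with a medicine in plan)
    if not in_facility and med_id is not None:
        lai_active = patient.lai_weeks_remaining > 0
        score = (ctx.med_adherence_static[med_id]
                 + ctx.w_stress * patient.stress
                 + ctx.w_support * patient.family_support)
        if patient.substance_abuse:
            score += ctx.w_substance
        if lai_active:
            score += ctx.w_lai
        if patient.weeks_since_contact <= ctx.contact_window:
            score += ctx.w_contact
        patient.adherence_score = score
        if patient.on_medication:
            if score < ctx.stop_threshold and not lai_active:
                patient.on_medication = False
        elif score > ctx.start_threshold:
            patient.on_medication = True

    # (4) appointment attendance (engaged community patients only)
    if not in_facility and not patient.lost_to_system:
        appts = ctx.plan_appts[patient.plan_id]
        slot = 8
        wk_id = state.week + patient.id
        for ptype, interval, offset in appts:
            if slot > 9:
                break
            if wk_id % interval == offset:
                attempt_appointment(patient, ptype, ctx, state,
                                    u_attend=u[slot], u_lai=u[10])
            slot += 1

    # (5) medication refill / weekly medication costs
    if patient.on_medication and med_id is not None:
        med = ctx.meds[med_id]
        if not in_facility:
            if patient.lai_weeks_remaining > 0:
                patient.lai_weeks_remaining -= 1
            elif (state.week % med.refill_frequency_weeks
                  == patient.id % med.refill_frequency_weeks):
                if patient.lost_to_system:
                    patient.on_medication = False  # prescription lapses
                elif u[11] >= access_factor(med.cost_to_patient_factor,
                                            patient.financial_resources, ctx.econ):
                    patient.on_medication = False
        if patient.on_medication:
            outlay = state.post_cost(patient.id, "medication_week", med.id,
                                     "medication", med.patient_cost_per_week,
                                     med.system_cost_per_week)
            if outlay:
                patient.financial_resources = max(
                    patient.financial_resources - outlay, 0.0)

    # (6) environment progression
    if was_episodic:
        patient.environment_weeks_remaining -= 1
        if patient.environment_weeks_remaining <= 0:
            if patient.environment_id == ctx.jail_id:
                release_from_jail(patient, ctx, state, u_location=u[12],
                                  u_handoff=u[13], u_med=u[4])
                events.append(("jail_release", patient.environment_id))
            else:
                _discharge_hospital(patient, ctx, state, u_loc=u[12],
                                    u_handoff=u[13])
                events.append(("hospital_discharge", patient.environment_id))
    elif patient.environment_weeks_remaining is None:
        if not patient.lost_to_system:
            if u[14] < dyn.plan_review_rate:
                # a provider-side plan change: the patient must be handed off
                state.wk["referrals"] += 1
                ok = refer_patient(patient, "community_mental_health_center",
                                   "community_mental_health_center", ctx, u=u[13])
                if not ok:
                    state.wk["handoff_failures"] += 1
                    events.append(("handoff_failure", "plan_review"))
        elif ctx.outreach > 0.0:
            located = ctx.located.get(patient.environment_id, 1.0)
            if u[14] < ctx.outreach * located:
                patient.lost_to_system = False
                patient.weeks_since_contact = 0
                state.wk["reengagements"] += 1
                events.append(("outreach_reengagement", ""))
        if patient.environment_weeks_remaining is None:
            row = ctx.transition_cum.get(
                (patient.environment_id, coarse_index(patient.mental_health)))
            if row is not None:
                dest = _pick(row, u[12])
                if dest != patient.environment_id:
                    state.move(patient, dest)

    # (7) health-score updates
    contact = patient.weeks_since_contact == 0
    noise = dyn.mh_noise_sd * (u[15] - 0.5) * _U12 if dyn.mh_noise_sd else 0.0
    env = ctx.envs[patient.environment_id]
    patient.mental_health = _mh_next(patient, dyn, env.weekly_mh_effect,
                                     contact, noise)
    severity = 0.0
    if patient.on_medication and patient.medicine_id is not None:
        severity = ctx.meds[patient.medicine_id].long_term_side_effect_severity
    patient.physical_health = _ph_next(patient, dyn, env.weekly_ph_effect,
                                       severity)

    # weekly environment costs (current environment at week end)
    if env.weekly_cost_third_party or env.weekly_cost_patient:
        outlay = state.post_cost(patient.id, "environment_week", env.id,
                                 env.cost_category, env.weekly_cost_patient,
                                 env.weekly_cost_third_party,
                                 crisis_origin=patient.crisis_origin_stay)
        if outlay:
            patient.financial_resources = max(
                patient.financial_resources - outlay, 0.0)

    # (8) income side of the finance update (costs were debited when posted)
    if patient.employed:
        patient.financial_resources += ctx.econ.employment_income_per_week

    if patient.on_medication != on_med_before:
        if patient.on_medication:
            state.wk["med_starts"] += 1
            events.append(("medication_start", ""))
        else:
            state.wk["med_stops"] += 1
            events.append(("medication_stop", ""))
        state.log(patient.id, events[-1][0])
    return patient, events


def _discharge_hospital(patient, ctx, state, *, u_loc, u_handoff) -> None:
    """Inpatient discharge: new plan, restart medication, refer to outpatient
    care (the handoff), then move to the drawn discharge location."""
    patient.environment_weeks_remaining = None
    patient.crisis_origin_stay = False
    patient.plan_id = ctx.plan_for(patient.diagnosis, ctx.initial_plan)
    patient.medicine_id = ctx.plans[patient.plan_id].medicine_id
    patient.on_medication = patient.medicine_id is not None
    state.wk["referrals"] += 1
    ok = refer_patient(patient, "hospital_inpatient",
                       "community_mental_health_center", ctx,
                       u=u_handoff, located_override=1.0)
    if not ok:
        state.wk["handoff_failures"] += 1
    if ctx.hospital_discharge_cum is not None:
        dest = _pick(ctx.hospital_discharge_cum, u_loc)
        state.move(patient, dest)
    state.log(patient.id, "hospital_discharge", patient.environment_id)
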