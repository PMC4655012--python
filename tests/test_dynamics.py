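"""The weekly per-patient update: critical outcomes, adherence, score updates,
environment transitions."""

import math
import random

import pytest

from spmi_ecosim.config import AdherenceChartConfig
from spmi_ecosim.dynamics import (adherence_step, draw_critical_outcomes,
                                  transition_environment, update_mental_health,
                                  update_physical_health, weekly_update)
from spmi_ecosim.ecosystem import EcosystemState, RunContext
from spmi_ecosim.population import synthesize_population


def make_state(cfg, population, record_events=False):
    ctx = RunContext(cfg)
    return ctx, EcosystemState(ctx, population, cfg.system.run_length_weeks,
                               record_events=record_events)


def snapshot(p):
    return (p.mental_health, p.physical_health, p.environment_id,
            p.on_medication, p.substance_abuse, p.employed,
            p.financial_resources, p.lost_to_system, p.alive)


class TestWeeklyUpdate:
    def test_frozen_dynamics_is_fixed_point(self, frozen_cfg):
        pop = synthesize_population(frozen_cfg, 3)
        ctx, state = make_state(frozen_cfg, pop)
        before = [snapshot(p) for p in pop]
        for p in pop:
            weekly_update(p, ctx, state)
        assert [snapshot(p) for p in pop] == before

    def test_deterministic_given_rng(self, small_cfg):
        results = []
        for _ in range(2):
            pop = synthesize_population(small_cfg, 21)
            ctx, state = make_state(small_cfg, pop)
            for p in pop:
                weekly_update(p, ctx, state)
            results.append([snapshot(p) for p in pop])
        assert results[0] == results[1]

    def test_forced_crisis_emits_one_crisis_event(self, frozen_cfg):
        frozen_cfg.patients.crisis_onset_probability = {
            c: 1.0 for c in ("severe", "serious", "moderate", "mild")}
        pop = synthesize_population(frozen_cfg, 3)
        ctx, state = make_state(frozen_cfg, pop)
        _, events = weekly_update(pop[0], ctx, state)
        assert [kind for kind, _ in events] == ["crisis"]
        assert state.wk["crises"] == 1


class TestCriticalOutcomes:
    def test_all_rates_zero_gives_none(self, frozen_cfg):
        pop = synthesize_population(frozen_cfg, 1)
        RunContext(frozen_cfg)
        out = draw_critical_outcomes(pop[0], frozen_cfg, random.Random(1))
        assert out.kind == "none"

    def test_certain_crisis_takes_priority(self, frozen_cfg):
        frozen_cfg.patients.crisis_onset_probability = {
            c: 1.0 for c in ("severe", "serious", "moderate", "mild")}
        frozen_cfg.patients.substance_start_probability = 1.0
        pop = synthesize_population(frozen_cfg, 2)
        for _ in range(20):
            assert draw_critical_outcomes(pop[0], frozen_cfg,
                                          random.Random(3)).kind == "crisis"

    def test_crisis_frequency_binomial(self, frozen_cfg):
        """Empirical crisis frequency within 3 SE of the configured rate."""
        p_crisis = 0.07
        frozen_cfg.patients.crisis_onset_probability = {
            c: p_crisis for c in ("severe", "serious", "moderate", "mild")}
        pop = synthesize_population(frozen_cfg, 4)
        rng = random.Random(99)
        n = 10_000
        hits = sum(draw_critical_outcomes(pop[0], frozen_cfg, rng).kind == "crisis"
                   for _ in range(n))
        se = math.sqrt(p_crisis * (1 - p_crisis) / n)
        assert abs(hits / n - p_crisis) < 3 * se

    def test_contact_protection_scales_crisis_rate(self, frozen_cfg):
        p_crisis = 0.10
        frozen_cfg.patients.crisis_onset_probability = {
            c: p_crisis for c in ("severe", "serious", "moderate", "mild")}
        frozen_cfg.dynamics.crisis_protection_contact = 0.5
        pop = synthesize_population(frozen_cfg, 4)
        patient = pop[0]
        patient.weeks_since_contact = 1  # recent contact: protected
        rng = random.Random(17)
        n = 10_000
        hits = sum(draw_critical_outcomes(patient, frozen_cfg, rng).kind == "crisis"
                   for _ in range(n))
        expected = p_crisis * 0.5
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se


class TestAdherenceChart:
    chart = AdherenceChartConfig()  # package defaults mirror the shipped chart

    def context(self, **kw):
        base = {"side_effect_severity": 0.25, "cost_to_patient_factor": 2,
                "lai_active": False, "recent_provider_contact": False}
        base.update(kw)
        return base

    def make_patient(self, frozen, **fields):
        pop = synthesize_population(frozen, 1)
        p = pop[0]
        p.medicine_id = "m"
        for k, v in fields.items():
            setattr(p, k, v)
        return p

    def test_neutral_score_no_transition(self, frozen_cfg):
        chart = AdherenceChartConfig(
            factor_weights={k: 1.0 for k in self.chart.factor_weights},
            stop_threshold=-1.0, start_threshold=1.0)
        p = self.make_patient(frozen_cfg, stress=0.0, family_support=0.0,
                              substance_abuse=False, on_medication=True)
        adherence_step(p, chart, {"side_effect_severity": 0.0,
                                  "cost_to_patient_factor": 0,
                                  "lai_active": False,
                                  "recent_provider_contact": False})
        assert p.adherence_score == 0.0
        assert p.on_medication

    def test_stressed_substance_user_stops(self, frozen_cfg):
        """With the default weights, maximal stress plus substance abuse and
        no support pushes the score below the stop threshold."""
        p = self.make_patient(frozen_cfg, stress=1.0, substance_abuse=True,
                              family_support=0.0, on_medication=True)
        score = (self.chart.factor_weights["stress"] * 1.0
                 + self.chart.factor_weights["substance_abuse"]
                 + self.chart.factor_weights["side_effect_severity"] * 0.25
                 + self.chart.factor_weights["cost_to_patient_factor"] * 2)
        assert score < self.chart.stop_threshold  # sanity on the arithmetic
        adherence_step(p, self.chart, self.context())
        assert not p.on_medication
        assert p.adherence_score == pytest.approx(score)

    def test_boundary_score_stays_off(self, frozen_cfg):
        """Transitions are strict: a score exactly at start_threshold stays off."""
        chart = AdherenceChartConfig(
            factor_weights={**{k: 0.0 for k in self.chart.factor_weights},
                            "family_support": 1.0},
            stop_threshold=-1.0, start_threshold=0.5)
        p = self.make_patient(frozen_cfg, family_support=0.5,
                              on_medication=False)
        adherence_step(p, chart, self.context())
        assert p.adherence_score == 0.5
        assert not p.on_medication

    def test_lai_suppresses_stop(self, frozen_cfg):
        p = self.make_patient(frozen_cfg, stress=1.0, substance_abuse=True,
                              family_support=0.0, on_medication=True)
        adherence_step(p, self.chart, self.context(lai_active=True))
        assert p.on_medication


class TestScoreUpdates:
    def test_all_deltas_zero_identity(self, frozen_cfg):
        pop = synthesize_population(frozen_cfg, 2)
        p = pop[0]
        assert update_mental_health(p, frozen_cfg, ()) == p.mental_health
        assert update_physical_health(p, frozen_cfg, ()) == p.physical_health

    def test_floor_clamps_large_shock(self, frozen_cfg):
        frozen_cfg.dynamics.untreated_decline = 500.0
        pop = synthesize_population(frozen_cfg, 2)
        p = pop[0]
        p.on_medication = False
        assert update_mental_health(p, frozen_cfg, ()) == p.mh_floor

    def test_untreated_decline_monotone_to_floor(self, frozen_cfg):
        """k weeks untreated follow the closed-form linear decline until the
        floor is reached, never dipping below it."""
        decline = 1.5
        frozen_cfg.dynamics.untreated_decline = decline
        pop = synthesize_population(frozen_cfg, 2)
        p = pop[0]
        p.on_medication = False
        start = p.mental_health
        for k in range(1, 30):
            p.mental_health = update_mental_health(p, frozen_cfg, ())
            assert p.mental_health == pytest.approx(
                max(start - k * decline, p.mh_floor))
        assert p.mental_health == p.mh_floor

    def test_long_term_side_effects_lower_physical_health(self, default_cfg):
        pop = synthesize_population(default_cfg, 3)
        p = pop[0]
        p.environment_id = "private_residence"
        p.ph_decline_factor = 0.0
        p.on_medication = True
        p.mental_health = p.physical_health  # neutralise the coupling pull
        cfg = default_cfg.copy()
        cfg.dynamics.coupling_ph = 0.0
        assert update_physical_health(p, cfg, ()) < p.physical_health

    def test_mental_physical_coupling_sign(self, frozen_cfg):
        frozen_cfg.dynamics.coupling_ph = 1.0
        pop = synthesize_population(frozen_cfg, 2)
        low, high = pop[0], pop[1]
        low.mental_health, high.mental_health = 20.0, 80.0
        low.physical_health = high.physical_health = 50.0
        assert update_physical_health(high, frozen_cfg, ()) > \
            update_physical_health(low, frozen_cfg, ())

    def test_scores_always_in_bounds(self, small_cfg):
        pop = synthesize_population(small_cfg, 77)
        ctx, state = make_state(small_cfg, pop)
        for week in range(30):
            state.reset_week(week)
            for p in pop:
                if p.alive:
                    weekly_update(p, ctx, state)
                    assert p.mh_floor <= p.mental_health <= 100.0
                    assert 1.0 <= p.physical_health <= 100.0


class TestEnvironmentTransitions:
    def test_absorbing_row_stays(self, frozen_cfg):
        pop = synthesize_population(frozen_cfg, 2)
        p = pop[0]
        assert transition_environment(p, frozen_cfg, random.Random(5)) == \
            "private_residence"

    def test_mid_stay_never_transitions(self, frozen_cfg):
        pop = synthesize_population(frozen_cfg, 2)
        p = pop[0]
        p.environment_id = "hospital_inpatient"
        p.environment_weeks_remaining = 3
        assert transition_environment(p, frozen_cfg, random.Random(5)) == \
            "hospital_inpatient"

    def test_full_destination_overflows(self, frozen_cfg):
        frozen_cfg.environment("private_residence").transition_matrix = {
            c: {"homeless": 1.0} for c in ("severe", "serious", "moderate", "mild")}
        frozen_cfg.environment("homeless").capacity = 0
        frozen_cfg.environment("homeless").overflow_environment_id = \
            "private_residence"
        frozen_cfg.environment("homeless").transition_matrix = {
            c: {"homeless": 1.0} for c in ("severe", "serious", "moderate", "mild")}
        pop = synthesize_population(frozen_cfg, 2)
        ctx, state = make_state(frozen_cfg, pop)
        p = pop[0]
        dest = transition_environment(p, ctx, random.Random(5), state=state)
        assert dest == "private_residence"  # bounced back off the full shelter

    def test_destination_frequencies_multinomial(self, frozen_cfg):
        row = {"private_residence": 0.5, "homeless": 0.3, "hospital_inpatient": 0.2}
        frozen_cfg.environment("private_residence").transition_matrix = {
            c: dict(row) for c in ("severe", "serious", "moderate", "mild")}
        pop = synthesize_population(frozen_cfg, 2)
        rng = random.Random(31)
        n = 10_000
        counts = {k: 0 for k in row}
        for _ in range(n):
            p = pop[0]
            p.environment_id = "private_residence"
            p.environment_weeks_remaining = None
            counts[transition_environment(p, frozen_cfg, rng)] += 1
        for dest, prob in row.items():
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(counts[dest] / n - prob) < 3 * se, dest
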