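"""Shared-capacity appointments, referral handoffs, crisis resolution and the
criminal-justice pathway."""

import math
import random

import pytest

from spmi_ecosim.config import ConfigError, Distribution
from spmi_ecosim.ecosystem import (EcosystemState, RunContext,
                                   attempt_appointment, process_arrest,
                                   refer_patient, release_from_jail,
                                   resolve_crisis)
from spmi_ecosim.population import synthesize_population


def make_state(cfg, n_pop=5, record_events=False):
    pop = synthesize_population(cfg, 13)
    ctx = RunContext(cfg)
    state = EcosystemState(ctx, pop, cfg.system.run_length_weeks,
                           record_events=record_events)
    return pop, ctx, state


class TestAppointments:
    def prepare(self, frozen_cfg, capacity, compliance=1.0):
        prov = frozen_cfg.provider_by_type("community_mental_health_center")
        prov.count = 1
        prov.capacity_per_week = capacity
        frozen_cfg.levers.patient_appointment_compliance_rate = compliance
        frozen_cfg.patients.population_size = 25
        return make_state(frozen_cfg)

    def test_zero_compliance_never_attends(self, frozen_cfg):
        pop, ctx, state = self.prepare(frozen_cfg, capacity=50, compliance=0.0)
        rng = random.Random(2)
        assert not any(
            attempt_appointment(p, "community_mental_health_center", ctx, state, rng)
            for p in pop)
        assert state.wk["kept"] == 0
        assert state.wk["scheduled"] == len(pop)

    def test_certain_attendance_with_capacity(self, frozen_cfg):
        pop, ctx, state = self.prepare(frozen_cfg, capacity=50, compliance=1.0)
        rng = random.Random(2)
        kept = sum(
            attempt_appointment(p, "community_mental_health_center", ctx, state, rng)
            for p in pop)
        assert kept == len(pop)  # free service, full compliance, ample capacity
        assert all(p.weeks_since_contact == 0 for p in pop)

    def test_capacity_caps_attendance(self, frozen_cfg):
        """20 fully compliant patients against 5 weekly slots: exactly 5 attend."""
        pop, ctx, state = self.prepare(frozen_cfg, capacity=5, compliance=1.0)
        rng = random.Random(2)
        kept = sum(
            attempt_appointment(p, "community_mental_health_center", ctx, state, rng)
            for p in pop[:20])
        assert kept == 5
        assert state.capacity_left["community_mental_health_center"] == 0

    def test_unknown_provider_type_rejected(self, frozen_cfg):
        pop, ctx, state = self.prepare(frozen_cfg, capacity=5)
        with pytest.raises(ConfigError):
            attempt_appointment(pop[0], "chiropractor", ctx, state,
                                random.Random(1))


class TestReferrals:
    def test_certain_handoff_succeeds(self, frozen_cfg):
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        assert refer_patient(p, "a", "b", ctx, random.Random(1))
        assert not p.lost_to_system

    def test_zero_handoff_loses_patient(self, frozen_cfg):
        frozen_cfg.levers.handoff_success_rate = 0.0
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        assert not refer_patient(p, "a", "b", ctx, random.Random(1))
        assert p.lost_to_system

    def test_success_frequency_binomial(self, frozen_cfg):
        rate = 0.6
        frozen_cfg.levers.handoff_success_rate = rate
        pop, ctx, state = make_state(frozen_cfg)
        rng = random.Random(77)
        n = 10_000
        hits = sum(refer_patient(pop[0], "a", "b", ctx, rng,
                                 located_override=1.0) for _ in range(n))
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(hits / n - rate) < 3 * se

    def test_located_probability_multiplies(self, frozen_cfg):
        frozen_cfg.levers.handoff_success_rate = 0.8
        frozen_cfg.environment("homeless").probability_of_being_located = 0.5
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        p.environment_id = "homeless"
        rng = random.Random(5)
        n = 10_000
        hits = sum(refer_patient(p, "a", "b", ctx, rng) for _ in range(n))
        expected = 0.8 * 0.5
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se


class TestCrisisResolution:
    def point_mass(self, frozen_cfg, outcome):
        frozen_cfg.patients.crisis_outcome_probabilities = {
            "engaged": {outcome: 1.0}, "lost": {outcome: 1.0}}

    def test_stabilized_keeps_environment(self, frozen_cfg):
        self.point_mass(frozen_cfg, "stabilized")
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        res = resolve_crisis(p, ctx, state, random.Random(3))
        assert res.outcome == "stabilized"
        assert p.environment_id == "private_residence"
        assert p.weeks_since_contact == 0

    def test_suicide_removes_patient(self, frozen_cfg):
        self.point_mass(frozen_cfg, "suicide")
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        before = state.occupancy["private_residence"]
        res = resolve_crisis(p, ctx, state, random.Random(3))
        assert res.outcome == "suicide"
        assert not p.alive
        assert state.occupancy["private_residence"] == before - 1

    def test_hospitalization_admits_with_length_of_stay(self, frozen_cfg):
        self.point_mass(frozen_cfg, "hospitalization")
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        resolve_crisis(p, ctx, state, random.Random(3))
        assert p.environment_id == "hospital_inpatient"
        assert p.environment_weeks_remaining == 2
        assert p.crisis_origin_stay

    def test_full_hospital_stabilizes_instead(self, frozen_cfg):
        self.point_mass(frozen_cfg, "hospitalization")
        frozen_cfg.environment("hospital_inpatient").capacity = 0
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        res = resolve_crisis(p, ctx, state, random.Random(3))
        assert res.outcome == "stabilized"
        assert p.environment_id == "private_residence"

    def test_crisis_shock_respects_floor(self, frozen_cfg):
        self.point_mass(frozen_cfg, "stabilized")
        frozen_cfg.dynamics.crisis_mh_shock = 500.0
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        resolve_crisis(p, ctx, state, random.Random(3))
        assert p.mental_health == p.mh_floor

    def test_outcome_mix_multinomial(self, frozen_cfg):
        mix = {"hospitalization": 0.4, "arrest": 0.2, "homelessness": 0.1,
               "stabilized": 0.25, "suicide": 0.05}
        frozen_cfg.patients.crisis_outcome_probabilities = {
            "engaged": mix, "lost": mix}
        pop, ctx, state = make_state(frozen_cfg)
        rng = random.Random(41)
        n = 10_000
        counts = dict.fromkeys(mix, 0)
        for _ in range(n):
            p = pop[1]
            p.alive = True
            p.environment_id = "private_residence"
            p.environment_weeks_remaining = None
            counts[resolve_crisis(p, ctx, state, rng).outcome] += 1
            state.occupancy = {eid: 0 for eid in ctx.envs}  # reset side effects
        for outcome, prob in mix.items():
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(counts[outcome] / n - prob) < 3 * se, outcome


class TestJusticePathway:
    def test_cit_officer_always_redirects(self, frozen_cfg):
        frozen_cfg.justice.cit_officer_probability = 1.0
        pop, ctx, state = make_state(frozen_cfg)
        for p in pop:
            assert process_arrest(p, ctx, state, random.Random(p.id)) == \
                "cit_redirect"
            assert p.environment_id != "correctional_facility"

    def test_deterministic_sentence(self, frozen_cfg):
        frozen_cfg.justice.sentence_weeks_by_degree["misdemeanor"] = \
            Distribution(kind="discrete_uniform", low=12, high=12)
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        assert process_arrest(p, ctx, state, random.Random(1)) == "incarcerated"
        assert p.environment_id == "correctional_facility"
        assert p.environment_weeks_remaining == 12
        assert not p.employed

    def test_branch_frequencies_match_probability_tree(self, frozen_cfg):
        jus = frozen_cfg.justice
        jus.cit_officer_probability = 0.3
        jus.crime_degree_distribution = Distribution.categorical(
            {"misdemeanor": 0.7, "felony": 0.3})
        jus.sentence_weeks_by_degree["felony"] = Distribution(
            kind="discrete_uniform", low=5, high=5)
        jus.jail_diversion_entry_probability = 0.4
        pop, ctx, state = make_state(frozen_cfg)
        rng = random.Random(8)
        n = 10_000
        counts = {"cit_redirect": 0, "diversion": 0, "incarcerated": 0}
        for _ in range(n):
            p = pop[2]
            p.environment_id = "private_residence"
            p.environment_weeks_remaining = None
            p.in_jail_diversion = False
            counts[process_arrest(p, ctx, state, rng)] += 1
            state.occupancy = {eid: 0 for eid in ctx.envs}
        expected = {
            "cit_redirect": 0.3,
            "diversion": 0.7 * 0.7 * 0.4,          # no CIT, misdemeanor, diverted
            "incarcerated": 0.7 * (0.3 + 0.7 * 0.6),
        }
        for branch, prob in expected.items():
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(counts[branch] / n - prob) < 3 * se, branch

    def test_release_point_mass_location_and_plan(self, frozen_cfg):
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        p.environment_id = "correctional_facility"
        state.occupancy = {eid: 0 for eid in ctx.envs}
        state.occupancy["correctional_facility"] = 1
        release_from_jail(p, ctx, state, random.Random(4))
        assert p.environment_id == "private_residence"
        assert p.plan_id == "bare"
        assert p.released_before

    def test_failed_release_handoff_loses_patient(self, frozen_cfg):
        frozen_cfg.levers.handoff_success_rate = 0.0
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        p.environment_id = "correctional_facility"
        state.occupancy = {eid: 0 for eid in ctx.envs}
        state.occupancy["correctional_facility"] = 1
        release_from_jail(p, ctx, state, random.Random(4))
        assert p.lost_to_system

    def test_rearrest_after_release_counts_as_recidivism(self, frozen_cfg):
        pop, ctx, state = make_state(frozen_cfg)
        p = pop[0]
        assert process_arrest(p, ctx, state, random.Random(1)) == "incarcerated"
        assert state.recidivist_arrests == 0
        release_from_jail(p, ctx, state, random.Random(2))
        process_arrest(p, ctx, state, random.Random(3))
        assert state.recidivist_arrests == 1


class TestCapacityConservation:
    def test_weekly_attendance_never_exceeds_capacity(self, small_cfg):
        from spmi_ecosim.engine import run_simulation
        result = run_simulation(small_cfg, 3)
        ctx = RunContext(small_cfg)
        for ptype, cap in ctx.weekly_capacity.items():
            col = f"util_{ptype}"
            if col in result.metrics:
                assert (result.metrics[col] <= 1.0 + 1e-12).all()
        assert (result.metrics["kept"] <=
                sum(ctx.weekly_capacity.values())).all()
        assert (result.metrics["kept"] + result.metrics["missed"] ==
                result.metrics["scheduled"]).all()
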