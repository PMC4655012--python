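"""Shared fixtures: the shipped profile and small programmatic test configs."""

from __future__ import annotations

import pytest

from spmi_ecosim.config import (AdherenceChartConfig, AppointmentConfig,
                                Distribution, DynamicsConfig, EconomicsConfig,
                                EnvironmentConfig, JusticeConfig,
                                MedicineConfig, ModelConfig,
                                PatientPopulationConfig, ProviderConfig,
                                SystemConfig, SystemLeversConfig,
                                TreatmentPlanConfig, load_default_profile,
                                validate_config)


@pytest.fixture(scope="session")
def default_cfg() -> ModelConfig:
    cfg = load_default_profile()
    assert validate_config(cfg) == []
    return cfg


def small_config(default: ModelConfig, population=150, weeks=52) -> ModelConfig:
    """The shipped profile scaled down for fast tests (capacities follow)."""
    cfg = default.copy()
    factor = population / cfg.patients.population_size
    cfg.patients.population_size = population
    cfg.system.run_length_weeks = weeks
    for prov in cfg.providers:
        prov.count = max(int(round(prov.count * factor)), 1)
    for env in cfg.environments:
        if env.capacity is not None:
            env.capacity = max(int(round(env.capacity * factor)), 1)
    return cfg


@pytest.fixture()
def small_cfg(default_cfg) -> ModelConfig:
    return small_config(default_cfg)


def frozen_config(population=50, weeks=52, **overrides) -> ModelConfig:
    """A fully frozen ecosystem: every stochastic rate and score delta is zero,
    transition rows are absorbing, and no plan carries a medicine.  The
    population state is a fixed point of the weekly update."""
    point0 = Distribution.point(0.0)
    cfg = ModelConfig(
        system=SystemConfig(run_length_weeks=weeks, seed=7, n_replications=3),
        patients=PatientPopulationConfig(
            population_size=population,
            age_bands=Distribution.categorical({"30-44": 1.0}),
            diagnoses=Distribution.categorical({"schizophrenia": 1.0}),
            initial_mental_health=Distribution.point(60.0),
            mh_floor_offset=Distribution.point(20.0),
            initial_physical_health=Distribution.point(60.0),
            ph_decline_factor=point0,
            family_support=Distribution.point(0.5),
            stress=Distribution.point(0.5),
            initial_financial_resources=Distribution.point(500.0),
            initial_environment=Distribution.categorical(
                {"private_residence": 1.0}),
            initial_treatment_plan={"schizophrenia": "bare"},
            substance_abuse_rate=0.0,
            employment_rate=0.0,
            initial_on_medication=0.0,
            propensity_to_commit_crime={c: 0.0 for c in
                                        ("severe", "serious", "moderate", "mild")},
            crisis_onset_probability={c: 0.0 for c in
                                      ("severe", "serious", "moderate", "mild")},
            crisis_outcome_probabilities={
                "engaged": {"stabilized": 1.0}, "lost": {"stabilized": 1.0}},
            substance_start_probability=0.0,
            substance_stop_probability=0.0,
            employment_gain_probability=0.0,
            employment_loss_probability=0.0,
        ),
        medicines=[],
        providers=[
            ProviderConfig(id="cmhc", provider_type="community_mental_health_center",
                           count=1, capacity_per_week=0),
            ProviderConfig(id="csu", provider_type="crisis_stabilization_unit",
                           count=1, capacity_per_week=0),
        ],
        treatment_plans=[
            TreatmentPlanConfig(id="bare", medicine_id=None, appointments=[],
                                designated_environment_id="private_residence"),
        ],
        environments=[
            EnvironmentConfig(
                id="private_residence", name="home", stability_flag=True,
                transition_matrix={c: {"private_residence": 1.0} for c in
                                   ("severe", "serious", "moderate", "mild")},
            ),
            EnvironmentConfig(
                id="homeless", name="street", stability_flag=False,
                transition_matrix={c: {"homeless": 1.0} for c in
                                   ("severe", "serious", "moderate", "mild")},
            ),
            EnvironmentConfig(
                id="hospital_inpatient", name="hospital", stability_flag=False,
                length_of_stay=Distribution(kind="discrete_uniform", low=2, high=2),
                cost_category="hospitalization",
                discharge_location={"private_residence": 1.0},
            ),
            EnvironmentConfig(
                id="correctional_facility", name="jail", stability_flag=False,
                length_of_stay=Distribution(kind="discrete_uniform", low=2, high=2),
                cost_category="incarceration",
            ),
        ],
        justice=JusticeConfig(
            initial_criminal_history=Distribution.categorical({"none": 1.0}),
            cit_officer_probability=0.0,
            crime_degree_distribution=Distribution.categorical(
                {"misdemeanor": 1.0}),
            sentence_weeks_by_degree={
                "misdemeanor": Distribution(kind="discrete_uniform", low=2, high=2)},
            jail_diversion_entry_probability=0.0,
            diversion_eligible_degrees=["misdemeanor"],
            discharge_location_distribution=Distribution.categorical(
                {"private_residence": 1.0}),
            discharge_plan_rule={"default": "bare"},
            release_on_medication_probability=0.0,
        ),
        economics=EconomicsConfig(employment_income_per_week=0.0,
                                  stabilization_cost_third_party=0.0,
                                  stabilization_cost_patient=0.0),
        levers=SystemLeversConfig(handoff_success_rate=1.0,
                                  patient_appointment_compliance_rate=0.45),
        adherence_chart=AdherenceChartConfig(
            factor_weights={k: 0.0 for k in (
                "stress", "substance_abuse", "side_effect_severity",
                "cost_to_patient_factor", "family_support", "lai_active",
                "recent_provider_contact")},
            stop_threshold=-1.0, start_threshold=1.0),
        dynamics=DynamicsConfig(
            medication_effect=0.0, contact_effect=0.0, untreated_decline=0.0,
            stress_weight=0.0, support_weight=0.0, coupling_mh=0.0,
            coupling_ph=0.0, side_effect_ph_scale=0.0, crisis_mh_shock=0.0,
            mh_noise_sd=0.0, crisis_protection_contact=0.0,
            plan_review_rate=0.0),
    )
    for path, value in overrides.items():
        node = cfg
        parts = path.split(".")
        for part in parts[:-1]:
            node = getattr(node, part)
        setattr(node, parts[-1], value)
    assert validate_config(cfg) == []
    return cfg


@pytest.fixture()
def frozen_cfg() -> ModelConfig:
    return frozen_config()
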