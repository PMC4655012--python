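"""Input-parameter schema for the care-ecosystem simulation.

The simulation is controlled entirely by a structured YAML profile grouped the
way the model's inputs are organised: system run controls, the patient
population and its initial-state distributions, treatment plans and medicines,
care providers, physical environments, law enforcement / criminal justice, and
the system-level levers (handoff success, appointment compliance, funding).

A profile is loaded into a :class:`ModelConfig`, a tree of frozen-ish
dataclasses.  Validation is non-raising at the core: :func:`validate_config`
returns a list of :class:`Violation` records (field path, observed value,
constraint), and :func:`load_config` raises only after collecting them all.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import math
import typing
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Optional

import yaml

__all__ = [
    "ConfigError",
    "ConfigFormatError",
    "ConfigValidationError",
    "Violation",
    "Distribution",
    "SystemConfig",
    "AdherenceChartConfig",
    "DynamicsConfig",
    "PatientPopulationConfig",
    "MedicineConfig",
    "ProviderConfig",
    "AppointmentConfig",
    "TreatmentPlanConfig",
    "EnvironmentConfig",
    "JusticeConfig",
    "EconomicsConfig",
    "SystemLeversConfig",
    "ModelConfig",
    "load_config",
    "save_config",
    "validate_config",
    "apply_funding_level",
    "config_hash",
    "default_profile_path",
    "load_default_profile",
    "MH_CATEGORIES",
]

#: Coarse mental-health reporting categories, most to least severe.
MH_CATEGORIES = ("severe", "serious", "moderate", "mild")

_PROB_SUM_TOL = 1e-9


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFormatError(ConfigError):
    """The profile file could not be parsed or has a malformed field."""


class ConfigValidationError(ConfigError):
    """A parsed profile violates one or more schema invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "\n".join(f"  - {v}" for v in violations)
        super().__init__(f"{len(violations)} configuration violation(s):\n{lines}")


@dataclass(frozen=True)
class Violation:
    """One validation failure: where, what was seen, what was expected."""

    path: str
    value: object
    constraint: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path} = {self.value!r}: expected {self.constraint}"


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """A small family of sampling distributions used throughout the profile.

    Kinds: ``point`` (value), ``uniform`` (low, high), ``truncnormal``
    (mean, sd, low, high; sampled by clipping a Gaussian draw),
    ``discrete_uniform`` (integer low..high inclusive) and ``categorical``
    (probs: mapping of label -> probability).
    """

    kind: str
    value: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    probs: Optional[dict] = None

    @staticmethod
    def point(value: float) -> "Distribution":
        return Distribution(kind="point", value=value)

    @staticmethod
    def categorical(probs: dict) -> "Distribution":
        return Distribution(kind="categorical", probs=dict(probs))

    @staticmethod
    def from_dict(data: dict, path: str = "distribution") -> "Distribution":
        if not isinstance(data, dict) or "kind" not in data:
            raise ConfigFormatError(f"{path}: expected a mapping with a 'kind' key")
        kind = data["kind"]
        known = {"point", "uniform", "truncnormal", "discrete_uniform", "categorical"}
        if kind not in known:
            raise ConfigFormatError(f"{path}.kind = {kind!r}: expected one of {sorted(known)}")
        fields = {k: v for k, v in data.items() if k != "kind"}
        try:
            return Distribution(kind=kind, **fields)
        except TypeError as exc:
            raise ConfigFormatError(f"{path}: {exc}") from None

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind}
        for name in ("value", "low", "high", "mean", "sd", "probs"):
            v = getattr(self, name)
            if v is not None:
                out[name] = copy.deepcopy(v) if isinstance(v, dict) else v
        return out

    # -- sampling -----------------------------------------------------------

    def sample(self, rng) -> object:
        """Draw one value using ``rng`` (a ``random.Random``)."""
        k = self.kind
        if k == "point":
            return self.value
        if k == "uniform":
            return self.low + (self.high - self.low) * rng.random()
        if k == "truncnormal":
            x = rng.gauss(self.mean, self.sd)
            return min(max(x, self.low), self.high)
        if k == "discrete_uniform":
            lo, hi = int(self.low), int(self.high)
            return lo + int(rng.random() * (hi - lo + 1))
        if k == "categorical":
            return self.sample_u(rng.random())
        raise ConfigError(f"unknown distribution kind {k!r}")

    def sample_u(self, u: float) -> object:
        """Inverse-CDF draw from a single uniform in [0, 1)."""
        k = self.kind
        if k == "categorical":
            acc = 0.0
            items = list(self.probs.items())
            for label, p in items:
                acc += p
                if u < acc:
                    return label
            return items[-1][0]
        if k == "point":
            return self.value
        if k == "uniform":
            return self.low + (self.high - self.low) * u
        if k == "discrete_uniform":
            lo, hi = int(self.low), int(self.high)
            return min(lo + int(u * (hi - lo + 1)), hi)
        if k == "truncnormal":
            raise ConfigError("truncnormal has no single-uniform inverse; use sample()")
        raise ConfigError(f"unknown distribution kind {k!r}")

    def mean_value(self) -> float:
        """Analytic mean for the numeric kinds (truncation ignored)."""
        k = self.kind
        if k == "point":
            return float(self.value)
        if k in ("uniform", "discrete_uniform"):
            return (self.low + self.high) / 2.0
        if k == "truncnormal":
            return float(self.mean)
        raise ConfigError(f"no scalar mean for kind {k!r}")

    def validate_into(self, path: str, out: list) -> None:
        k = self.kind
        if k == "point" and self.value is None:
            out.append(Violation(f"{path}.value", None, "a numeric value"))
        if k in ("uniform", "discrete_uniform", "truncnormal"):
            if self.low is None or self.high is None or self.low > self.high:
                out.append(Violation(f"{path}", (self.low, self.high), "low <= high"))
        if k == "truncnormal" and (self.sd is None or self.sd < 0):
            out.append(Violation(f"{path}.sd", self.sd, "sd >= 0"))
        if k == "categorical":
            if not self.probs:
                out.append(Violation(f"{path}.probs", self.probs, "a non-empty mapping"))
                return
            total = 0.0
            for label, p in self.probs.items():
                if not (0.0 <= p <= 1.0):
                    out.append(Violation(f"{path}.probs[{label}]", p, "probability in [0, 1]"))
                total += p
            if abs(total - 1.0) > _PROB_SUM_TOL:
                out.append(Violation(f"{path}.probs", total, "probabilities summing to 1"))


# ---------------------------------------------------------------------------
# Config groups
# ---------------------------------------------------------------------------


@dataclass
class SystemConfig:
    """Run controls: tick count, calendar metadata, seeding, replication."""

    run_length_weeks: int = 260
    start_date: str = "2015-01-05"
    seed: int = 20150105
    n_replications: int = 30


@dataclass
class AdherenceChartConfig:
    """Medication-adherence state chart: factor weights and thresholds.

    The adherence score is a signed weighted sum of patient/plan factors; an
    on-medication patient stops when the score falls strictly below
    ``stop_threshold`` and an off-medication patient (re)starts when it rises
    strictly above ``start_threshold`` (hysteresis permitted,
    stop <= start).  An active long-acting injectable suppresses the
    off-transition until the injection interval lapses.
    """

    factor_weights: dict = field(
        default_factory=lambda: {
            "stress": -1.4,
            "substance_abuse": -1.8,
            "side_effect_severity": -1.0,
            "cost_to_patient_factor": -0.15,
            "family_support": 1.2,
            "lai_active": 1.0,
            "recent_provider_contact": 1.3,
        }
    )
    stop_threshold: float = -1.05
    start_threshold: float = 0.0
    contact_recent_weeks: int = 4


@dataclass
class DynamicsConfig:
    """Magnitudes for the weekly health-score updates (profile-calibrated).

    All values are per-week score deltas on the 1-100 scales unless noted.
    ``coupling_mh``/``coupling_ph`` scale the cross-pull terms
    ``coupling * (other - self) / 100`` linking the two scores.
    """

    medication_effect: float = 0.55
    contact_effect: float = 0.55
    untreated_decline: float = 0.85
    stress_weight: float = 0.8
    support_weight: float = 0.5
    coupling_mh: float = 1.2
    coupling_ph: float = 1.0
    side_effect_ph_scale: float = 0.3
    crisis_mh_shock: float = 9.0
    mh_noise_sd: float = 0.8
    #: relative reduction of the weekly crisis-onset probability while the
    #: patient has had provider contact within the adherence chart's recency
    #: window (active treatment intercepts decompensation before it becomes
    #: a crisis)
    crisis_protection_contact: float = 0.40
    #: weekly probability that a provider reviews/changes the plan, which
    #: requires a referral handoff between providers
    plan_review_rate: float = 0.006


@dataclass
class PatientPopulationConfig:
    """Initial-state distributions and weekly event probabilities."""

    population_size: int = 1000
    age_bands: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"18-29": 0.22, "30-44": 0.34, "45-59": 0.29, "60+": 0.15}
        )
    )
    diagnoses: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"schizophrenia": 0.48, "schizoaffective": 0.17, "bipolar_severe": 0.35}
        )
    )
    initial_mental_health: Distribution = field(
        default_factory=lambda: Distribution(
            kind="truncnormal", mean=55, sd=14, low=20, high=88
        )
    )
    #: per-patient minimum mental-health score, expressed as an offset below
    #: the initial score: floor = clip(initial - offset, 5, initial)
    mh_floor_offset: Distribution = field(
        default_factory=lambda: Distribution(kind="uniform", low=10, high=28)
    )
    initial_physical_health: Distribution = field(
        default_factory=lambda: Distribution(
            kind="truncnormal", mean=62, sd=12, low=25, high=95
        )
    )
    ph_decline_factor: Distribution = field(
        default_factory=lambda: Distribution(kind="uniform", low=-0.06, high=0.0)
    )
    family_support: Distribution = field(
        default_factory=lambda: Distribution(kind="uniform", low=0.0, high=1.0)
    )
    stress: Distribution = field(
        default_factory=lambda: Distribution(kind="uniform", low=0.1, high=0.9)
    )
    initial_financial_resources: Distribution = field(
        default_factory=lambda: Distribution(kind="uniform", low=0.0, high=2000.0)
    )
    initial_environment: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"private_residence": 0.60, "assisted_living": 0.24, "homeless": 0.16}
        )
    )
    initial_treatment_plan: dict = field(
        default_factory=lambda: {
            "schizophrenia": "standard",
            "schizoaffective": "intensive",
            "bipolar_severe": "standard",
        }
    )
    substance_abuse_rate: float = 0.22
    employment_rate: float = 0.18
    initial_on_medication: float = 0.62
    propensity_to_commit_crime: dict = field(
        default_factory=lambda: {
            "severe": 0.0020, "serious": 0.0012, "moderate": 0.0006, "mild": 0.0003
        }
    )
    crisis_onset_probability: dict = field(
        default_factory=lambda: {
            "severe": 0.011, "serious": 0.0065, "moderate": 0.0035, "mild": 0.0018
        }
    )
    #: outcome mix of a crisis, by engagement status; the "lost" mix is
    #: arrest-heavier because no provider is positioned to intervene
    crisis_outcome_probabilities: dict = field(
        default_factory=lambda: {
            "engaged": {
                "hospitalization": 0.42, "arrest": 0.13, "homelessness": 0.05,
                "stabilized": 0.38, "suicide": 0.02,
            },
            "lost": {
                "hospitalization": 0.30, "arrest": 0.20, "homelessness": 0.12,
                "stabilized": 0.33, "suicide": 0.05,
            },
        }
    )
    substance_start_probability: float = 0.0025
    substance_stop_probability: float = 0.010
    employment_gain_probability: float = 0.006
    employment_loss_probability: float = 0.009


@dataclass
class MedicineConfig:
    id: str = ""
    generation: str = "second"
    refill_frequency_weeks: int = 4
    dosage: str = "standard"
    cost_to_patient_factor: int = 2
    system_cost_per_week: float = 0.0
    patient_cost_per_week: float = 0.0
    formulary_status: bool = True
    short_term_side_effect_severity: float = 0.0
    long_term_side_effect_severity: float = 0.0
    is_long_acting_injectable: bool = False
    lai_interval_weeks: int = 12


@dataclass
class ProviderConfig:
    id: str = ""
    provider_type: str = ""
    count: int = 1
    capacity_per_week: int = 0
    lai_probability: float = 0.0
    cost_to_patient_factor: int = 0
    patient_cost_per_visit: float = 0.0
    third_party_cost_per_visit: float = 0.0
    mh_effect_per_visit: float = 0.0


@dataclass
class AppointmentConfig:
    provider_type: str = ""
    interval_weeks: int = 4
    #: staggers this appointment's cadence against the plan's other
    #: appointments so contacts spread over the interval instead of landing
    #: in the same week
    phase_offset_weeks: int = 0


@dataclass
class TreatmentPlanConfig:
    id: str = ""
    medicine_id: Optional[str] = None
    appointments: list = field(default_factory=list)  # list[AppointmentConfig]
    designated_environment_id: str = "private_residence"


@dataclass
class EnvironmentConfig:
    id: str = ""
    name: str = ""
    stability_flag: bool = True
    probability_of_being_located: float = 1.0
    capacity: Optional[int] = None  # None = unbounded
    length_of_stay: Optional[Distribution] = None  # episodic environments only
    weekly_mh_effect: float = 0.0
    weekly_ph_effect: float = 0.0
    weekly_cost_third_party: float = 0.0
    weekly_cost_patient: float = 0.0
    cost_category: str = "housing"
    #: for non-episodic environments: per mental-health category, a categorical
    #: distribution over destination environment ids (including self)
    transition_matrix: Optional[dict] = None
    #: for episodic environments: where patients go on discharge
    discharge_location: Optional[dict] = None
    overflow_environment_id: Optional[str] = None

    @property
    def episodic(self) -> bool:
        return self.length_of_stay is not None


@dataclass
class JusticeConfig:
    initial_criminal_history: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"none": 0.55, "minor": 0.30, "major": 0.15}
        )
    )
    cit_officer_probability: float = 0.25
    crime_degree_distribution: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"misdemeanor": 0.62, "felony": 0.30, "felony_serious": 0.08}
        )
    )
    sentence_weeks_by_degree: dict = field(
        default_factory=lambda: {
            "misdemeanor": Distribution(kind="discrete_uniform", low=2, high=8),
            "felony": Distribution(kind="discrete_uniform", low=8, high=30),
            "felony_serious": Distribution(kind="discrete_uniform", low=30, high=120),
        }
    )
    jail_diversion_entry_probability: float = 0.35
    diversion_eligible_degrees: list = field(default_factory=lambda: ["misdemeanor"])
    discharge_location_distribution: Distribution = field(
        default_factory=lambda: Distribution.categorical(
            {"private_residence": 0.50, "assisted_living": 0.20, "homeless": 0.30}
        )
    )
    #: diagnosis -> plan id assigned on release ("default" falls back to the
    #: population's initial_treatment_plan mapping)
    discharge_plan_rule: dict = field(default_factory=lambda: {"default": "standard"})
    release_on_medication_probability: float = 0.5


@dataclass
class EconomicsConfig:
    employment_income_per_week: float = 160.0
    #: the access multiplier is 1 - (factor/5) * strain(resources) with strain
    #: decaying from strain_high (destitute) to strain_low (resourced)
    access_strain_low: float = 0.15
    access_strain_high: float = 0.55
    resource_scale: float = 900.0
    stabilization_cost_third_party: float = 400.0
    stabilization_cost_patient: float = 15.0


@dataclass
class SystemLeversConfig:
    """System-level levers: the two care-coordination rates and funding."""

    handoff_success_rate: float = 0.95
    patient_appointment_compliance_rate: float = 0.45
    funding_support_level: float = 1.0
    #: weekly probability that outreach re-engages a lost patient (default 0;
    #: lost patients otherwise re-engage only through crisis resolution)
    outreach_reengagement_rate: float = 0.0


@dataclass
class ModelConfig:
    """The full input-parameter set for one simulated city profile."""

    system: SystemConfig = field(default_factory=SystemConfig)
    patients: PatientPopulationConfig = field(default_factory=PatientPopulationConfig)
    medicines: list = field(default_factory=list)  # list[MedicineConfig]
    providers: list = field(default_factory=list)  # list[ProviderConfig]
    treatment_plans: list = field(default_factory=list)  # list[TreatmentPlanConfig]
    environments: list = field(default_factory=list)  # list[EnvironmentConfig]
    justice: JusticeConfig = field(default_factory=JusticeConfig)
    economics: EconomicsConfig = field(default_factory=EconomicsConfig)
    levers: SystemLeversConfig = field(default_factory=SystemLeversConfig)
    adherence_chart: AdherenceChartConfig = field(default_factory=AdherenceChartConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    schema_version: int = 1

    # -- lookups ------------------------------------------------------------

    def medicine(self, mid: str) -> MedicineConfig:
        for m in self.medicines:
            if m.id == mid:
                return m
        raise ConfigError(f"unknown medicine id {mid!r}")

    def plan(self, pid: str) -> TreatmentPlanConfig:
        for p in self.treatment_plans:
            if p.id == pid:
                return p
        raise ConfigError(f"unknown treatment plan id {pid!r}")

    def environment(self, eid: str) -> EnvironmentConfig:
        for e in self.environments:
            if e.id == eid:
                return e
        raise ConfigError(f"unknown environment id {eid!r}")

    def provider_by_type(self, ptype: str) -> ProviderConfig:
        for p in self.providers:
            if p.provider_type == ptype:
                return p
        raise ConfigError(f"unknown provider type {ptype!r}")

    def to_dict(self) -> dict:
        return _to_obj(self)

    @staticmethod
    def from_dict(data: dict) -> "ModelConfig":
        return _from_obj(ModelConfig, data, "config")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Generic dict <-> dataclass mapping
# ---------------------------------------------------------------------------

_LIST_ITEM_TYPES = {
    ("ModelConfig", "medicines"): MedicineConfig,
    ("ModelConfig", "providers"): ProviderConfig,
    ("ModelConfig", "treatment_plans"): TreatmentPlanConfig,
    ("ModelConfig", "environments"): EnvironmentConfig,
    ("TreatmentPlanConfig", "appointments"): AppointmentConfig,
}

_DIST_VALUED_DICTS = {
    ("JusticeConfig", "sentence_weeks_by_degree"),
}


def _from_obj(tp, obj, path):
    origin = typing.get_origin(tp)
    if dataclasses.is_dataclass(tp):
        if not isinstance(obj, dict):
            raise ConfigFormatError(f"{path}: expected a mapping for {tp.__name__}")
        hints = typing.get_type_hints(tp)
        known = {f.name for f in dataclasses.fields(tp)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigFormatError(
                f"{path}: unknown field(s) {sorted(unknown)} for {tp.__name__}"
            )
        kwargs = {}
        for f in dataclasses.fields(tp):
            if f.name not in obj:
                continue
            raw = obj[f.name]
            fpath = f"{path}.{f.name}"
            item_tp = _LIST_ITEM_TYPES.get((tp.__name__, f.name))
            if item_tp is not None:
                if not isinstance(raw, list):
                    raise ConfigFormatError(f"{fpath}: expected a list")
                kwargs[f.name] = [
                    _from_obj(item_tp, x, f"{fpath}[{i}]") for i, x in enumerate(raw)
                ]
            elif (tp.__name__, f.name) in _DIST_VALUED_DICTS:
                kwargs[f.name] = {
                    k: Distribution.from_dict(v, f"{fpath}.{k}") for k, v in raw.items()
                }
            else:
                kwargs[f.name] = _from_obj(hints[f.name], raw, fpath)
        try:
            return tp(**kwargs)
        except TypeError as exc:
            raise ConfigFormatError(f"{path}: {exc}") from None
    if origin is typing.Union:  # Optional[...]
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if obj is None:
            return None
        return _from_obj(args[0], obj, path)
    if tp is Distribution:
        if isinstance(obj, Distribution):
            return obj
        return Distribution.from_dict(obj, path)
    if tp is float:
        if isinstance(obj, bool) or not isinstance(obj, (int, float)):
            raise ConfigFormatError(f"{path}: expected a number, got {obj!r}")
        return float(obj)
    if tp is int:
        if isinstance(obj, bool) or not isinstance(obj, int):
            raise ConfigFormatError(f"{path}: expected an integer, got {obj!r}")
        return obj
    if tp is bool:
        if not isinstance(obj, bool):
            raise ConfigFormatError(f"{path}: expected a boolean, got {obj!r}")
        return obj
    if tp is str:
        return str(obj)
    # untyped containers (dict, list) pass through
    return copy.deepcopy(obj)


def _to_obj(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        out = {}
        for f in dataclasses.fields(value):
            out[f.name] = _to_obj(getattr(value, f.name))
        return out
    if isinstance(value, Distribution):
        return value.to_dict()
    if isinstance(value, dict):
        return {k: _to_obj(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_to_obj(v) for v in value]
    return value


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(out, path, value):
    if not (0.0 <= value <= 1.0):
        out.append(Violation(path, value, "probability in [0, 1]"))


def validate_config(cfg: ModelConfig, lint: bool = False) -> list:
    """Return all invariant violations in ``cfg`` (empty list = valid).

    ``lint=True`` adds profile-plausibility checks (e.g. facility weekly costs
    dominating outpatient visit costs) on top of the hard invariants.
    """
    out: list = []
    sysc = cfg.system
    if sysc.run_length_weeks < 0:
        out.append(Violation("system.run_length_weeks", sysc.run_length_weeks, ">= 0"))
    if sysc.n_replications < 1:
        out.append(Violation("system.n_replications", sysc.n_replications, ">= 1"))

    pats = cfg.patients
    if pats.population_size < 0:
        out.append(Violation("patients.population_size", pats.population_size, ">= 0"))
    for name in ("age_bands", "diagnoses", "initial_environment",
                 "initial_mental_health", "mh_floor_offset",
                 "initial_physical_health", "ph_decline_factor", "family_support",
                 "stress", "initial_financial_resources"):
        getattr(pats, name).validate_into(f"patients.{name}", out)
    for name in ("substance_abuse_rate", "employment_rate", "initial_on_medication",
                 "substance_start_probability", "substance_stop_probability",
                 "employment_gain_probability", "employment_loss_probability"):
        _check_prob(out, f"patients.{name}", getattr(pats, name))
    for table in ("propensity_to_commit_crime", "crisis_onset_probability"):
        d = getattr(pats, table)
        for cat in MH_CATEGORIES:
            if cat not in d:
                out.append(Violation(f"patients.{table}", sorted(d),
                                     f"an entry for category {cat!r}"))
            else:
                _check_prob(out, f"patients.{table}.{cat}", d[cat])
    for status, mix in pats.crisis_outcome_probabilities.items():
        Distribution.categorical(mix).validate_into(
            f"patients.crisis_outcome_probabilities.{status}", out
        )

    med_ids = [m.id for m in cfg.medicines]
    for i, m in enumerate(cfg.medicines):
        p = f"medicines[{i}]({m.id})"
        if m.cost_to_patient_factor not in (0, 1, 2, 3, 4, 5):
            out.append(Violation(f"{p}.cost_to_patient_factor",
                                 m.cost_to_patient_factor, "an integer in 0-5"))
        if m.refill_frequency_weeks < 1:
            out.append(Violation(f"{p}.refill_frequency_weeks",
                                 m.refill_frequency_weeks, ">= 1"))
        for name in ("short_term_side_effect_severity", "long_term_side_effect_severity"):
            v = getattr(m, name)
            if not (0.0 <= v <= 1.0):
                out.append(Violation(f"{p}.{name}", v, "severity in [0, 1]"))
    _check_unique(out, "medicines", med_ids)

    prov_ids = [p.id for p in cfg.providers]
    prov_types = [p.provider_type for p in cfg.providers]
    for i, pr in enumerate(cfg.providers):
        p = f"providers[{i}]({pr.id})"
        if pr.count < 0:
            out.append(Violation(f"{p}.count", pr.count, ">= 0"))
        if pr.capacity_per_week < 0:
            out.append(Violation(f"{p}.capacity_per_week", pr.capacity_per_week, ">= 0"))
        _check_prob(out, f"{p}.lai_probability", pr.lai_probability)
        if pr.cost_to_patient_factor not in (0, 1, 2, 3, 4, 5):
            out.append(Violation(f"{p}.cost_to_patient_factor",
                                 pr.cost_to_patient_factor, "an integer in 0-5"))
    _check_unique(out, "providers", prov_ids)
    _check_unique(out, "providers(provider_type)", prov_types)

    env_ids = [e.id for e in cfg.environments]
    _check_unique(out, "environments", env_ids)
    env_set = set(env_ids)
    for i, env in enumerate(cfg.environments):
        p = f"environments[{i}]({env.id})"
        _check_prob(out, f"{p}.probability_of_being_located",
                    env.probability_of_being_located)
        if env.capacity is not None and env.capacity < 0:
            out.append(Violation(f"{p}.capacity", env.capacity, ">= 0 or null"))
        if env.episodic and env.stability_flag:
            out.append(Violation(f"{p}.stability_flag", True,
                                 "false for episodic environments"))
        if env.length_of_stay is not None:
            env.length_of_stay.validate_into(f"{p}.length_of_stay", out)
        if env.transition_matrix is not None:
            for cat in MH_CATEGORIES:
                if cat not in env.transition_matrix:
                    out.append(Violation(f"{p}.transition_matrix", sorted(env.transition_matrix),
                                         f"a row for category {cat!r}"))
                    continue
                row = env.transition_matrix[cat]
                total = sum(row.values())
                if abs(total - 1.0) > _PROB_SUM_TOL:
                    out.append(Violation(f"{p}.transition_matrix.{cat}", total,
                                         "row probabilities summing to 1"))
                for dest, prob in row.items():
                    _check_prob(out, f"{p}.transition_matrix.{cat}[{dest}]", prob)
                    if dest not in env_set:
                        out.append(Violation(f"{p}.transition_matrix.{cat}[{dest}]",
                                             dest, "a known environment id"))
        if env.discharge_location is not None:
            Distribution.categorical(env.discharge_location).validate_into(
                f"{p}.discharge_location", out)
            for dest in env.discharge_location:
                if dest not in env_set:
                    out.append(Violation(f"{p}.discharge_location[{dest}]", dest,
                                         "a known environment id"))
        if env.overflow_environment_id is not None and \
                env.overflow_environment_id not in env_set:
            out.append(Violation(f"{p}.overflow_environment_id",
                                 env.overflow_environment_id, "a known environment id"))

    plan_ids = [p.id for p in cfg.treatment_plans]
    _check_unique(out, "treatment_plans", plan_ids)
    ptype_set = set(prov_types)
    for i, plan in enumerate(cfg.treatment_plans):
        p = f"treatment_plans[{i}]({plan.id})"
        if plan.medicine_id is not None and plan.medicine_id not in med_ids:
            out.append(Violation(f"{p}.medicine_id", plan.medicine_id,
                                 "a known medicine id"))
        if plan.designated_environment_id not in env_set:
            out.append(Violation(f"{p}.designated_environment_id",
                                 plan.designated_environment_id, "a known environment id"))
        for j, appt in enumerate(plan.appointments):
            if appt.provider_type not in ptype_set:
                out.append(Violation(f"{p}.appointments[{j}].provider_type",
                                     appt.provider_type, "a known provider type"))
            if appt.interval_weeks < 1:
                out.append(Violation(f"{p}.appointments[{j}].interval_weeks",
                                     appt.interval_weeks, ">= 1"))
    for diag, pid in cfg.patients.initial_treatment_plan.items():
        if pid not in plan_ids:
            out.append(Violation(f"patients.initial_treatment_plan.{diag}", pid,
                                 "a known treatment plan id"))

    jus = cfg.justice
    jus.initial_criminal_history.validate_into("justice.initial_criminal_history", out)
    _check_prob(out, "justice.cit_officer_probability", jus.cit_officer_probability)
    _check_prob(out, "justice.jail_diversion_entry_probability",
                jus.jail_diversion_entry_probability)
    jus.crime_degree_distribution.validate_into("justice.crime_degree_distribution", out)
    degrees = set((jus.crime_degree_distribution.probs or {}).keys())
    for deg in degrees:
        if deg not in jus.sentence_weeks_by_degree:
            out.append(Violation("justice.sentence_weeks_by_degree", deg,
                                 f"a sentence distribution for degree {deg!r}"))
        else:
            jus.sentence_weeks_by_degree[deg].validate_into(
                f"justice.sentence_weeks_by_degree.{deg}", out)
    for deg in jus.diversion_eligible_degrees:
        if deg not in degrees:
            out.append(Violation("justice.diversion_eligible_degrees", deg,
                                 "a known crime degree"))
    jus.discharge_location_distribution.validate_into(
        "justice.discharge_location_distribution", out)
    for dest in (jus.discharge_location_distribution.probs or {}):
        if dest not in env_set:
            out.append(Violation(f"justice.discharge_location_distribution[{dest}]",
                                 dest, "a known environment id"))
    for diag, pid in jus.discharge_plan_rule.items():
        if diag != "default" and pid not in plan_ids:
            out.append(Violation(f"justice.discharge_plan_rule.{diag}", pid,
                                 "a known treatment plan id"))
    _check_prob(out, "justice.release_on_medication_probability",
                jus.release_on_medication_probability)

    lev = cfg.levers
    _check_prob(out, "levers.handoff_success_rate", lev.handoff_success_rate)
    _check_prob(out, "levers.patient_appointment_compliance_rate",
                lev.patient_appointment_compliance_rate)
    if lev.funding_support_level < 0:
        out.append(Violation("levers.funding_support_level",
                             lev.funding_support_level, ">= 0"))
    _check_prob(out, "levers.outreach_reengagement_rate", lev.outreach_reengagement_rate)

    chart = cfg.adherence_chart
    if chart.stop_threshold > chart.start_threshold:
        out.append(Violation("adherence_chart.stop_threshold", chart.stop_threshold,
                             f"<= start_threshold ({chart.start_threshold})"))

    econ = cfg.economics
    if not (0.0 <= econ.access_strain_low <= econ.access_strain_high <= 1.0):
        out.append(Violation("economics.access_strain_low/high",
                             (econ.access_strain_low, econ.access_strain_high),
                             "0 <= strain_low <= strain_high <= 1"))
    if econ.resource_scale <= 0:
        out.append(Violation("economics.resource_scale", econ.resource_scale, "> 0"))

    if lint:
        out.extend(_lint_config(cfg))
    return out


def _lint_config(cfg: ModelConfig) -> list:
    """Plausibility checks on cost magnitudes (not hard invariants)."""
    out = []
    visit_costs = [p.third_party_cost_per_visit + p.patient_cost_per_visit
                   for p in cfg.providers
                   if p.capacity_per_week > 0
                   and p.provider_type != "crisis_stabilization_unit"]
    top_visit = max(visit_costs, default=0.0)
    for eid in ("hospital_inpatient", "correctional_facility"):
        try:
            env = cfg.environment(eid)
        except ConfigError:
            continue
        weekly = env.weekly_cost_third_party + env.weekly_cost_patient
        if weekly <= 3 * top_visit:
            out.append(Violation(f"environments({eid}).weekly_cost_third_party",
                                 weekly,
                                 "facility weekly cost well above outpatient visit cost"))
    return out


def _check_unique(out, path, ids):
    seen = set()
    for x in ids:
        if x in seen:
            out.append(Violation(path, x, "unique ids"))
        seen.add(x)


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------


def load_config(path, validate: bool = True) -> ModelConfig:
    """Load and validate a YAML profile into a :class:`ModelConfig`.

    Raises :class:`ConfigFormatError` on parse/typing failures (naming the
    line or field) and :class:`ConfigValidationError` listing every violated
    invariant.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigFormatError(f"{path}: YAML parse error{loc}: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigFormatError(f"{path}: profile must be a YAML mapping")
    cfg = ModelConfig.from_dict(data)
    if validate:
        violations = validate_config(cfg)
        if violations:
            raise ConfigValidationError(violations)
    return cfg


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def config_hash(cfg: ModelConfig) -> str:
    """Stable content hash of a config (canonical YAML, sorted keys)."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def default_profile_path() -> str:
    """Path of the shipped calibrated city profile."""
    ref = _importlib_resources.files("spmi_ecosim") / "profiles" / "default_city.yaml"
    return str(ref)


def load_default_profile() -> ModelConfig:
    return load_config(default_profile_path())


# ---------------------------------------------------------------------------
# Funding lever
# ---------------------------------------------------------------------------


def apply_funding_level(cfg: ModelConfig, level: float) -> ModelConfig:
    """Derive a config under a different overall funding-support level.

    Provider counts scale linearly (floored, min 0).  Cost-to-patient factors
    on medicines and provider services shift by ``round(log2(level))`` in the
    opposite direction (more funding -> cheaper access), clamped to 0-5.
    ``level == 1`` returns an identical copy.  The input is never mutated.
    """
    if level < 0:
        raise ValueError(f"funding level must be >= 0, got {level}")
    new = cfg.copy()
    shift = -5 if level == 0 else int(round(math.log2(level)))
    for pr in new.providers:
        pr.count = max(int(math.floor(pr.count * level)), 0)
        pr.cost_to_patient_factor = min(max(pr.cost_to_patient_factor - shift, 0), 5)
    for m in new.medicines:
        m.cost_to_patient_factor = min(max(m.cost_to_patient_factor - shift, 0), 5)
    new.levers.funding_support_level = cfg.levers.funding_support_level
    return new
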