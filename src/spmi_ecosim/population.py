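"""Patient agents and synthesis of the initial population.

Every patient is synthesized at run start from the profile's distributions;
no external microdata is ingested.  Fields are drawn independently except for
the constraint that the per-patient mental-health floor cannot exceed the
initial mental-health score (enforced by clipping) and the diagnosis-
conditioned initial treatment plan.

Each patient owns a dedicated ``random.Random`` substream derived from the
run seed and the patient id.  Substreams make runs bit-reproducible and give
strong common-random-number pairing across lever values: changing a system
lever perturbs only the draws of the patients it touches.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields as dc_fields

import pandas as pd

from .config import ConfigError, ModelConfig

__all__ = ["Patient", "synthesize_population", "mh_category", "coarse_index",
           "patient_stream", "population_to_frame"]

#: coarse category labels indexed by :func:`coarse_index`
_COARSE = ("severe", "serious", "moderate", "mild")


def mh_category(score: float, coarse: bool = False) -> str:
    """Map a 1-100 functioning score to its reporting band.

    The fine bands are the ten decile ranges of a GAF-style scale
    (``"1-10"`` ... ``"91-100"``); ``coarse=True`` collapses them to
    ``severe`` (<=30), ``serious`` (31-50), ``moderate`` (51-70) and
    ``mild`` (>70).  The mapping is total and monotone on [1, 100].
    """
    if not (1.0 <= score <= 100.0):
        raise ValueError(f"mental-health score must be in [1, 100], got {score}")
    if coarse:
        return _COARSE[coarse_index(score)]
    band = min(int((score - 1) // 10), 9)
    return f"{band * 10 + 1}-{band * 10 + 10}"


def coarse_index(score: float) -> int:
    """0=severe, 1=serious, 2=moderate, 3=mild (fast path for the engine)."""
    if score <= 30.0:
        return 0
    if score <= 50.0:
        return 1
    if score <= 70.0:
        return 2
    return 3


def patient_stream(seed: int, patient_id: int) -> random.Random:
    """The dedicated RNG substream for one patient under one run seed."""
    return random.Random(f"{seed}:p{patient_id}")


@dataclass
class Patient:
    """One simulated person with serious and persistent mental illness."""

    id: int
    age_band: str
    diagnosis: str
    mental_health: float
    mh_floor: float
    physical_health: float
    ph_decline_factor: float
    on_medication: bool
    adherence_score: float
    substance_abuse: bool
    employed: bool
    family_support: float
    stress: float
    environment_id: str
    environment_weeks_remaining: int | None
    plan_id: str
    medicine_id: str | None
    financial_resources: float
    criminal_history: str
    in_jail_diversion: bool
    lost_to_system: bool
    alive: bool = True
    weeks_since_contact: int = 99
    lai_weeks_remaining: int = 0
    crisis_origin_stay: bool = False
    released_before: bool = False
    initial_category: int = 3
    visit_mh_bonus: float = 0.0  # transient, reset each week
    rng: random.Random = field(default=None, compare=False, repr=False)

    def check_invariants(self) -> None:
        assert 1.0 <= self.mh_floor <= self.mental_health <= 100.0, self
        assert 1.0 <= self.physical_health <= 100.0, self
        if self.lost_to_system:
            # a lost patient has no scheduled appointments (plan suspended)
            assert not self.in_jail_diversion


def synthesize_population(cfg: ModelConfig, seed: int) -> list:
    """Create exactly ``cfg.patients.population_size`` patients.

    Deterministic given ``(cfg, seed)``: every field of patient ``i`` is drawn
    from its configured distribution using the patient's own substream, in a
    fixed documented order.
    """
    pats = cfg.patients
    for path, dist in (
        ("patients.age_bands", pats.age_bands),
        ("patients.diagnoses", pats.diagnoses),
        ("patients.initial_environment", pats.initial_environment),
        ("justice.initial_criminal_history", cfg.justice.initial_criminal_history),
    ):
        if dist.kind == "categorical" and not dist.probs:
            raise ConfigError(f"{path}: empty distribution")
    if not pats.initial_treatment_plan:
        raise ConfigError("patients.initial_treatment_plan: empty mapping")
    population = []
    for i in range(pats.population_size):
        rng = patient_stream(seed, i)
        age = pats.age_bands.sample(rng)
        diagnosis = pats.diagnoses.sample(rng)
        mh = float(pats.initial_mental_health.sample(rng))
        mh = min(max(mh, 1.0), 100.0)
        offset = float(pats.mh_floor_offset.sample(rng))
        floor = min(max(mh - offset, 5.0), mh)
        floor = max(floor, 1.0)
        ph = float(pats.initial_physical_health.sample(rng))
        ph = min(max(ph, 1.0), 100.0)
        decline = float(pats.ph_decline_factor.sample(rng))
        support = float(pats.family_support.sample(rng))
        stress = float(pats.stress.sample(rng))
        resources = float(pats.initial_financial_resources.sample(rng))
        env = pats.initial_environment.sample(rng)
        substance = rng.random() < pats.substance_abuse_rate
        employed = rng.random() < pats.employment_rate
        history = cfg.justice.initial_criminal_history.sample(rng)
        plan_id = pats.initial_treatment_plan.get(
            diagnosis, next(iter(pats.initial_treatment_plan.values())))
        plan = cfg.plan(plan_id)
        on_med = plan.medicine_id is not None and rng.random() < pats.initial_on_medication
        population.append(Patient(
            id=i,
            age_band=age,
            diagnosis=diagnosis,
            mental_health=mh,
            mh_floor=floor,
            physical_health=ph,
            ph_decline_factor=decline,
            on_medication=on_med,
            adherence_score=0.0,
            substance_abuse=substance,
            employed=employed,
            family_support=support,
            stress=stress,
            environment_id=env,
            environment_weeks_remaining=None,
            plan_id=plan_id,
            medicine_id=plan.medicine_id,
            financial_resources=resources,
            criminal_history=history,
            in_jail_diversion=False,
            lost_to_system=False,
            initial_category=coarse_index(mh),
            rng=rng,
        ))
    return population


def population_to_frame(population: list) -> pd.DataFrame:
    """Flat-table dump of a population for inspection and fixtures."""
    cols = [f.name for f in dc_fields(Patient) if f.name != "rng"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in population])
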