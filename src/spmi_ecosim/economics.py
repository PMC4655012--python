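"""Cost accounting and patient finances.

Costs are tracked in an abstract currency unit, split into the patient-borne
share and the third-party share (insurers, government, charities); the total
cost of care is exactly their sum.  Headline results are reported as percent
changes against a baseline run, so the unit itself never enters a result.

Hospitalization and incarceration postings additionally carry a
``crisis_origin`` flag so that crisis-attributable costs can be separated
from, e.g., incarceration following a crime committed outside a crisis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import ConfigError, EconomicsConfig, ModelConfig

__all__ = ["CATEGORIES", "CostEvent", "CostLedger", "access_factor",
           "cost_event", "update_finances"]

CATEGORIES = ("medication", "outpatient", "hospitalization", "incarceration",
              "housing", "stabilization", "diversion")


@dataclass(frozen=True)
class CostEvent:
    """One costed occurrence, as emitted by the weekly update."""

    id: int
    week: int
    patient_id: int
    kind: str  # medication_week | visit | environment_week | stabilization | diversion_week
    detail: str  # medicine id / provider type / environment id
    crisis_origin: bool = False


class CostLedger:
    """Per-week, per-category accumulators, split patient / third-party."""

    def __init__(self, n_weeks: int):
        self.n_weeks = n_weeks
        n = max(n_weeks, 1)
        # plain float lists: [patient-borne per week, third-party per week]
        self._acc = {cat: ([0.0] * n, [0.0] * n) for cat in CATEGORIES}
        self._crisis = {
            "hospitalization": ([0.0] * n, [0.0] * n),
            "incarceration": ([0.0] * n, [0.0] * n),
        }
        self._posted_total = 0.0
        self._seen_event_ids: set = set()

    # -- posting ------------------------------------------------------------

    def post(self, week: int, category: str, patient_amt: float, third_amt: float,
             crisis_origin: bool = False) -> None:
        if patient_amt < 0 or third_amt < 0:
            raise ValueError("cost amounts must be non-negative")
        pat, third = self._acc[category]
        pat[week] += patient_amt
        third[week] += third_amt
        if crisis_origin and category in self._crisis:
            cpat, cthird = self._crisis[category]
            cpat[week] += patient_amt
            cthird[week] += third_amt
        self._posted_total += patient_amt + third_amt

    # -- queries ------------------------------------------------------------

    def category_total(self, category: str, crisis_only: bool = False) -> float:
        src = self._crisis if crisis_only else self._acc
        pat, third = src[category]
        return sum(pat) + sum(third)

    def total(self) -> float:
        return float(sum(sum(p) + sum(t) for p, t in self._acc.values()))

    def posted_total(self) -> float:
        """Sum over every posted amount; equals :meth:`total` by construction
        (asserted in the test suite as ledger conservation)."""
        return self._posted_total

    def patient_total(self) -> float:
        return float(sum(sum(p) for p, _ in self._acc.values()))

    def third_party_total(self) -> float:
        return float(sum(sum(t) for _, t in self._acc.values()))

    def weekly_total(self, week: int) -> float:
        return float(sum(p[week] + t[week] for p, t in self._acc.values()))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-week, per-category table (patient / third-party / total)."""
        rows = []
        for cat in CATEGORIES:
            pat, third = self._acc[cat]
            for w in range(self.n_weeks):
                rows.append((w, cat, pat[w], third[w], pat[w] + third[w]))
        return pd.DataFrame(rows, columns=["week", "category", "patient_borne",
                                           "third_party", "total"])


def _event_amounts(event: CostEvent, cfg: ModelConfig):
    """Map an event to (category, patient_amount, third_party_amount)."""
    kind = event.kind
    if kind == "medication_week":
        med = cfg.medicine(event.detail)
        return "medication", med.patient_cost_per_week, med.system_cost_per_week
    if kind == "visit":
        prov = cfg.provider_by_type(event.detail)
        return "outpatient", prov.patient_cost_per_visit, prov.third_party_cost_per_visit
    if kind == "environment_week":
        env = cfg.environment(event.detail)
        return env.cost_category, env.weekly_cost_patient, env.weekly_cost_third_party
    if kind == "stabilization":
        econ = cfg.economics
        return ("stabilization", econ.stabilization_cost_patient,
                econ.stabilization_cost_third_party)
    if kind == "diversion_week":
        prov = cfg.provider_by_type(event.detail)
        return "diversion", prov.patient_cost_per_visit, prov.third_party_cost_per_visit
    raise ConfigError(f"unknown costed event kind {kind!r}")


def cost_event(event: CostEvent, cfg: ModelConfig, ledger: CostLedger) -> CostLedger:
    """Post one costed event to the ledger; idempotent per event id."""
    if event.id in ledger._seen_event_ids:
        return ledger
    category, patient_amt, third_amt = _event_amounts(event, cfg)
    ledger.post(event.week, category, patient_amt, third_amt, event.crisis_origin)
    ledger._seen_event_ids.add(event.id)
    return ledger


def update_finances(patient, cfg: ModelConfig, events) -> float:
    """Weekly finance update: income minus patient-borne costs, floored at 0.

    ``events`` is the patient's costed events for the week.  Returns the new
    resource level (also written back to the patient).
    """
    income = cfg.economics.employment_income_per_week if patient.employed else 0.0
    outlay = 0.0
    for ev in events:
        _, patient_amt, _ = _event_amounts(ev, cfg)
        outlay += patient_amt
    resources = max(patient.financial_resources + income - outlay, 0.0)
    patient.financial_resources = resources
    return resources


def access_factor(cost_to_patient_factor: int, resources: float,
                  econ: EconomicsConfig) -> float:
    """Probability multiplier for accessing a service with this cost factor.

    Factor 0 is free access (multiplier 1.0).  The multiplier is monotone
    non-increasing in the factor and non-decreasing in the patient's
    financial resources: ``1 - (factor/5) * strain(resources)`` where strain
    decays exponentially from ``access_strain_high`` (no resources) to
    ``access_strain_low`` (well-resourced).
    """
    if cost_to_patient_factor not in (0, 1, 2, 3, 4, 5):
        raise ValueError(
            f"cost-to-patient factor must be an integer 0-5, got {cost_to_patient_factor}")
    if cost_to_patient_factor == 0:
        return 1.0
    lo, hi = econ.access_strain_low, econ.access_strain_high
    strain = lo + (hi - lo) * math.exp(-max(resources, 0.0) / econ.resource_scale)
    return 1.0 - (cost_to_patient_factor / 5.0) * strain
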