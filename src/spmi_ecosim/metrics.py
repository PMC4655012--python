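"""Per-tick metric aggregation and end-of-run results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .economics import CostLedger

__all__ = ["WeeklyMetrics", "RunResult"]


@dataclass
class WeeklyMetrics:
    """Aggregates for one weekly tick (one row of the metric series)."""

    week: int
    population_living: int
    count_severe: int
    count_serious: int
    count_moderate: int
    count_mild: int
    on_medication: int
    lost_to_system: int
    employed: int
    substance_abuse: int
    crises: int
    hospitalizations: int
    arrests: int
    recidivist_arrests: int
    suicides: int
    homeless_entries: int
    crimes: int
    scheduled: int
    kept: int
    releases: int
    diversions: int
    referrals: int
    handoff_failures: int
    reengagements: int
    mean_mental_health: float
    mean_physical_health: float
    cost_patient: float
    cost_third_party: float
    env_counts: dict = field(default_factory=dict)
    utilization: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items()
               if k not in ("env_counts", "utilization")}
        for eid, n in self.env_counts.items():
            row[f"env_{eid}"] = n
        for ptype, util in self.utilization.items():
            row[f"util_{ptype}"] = util
        row["missed"] = self.scheduled - self.kept
        return row


@dataclass
class RunResult:
    """Everything one simulation run produced.

    ``metrics`` is the weekly series (one row per tick); ``summary`` holds
    end-of-run aggregates (annualized counts, final-year means, cost totals);
    ``variability`` reports the per-patient temporal standard deviation of
    the mental-health score by initial severity class.
    """

    config_hash: str
    seed: int
    run_length_weeks: int
    population_size: int
    metrics: pd.DataFrame
    ledger: CostLedger
    summary: dict
    variability: pd.DataFrame
    events: Optional[list] = None
    initial_on_medication: int = 0

    def events_frame(self) -> pd.DataFrame:
        cols = ["week", "patient_id", "kind", "detail", "amount_patient",
                "amount_third_party"]
        return pd.DataFrame(self.events or [], columns=cols)

    def summary_text(self) -> str:
        lines = ["Simulation run summary",
                 "======================",
                 f"config hash : {self.config_hash[:12]}…",
                 f"seed        : {self.seed}",
                 f"weeks       : {self.run_length_weeks}",
                 f"patients    : {self.population_size}", ""]
        for key, val in self.summary.items():
            if isinstance(val, float):
                lines.append(f"{key:38s} {val:14.3f}")
            else:
                lines.append(f"{key:38s} {val!s:>14}")
        return "\n".join(lines)


def summarize(metrics: pd.DataFrame, ledger: CostLedger, population_size: int,
              n_weeks: int, suicides_total: int, releases: int,
              recidivist_arrests: int) -> dict:
    """End-of-run summary statistics from the weekly series and the ledger."""
    years = n_weeks / 52.0 if n_weeks else float("nan")
    out: dict = {"population_size": population_size, "run_length_weeks": n_weeks}
    if n_weeks == 0 or metrics.empty:
        return out
    last_year = metrics.tail(min(52, len(metrics)))
    living = metrics["population_living"]
    out.update({
        "annual_crises": metrics["crises"].sum() / years,
        "annual_hospitalizations": metrics["hospitalizations"].sum() / years,
        "annual_arrests": metrics["arrests"].sum() / years,
        "annual_homeless_entries": metrics["homeless_entries"].sum() / years,
        "annual_suicides": suicides_total / years,
        "on_medication_share": float(
            (last_year["on_medication"] / last_year["population_living"]).mean() * 100.0),
        "lost_share": float(
            (last_year["lost_to_system"] / last_year["population_living"]).mean() * 100.0),
        "adherence_rate_final_week": float(
            metrics["on_medication"].iloc[-1] / max(living.iloc[-1], 1) * 100.0),
        "attendance_rate": float(
            metrics["kept"].sum() / max(metrics["scheduled"].sum(), 1) * 100.0),
        "mean_mental_health_final_year": float(last_year["mean_mental_health"].mean()),
        "mean_physical_health_final_year": float(
            last_year["mean_physical_health"].mean()),
        "recidivism_rate": (recidivist_arrests / releases * 100.0) if releases else 0.0,
        "total_cost": ledger.total(),
        "cost_patient_borne": ledger.patient_total(),
        "cost_third_party": ledger.third_party_total(),
    })
    for cat in ("medication", "outpatient", "hospitalization", "incarceration",
                "housing", "stabilization", "diversion"):
        out[f"cost_{cat}"] = ledger.category_total(cat)
    out["cost_hospitalization_crisis"] = ledger.category_total(
        "hospitalization", crisis_only=True)
    out["cost_incarceration_crisis"] = ledger.category_total(
        "incarceration", crisis_only=True)
    for col in metrics.columns:
        if col.startswith("env_"):
            out[f"mean_{col}_final_year"] = float(last_year[col].mean())
    return out
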