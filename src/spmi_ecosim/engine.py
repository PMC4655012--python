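"""The simulation loop: weekly ticks, replications, and result export.

A run is bit-reproducible given (config, seed): the population, every
patient's weekly draws, and the weekly shuffle of patient update order all
derive deterministically from the seed.  Patients update sequentially in a
freshly shuffled order each week because shared capacities make order matter.
"""

from __future__ import annotations

import json
import math
import os
import random

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import (ConfigValidationError, ModelConfig, apply_funding_level,
                     config_hash, validate_config)
from .dynamics import weekly_update
from .ecosystem import EcosystemState, RunContext
from .metrics import RunResult, WeeklyMetrics, summarize
from .population import synthesize_population

__all__ = ["run_simulation", "run_replications", "export_results",
           "load_exported_metrics"]


def run_simulation(cfg: ModelConfig, seed: int,
                   record_events: bool = False) -> RunResult:
    """Run one full simulation of ``cfg.system.run_length_weeks`` weekly ticks.

    Raises :class:`ConfigValidationError` if the config is invalid.  With
    ``record_events=True`` the result carries the full typed event log
    (slower and memory-heavier; off by default for sweeps).
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)
    base_hash = config_hash(cfg)
    if cfg.levers.funding_support_level != 1.0:
        cfg = apply_funding_level(cfg, cfg.levers.funding_support_level)

    n_weeks = cfg.system.run_length_weeks
    population = synthesize_population(cfg, seed)
    n0 = len(population)
    initial_on_med = sum(1 for p in population if p.on_medication)
    ctx = RunContext(cfg)
    state = EcosystemState(ctx, population, n_weeks, record_events=record_events)
    sys_rng = random.Random(f"{seed}:sys")

    # per-patient temporal variability accumulators (Welford-free: sum/sumsq)
    var_sum = np.zeros(n0)
    var_sumsq = np.zeros(n0)
    var_n = np.zeros(n0, dtype=np.int64)

    rows = []
    suicides_total = 0
    env_ids = list(ctx.envs)
    ptypes = [pt for pt, cap in ctx.weekly_capacity.items() if cap > 0]
    order = list(population)

    for week in range(n_weeks):
        state.reset_week(week)
        order = [p for p in order if p.alive]
        sys_rng.shuffle(order)
        for p in order:
            weekly_update(p, ctx, state)
        # aggregate
        wk = state.wk
        suicides_total += wk["suicides"]
        n_live = 0
        counts = [0, 0, 0, 0]
        on_med = lost = employed = substance = 0
        mh_sum = ph_sum = 0.0
        env_counts = dict.fromkeys(env_ids, 0)
        for p in population:
            if not p.alive:
                continue
            n_live += 1
            s = p.mental_health
            counts[0 if s <= 30.0 else 1 if s <= 50.0 else 2 if s <= 70.0 else 3] += 1
            if p.on_medication:
                on_med += 1
            if p.lost_to_system:
                lost += 1
            if p.employed:
                employed += 1
            if p.substance_abuse:
                substance += 1
            mh_sum += s
            ph_sum += p.physical_health
            env_counts[p.environment_id] += 1
            i = p.id
            var_sum[i] += s
            var_sumsq[i] += s * s
            var_n[i] += 1
        utilization = {
            pt: 1.0 - state.capacity_left[pt] / ctx.weekly_capacity[pt]
            for pt in ptypes
        }
        rows.append(WeeklyMetrics(
            week=week, population_living=n_live,
            count_severe=counts[0], count_serious=counts[1],
            count_moderate=counts[2], count_mild=counts[3],
            on_medication=on_med, lost_to_system=lost, employed=employed,
            substance_abuse=substance, crises=wk["crises"],
            hospitalizations=wk["hospitalizations"], arrests=wk["arrests"],
            recidivist_arrests=wk["recidivist_arrests"], suicides=wk["suicides"],
            homeless_entries=wk["homeless_entries"], crimes=wk["crimes"],
            scheduled=wk["scheduled"], kept=wk["kept"], releases=wk["releases"],
            diversions=wk["diversions"], referrals=wk["referrals"],
            handoff_failures=wk["handoff_failures"],
            reengagements=wk["reengagements"],
            mean_mental_health=mh_sum / n_live if n_live else float("nan"),
            mean_physical_health=ph_sum / n_live if n_live else float("nan"),
            cost_patient=float(sum(p[week] for p, _ in state.ledger._acc.values())),
            cost_third_party=float(sum(t[week]
                                       for _, t in state.ledger._acc.values())),
            env_counts=env_counts, utilization=utilization,
        ).to_row())

    metrics = pd.DataFrame(rows)
    variability = _variability_frame(population, var_sum, var_sumsq, var_n)
    summary = summarize(metrics, state.ledger, n0, n_weeks, suicides_total,
                        state.releases, state.recidivist_arrests)
    return RunResult(
        config_hash=base_hash, seed=seed, run_length_weeks=n_weeks,
        population_size=n0, metrics=metrics, ledger=state.ledger,
        summary=summary, variability=variability,
        events=state.events, initial_on_medication=initial_on_med,
    )


def _variability_frame(population, var_sum, var_sumsq, var_n) -> pd.DataFrame:
    """Mean per-patient temporal SD of the mental-health score, by the
    patient's initial severity class."""
    classes = ("severe", "serious", "moderate", "mild")
    rows = []
    by_class: dict = {c: [] for c in classes}
    for p in population:
        i = p.id
        if var_n[i] >= 2:
            n = var_n[i]
            mean = var_sum[i] / n
            var = max(var_sumsq[i] / n - mean * mean, 0.0)
            by_class[classes[p.initial_category]].append(math.sqrt(var))
    for c in classes:
        sds = by_class[c]
        rows.append({
            "patient_class": c, "n_patients": len(sds),
            "mean_temporal_sd": float(np.mean(sds)) if sds else 0.0,
        })
    return pd.DataFrame(rows)


def run_replications(cfg: ModelConfig, n: int, base_seed: int):
    """Run ``n`` independent replications with seeds derived from ``base_seed``.

    Returns ``(results, pooled)`` where ``pooled`` is a DataFrame with the
    mean and standard error of every numeric summary metric across
    replications (SE is NaN when ``n == 1``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    results = [run_simulation(cfg, base_seed + i) for i in range(n)]
    keys = [k for k, v in results[0].summary.items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)]
    rows = []
    for key in keys:
        vals = np.array([r.summary[key] for r in results], dtype=float)
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"metric": key, "mean": float(vals.mean()), "se": se, "n": n})
    pooled = pd.DataFrame(rows).set_index("metric")
    return results, pooled


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_results(result: RunResult, out_dir) -> dict:
    """Write the run to ``out_dir``: weekly metrics, cost ledger, event log
    (when recorded), variability report, and a JSON manifest sufficient to
    reproduce the run.  Returns the mapping of written file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    result.metrics.to_csv(_p("weekly_metrics.csv"), index=False)
    result.ledger.to_frame().to_csv(_p("cost_ledger.csv"), index=False)
    result.variability.to_csv(_p("variability.csv"), index=False)
    if result.events is not None:
        result.events_frame().to_csv(_p("events.csv"), index=False)
    manifest = {
        "config_hash": result.config_hash,
        "seed": result.seed,
        "run_length_weeks": result.run_length_weeks,
        "population_size": result.population_size,
        "initial_on_medication": result.initial_on_medication,
        "package_version": _pkg_version,
        "summary": result.summary,
    }
    with open(_p("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def load_exported_metrics(out_dir) -> pd.DataFrame:
    return pd.read_csv(os.path.join(out_dir, "weekly_metrics.csv"))
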