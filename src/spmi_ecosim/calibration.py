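"""Tiered calibration of a profile against aggregate reference targets.

Calibration tunes declared profile parameters so that replicated-run means of
headline outputs match reference values within tolerance bands, tier by tier:
tier 1 is a single high-confidence aggregate (the annual number of mental-
health crises), later tiers its component outcomes (hospitalizations,
arrests, homelessness, suicides) and their drivers (adherence, living
arrangements).  Because adjusting an input to move one metric usually moves
others, the objective for a tier always re-includes every earlier tier's
targets: an accepted step can never push an already-calibrated metric back
out of band.

The search is automated coordinate descent: for each tunable parameter in
turn, a bounded golden-section line search on the replication-mean objective,
with fixed common random numbers across evaluations to tame simulation noise.
Reference values shipped with the default profile are repo-chosen plausible
magnitudes, not measurements of any real city.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .config import ConfigError, ModelConfig, validate_config
from .engine import run_replications
from .metrics import RunResult

__all__ = ["CalibrationTarget", "TunableParam", "CalibrationResult",
           "calibrate", "variability_check", "load_targets_file"]

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class CalibrationTarget:
    """One reference value to match: a summary metric, a tolerance, a tier."""

    metric: str            # a key of RunResult.summary (e.g. "annual_crises")
    reference: float
    tolerance: float = 0.20  # relative
    tier: int = 1

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ConfigError(f"target {self.metric}: tolerance must be > 0")
        if self.reference == 0:
            raise ConfigError(f"target {self.metric}: reference must be nonzero")


@dataclass(frozen=True)
class TunableParam:
    """A config path with bounds.  ``scale:`` paths multiply every value of a
    numeric mapping (e.g. all four crisis-onset probabilities) by the searched
    factor; plain dotted paths set the value directly."""

    path: str
    low: float
    high: float
    tier: int = 1


@dataclass
class CalibrationResult:
    profile: ModelConfig
    achieved: dict              # metric -> relative error at the final profile
    simulated: dict             # metric -> replication-mean value
    iterations: int             # simulation evaluations used
    converged: bool
    history: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "relative_error": e,
                 "simulated": self.simulated.get(m)}
                for m, e in self.achieved.items()]
        return pd.DataFrame(rows)


# -- config path plumbing ---------------------------------------------------


def _get_path(tree: dict, dotted: str):
    node = tree
    for part in dotted.split("."):
        node = node[part]
    return node


def _set_path(tree: dict, dotted: str, value) -> None:
    parts = dotted.split(".")
    node = tree
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


def _apply_param(base_tree: dict, param: TunableParam, x: float) -> dict:
    import copy
    tree = copy.deepcopy(base_tree)
    if param.path.startswith("scale:"):
        dotted = param.path[len("scale:"):]
        mapping = _get_path(tree, dotted)
        if not isinstance(mapping, dict):
            raise ConfigError(f"{param.path}: scale target must be a mapping")
        _set_path(tree, dotted, {k: min(v * x, 1.0) for k, v in mapping.items()})
    else:
        _set_path(tree, param.path, x)
    return tree


# -- calibration ------------------------------------------------------------


def calibrate(cfg0: ModelConfig, targets: list, tunable_params: list,
              budget: int = 60, seed: int = 424242,
              n_replications: int = 2) -> CalibrationResult:
    """Tune ``tunable_params`` so every target's replication-mean output falls
    within its tolerance band, processing tiers in ascending order.

    ``budget`` caps the number of simulation evaluations (each evaluation is
    ``n_replications`` runs with common seeds).  Returns achieved relative
    errors for every target whether or not the search converged.
    """
    if not targets:
        raise ConfigError("calibrate: no targets supplied")
    tiers = sorted({t.tier for t in targets})
    if not tunable_params:
        raise ConfigError("calibrate: empty tunable-parameter set")

    evals = {"n": 0}
    cache: dict = {}

    def evaluate(tree: dict) -> dict:
        key = yaml.safe_dump(tree, sort_keys=True)
        if key in cache:
            return cache[key]
        cfg = ModelConfig.from_dict(tree)
        _, pooled = run_replications(cfg, n_replications, seed)
        means = pooled["mean"].to_dict()
        cache[key] = means
        evals["n"] += 1
        return means

    def objective(means: dict, upto_tier: int) -> float:
        """Worst normalized error over all targets up to this tier
        (<= 1 means every such target is within tolerance)."""
        worst = 0.0
        for t in targets:
            if t.tier <= upto_tier:
                sim = means.get(t.metric)
                if sim is None:
                    raise ConfigError(f"unknown calibration metric {t.metric!r}")
                err = abs(sim - t.reference) / abs(t.reference)
                worst = max(worst, err / t.tolerance)
        return worst

    tree = cfg0.to_dict()
    history = []
    means = evaluate(tree)
    for tier in tiers:
        params = [p for p in tunable_params if p.tier == tier]
        if not params and objective(means, tier) > 1.0:
            raise ConfigError(f"calibration tier {tier}: no tunable parameters")
        best = objective(means, tier)
        for _pass in range(3):
            if best <= 1.0 or evals["n"] >= budget:
                break
            improved = False
            for param in params:
                if evals["n"] >= budget:
                    break
                x_best, f_best, m_best = _golden_section(
                    lambda x: evaluate(_apply_param(tree, param, x)),
                    lambda m: objective(m, tier),
                    param, budget - evals["n"])
                if f_best < best - 1e-12:
                    tree = _apply_param(tree, param, x_best)
                    best = f_best
                    means = m_best
                    improved = True
                    history.append({"tier": tier, "param": param.path,
                                    "value": x_best, "objective": best})
            if not improved:
                break

    final_cfg = ModelConfig.from_dict(tree)
    violations = validate_config(final_cfg)
    if violations:  # calibration must never emit an invalid profile
        raise ConfigError(f"calibration produced an invalid profile: {violations}")
    achieved = {}
    for t in targets:
        sim = means[t.metric]
        achieved[t.metric] = abs(sim - t.reference) / abs(t.reference)
    converged = all(achieved[t.metric] <= t.tolerance for t in targets)
    return CalibrationResult(profile=final_cfg, achieved=achieved,
                             simulated={t.metric: means[t.metric] for t in targets},
                             iterations=evals["n"], converged=converged,
                             history=history)


def _golden_section(evaluate, objective, param: TunableParam, max_evals: int):
    """Bounded golden-section minimisation of a (noisy) unimodal objective."""
    a, b = param.low, param.high
    budget = max(min(max_evals, 8), 2)
    pts = []

    def f(x):
        m = evaluate_at(x)
        return objective(m), m

    evals_done = {}

    def evaluate_at(x):
        if x not in evals_done:
            evals_done[x] = evaluate(x)
        return evals_done[x]

    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc, mc = f(c)
    fd, md = f(d)
    pts.extend([(fc, c, mc), (fd, d, md)])
    used = 2
    while used < budget and (b - a) > 1e-4 * (param.high - param.low):
        if fc < fd:
            b, d, fd, md = d, c, fc, mc
            c = b - _GOLD * (b - a)
            fc, mc = f(c)
            pts.append((fc, c, mc))
        else:
            a, c, fc, mc = c, d, fd, md
            d = a + _GOLD * (b - a)
            fd, md = f(d)
            pts.append((fd, d, md))
        used += 1
    fbest, xbest, mbest = min(pts, key=lambda t: t[0])
    return xbest, fbest, mbest


# -- internal-dynamics variability check ------------------------------------


def variability_check(result: RunResult, bounds) -> pd.DataFrame:
    """Flag patient classes whose mental-health scores vary too much over time.

    ``bounds`` is either a single maximum temporal standard deviation applied
    to every class or a mapping of class name -> bound.  Returns the
    per-class report with a ``flagged`` column.
    """
    report = result.variability.copy()
    if isinstance(bounds, dict):
        report["bound"] = report["patient_class"].map(bounds)
    else:
        report["bound"] = float(bounds)
    report["flagged"] = report["mean_temporal_sd"] > report["bound"]
    return report


# -- targets file -----------------------------------------------------------


def load_targets_file(path):
    """Read a calibration-targets YAML file -> (targets, tunables)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    targets = [CalibrationTarget(**t) for t in data.get("targets", [])]
    tunables = [TunableParam(**p) for p in data.get("tunables", [])]
    return targets, tunables
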