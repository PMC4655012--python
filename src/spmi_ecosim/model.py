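"""High-level modelling surface: build a model from a profile, simulate, fit.

:class:`EcosystemModel` wraps a validated :class:`~spmi_ecosim.config.ModelConfig`
the way statistical packages wrap a model specification: ``simulate`` produces
a :class:`SimulationResults` (with ``summary()``), ``replicate`` pools
replications, ``fit`` runs the tiered calibration and returns a
:class:`CalibrationFit`, and ``sweep`` runs one of the two intervention
experiments.
"""

from __future__ import annotations

from typing import Optional

from .calibration import CalibrationResult, calibrate, load_targets_file
from .config import (ModelConfig, config_hash, load_config,
                     load_default_profile, validate_config)
from .engine import export_results, run_replications, run_simulation
from .experiments import SweepResult, SweepSpec, run_sweep
from .metrics import RunResult

__all__ = ["EcosystemModel", "SimulationResults", "CalibrationFit"]


class SimulationResults:
    """Results of one simulation run (thin wrapper around :class:`RunResult`)."""

    def __init__(self, run: RunResult):
        self.run = run
        self.metrics = run.metrics
        self.summary_dict = run.summary

    def summary(self) -> str:
        return self.run.summary_text()

    def export(self, out_dir) -> dict:
        return export_results(self.run, out_dir)

    def __getattr__(self, name):
        return getattr(self.run, name)


class CalibrationFit:
    """A fitted (calibrated) profile with per-target achieved errors."""

    def __init__(self, result: CalibrationResult):
        self.result = result
        self.profile = result.profile
        self.converged = result.converged

    def summary(self) -> str:
        frame = self.result.summary_frame()
        lines = ["Calibration fit",
                 "===============",
                 f"converged   : {self.result.converged}",
                 f"evaluations : {self.result.iterations}", ""]
        lines.append(frame.to_string(index=False,
                                     float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


class EcosystemModel:
    """An agent-based model of one city's SPMI care ecosystem."""

    def __init__(self, config: ModelConfig, validate: bool = True):
        if validate:
            violations = validate_config(config)
            if violations:
                from .config import ConfigValidationError
                raise ConfigValidationError(violations)
        self.config = config

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "EcosystemModel":
        return cls(load_config(path), validate=False)  # load_config validates

    @classmethod
    def default_city(cls) -> "EcosystemModel":
        """The shipped calibrated city profile."""
        return cls(load_default_profile(), validate=False)

    # -- running ------------------------------------------------------------

    def simulate(self, seed: Optional[int] = None,
                 record_events: bool = False) -> SimulationResults:
        seed = self.config.system.seed if seed is None else seed
        return SimulationResults(run_simulation(self.config, seed,
                                                record_events=record_events))

    def replicate(self, n: Optional[int] = None,
                  seed: Optional[int] = None):
        """Run ``n`` replications; returns (list of results, pooled frame)."""
        n = self.config.system.n_replications if n is None else n
        seed = self.config.system.seed if seed is None else seed
        results, pooled = run_replications(self.config, n, seed)
        return [SimulationResults(r) for r in results], pooled

    # -- fitting (calibration) ----------------------------------------------

    def fit(self, targets, tunable_params, budget: int = 60,
            seed: int = 424242, n_replications: int = 2) -> CalibrationFit:
        """Calibrate the profile to aggregate targets (tiered); see
        :func:`spmi_ecosim.calibration.calibrate`."""
        result = calibrate(self.config, targets, tunable_params,
                           budget=budget, seed=seed,
                           n_replications=n_replications)
        return CalibrationFit(result)

    def fit_from_file(self, targets_path, **kwargs) -> CalibrationFit:
        targets, tunables = load_targets_file(targets_path)
        return self.fit(targets, tunables, **kwargs)

    # -- experiments --------------------------------------------------------

    def sweep(self, lever: str, start: Optional[int] = None,
              stop: Optional[int] = None, replications: int = 30,
              base_seed: int = 7_000_000) -> SweepResult:
        spec = SweepSpec(lever=lever, base_config=self.config, start=start,
                         stop=stop, replications=replications,
                         base_seed=base_seed)
        return run_sweep(spec)

    # -- misc ---------------------------------------------------------------

    @property
    def hash(self) -> str:
        return config_hash(self.config)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = self.config
        return (f"<EcosystemModel {c.patients.population_size} patients, "
                f"{c.system.run_length_weeks} weeks, hash {self.hash[:8]}>")
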