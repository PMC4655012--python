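"""Tiered calibration and the internal-variability check."""

import math
import random

import numpy as np
import pytest

from spmi_ecosim.calibration import (CalibrationTarget, TunableParam,
                                     calibrate, variability_check)
from spmi_ecosim.engine import run_replications, run_simulation

from conftest import frozen_config


class TestCalibrate:
    def test_satisfied_targets_return_unchanged(self):
        """A profile already inside every tolerance band converges without
        touching a parameter."""
        cfg = frozen_config(population=150, weeks=52)
        p = 0.02
        cfg.patients.crisis_onset_probability = {
            c: p for c in ("severe", "serious", "moderate", "mild")}
        reference = 150 * 52 * p
        targets = [CalibrationTarget("annual_crises", reference, 0.20, tier=1)]
        tunables = [TunableParam("scale:patients.crisis_onset_probability",
                                 0.25, 4.0, tier=1)]
        result = calibrate(cfg, targets, tunables, budget=10, seed=5,
                           n_replications=2)
        assert result.converged
        assert result.profile == cfg
        assert result.achieved["annual_crises"] <= 0.20

    def test_recovers_rate_from_analytic_target(self):
        """With frozen dynamics the annual crisis count is N * 52 * p, so the
        tuned scale must land within 5% of the analytic solution."""
        cfg = frozen_config(population=400, weeks=52)
        p0 = 0.010
        cfg.patients.crisis_onset_probability = {
            c: p0 for c in ("severe", "serious", "moderate", "mild")}
        p_target = 0.016  # analytic scale: 1.6
        reference = 400 * 52 * p_target
        targets = [CalibrationTarget("annual_crises", reference, 0.02, tier=1)]
        tunables = [TunableParam("scale:patients.crisis_onset_probability",
                                 0.25, 4.0, tier=1)]
        result = calibrate(cfg, targets, tunables, budget=14, seed=77,
                           n_replications=2)
        tuned = result.profile.patients.crisis_onset_probability["mild"]
        assert tuned / p0 == pytest.approx(1.6, rel=0.05)
        assert result.achieved["annual_crises"] <= 0.05

    def test_empty_tunables_rejected(self):
        cfg = frozen_config(population=30, weeks=8)
        targets = [CalibrationTarget("annual_crises", 10.0, 0.2, tier=1)]
        with pytest.raises(Exception):
            calibrate(cfg, targets, [], budget=4, seed=1)

    def test_later_tier_keeps_earlier_tier_in_band(self):
        """The tier-2 search may not push the tier-1 metric out of band."""
        cfg = frozen_config(population=200, weeks=52)
        p = 0.02
        cfg.patients.crisis_onset_probability = {
            c: p for c in ("severe", "serious", "moderate", "mild")}
        cfg.patients.crisis_outcome_probabilities = {
            "engaged": {"stabilized": 1.0}, "lost": {"stabilized": 1.0}}
        targets = [
            CalibrationTarget("annual_crises", 200 * 52 * p, 0.10, tier=1),
            # an impossible-to-improve tier-2 target: the search must still
            # refuse steps that break tier 1
            CalibrationTarget("annual_suicides", 1.0, 5.0, tier=2),
        ]
        tunables = [
            TunableParam("scale:patients.crisis_onset_probability",
                         0.25, 4.0, tier=1),
            TunableParam("scale:patients.crisis_onset_probability",
                         0.25, 4.0, tier=2),
        ]
        result = calibrate(cfg, targets, tunables, budget=16, seed=9,
                           n_replications=1)
        assert result.achieved["annual_crises"] <= 0.10

    def test_result_profile_always_valid(self):
        from spmi_ecosim.config import validate_config
        cfg = frozen_config(population=100, weeks=26)
        cfg.patients.crisis_onset_probability = {
            c: 0.01 for c in ("severe", "serious", "moderate", "mild")}
        targets = [CalibrationTarget("annual_crises", 100 * 52 * 0.02, 0.10,
                                     tier=1)]
        tunables = [TunableParam("scale:patients.crisis_onset_probability",
                                 0.25, 4.0, tier=1)]
        result = calibrate(cfg, targets, tunables, budget=10, seed=3,
                           n_replications=1)
        assert validate_config(result.profile) == []


class TestVariabilityCheck:
    def test_frozen_dynamics_nothing_flagged(self):
        cfg = frozen_config(population=60, weeks=52)
        report = variability_check(run_simulation(cfg, 4), bounds=0.5)
        assert (report["mean_temporal_sd"] == 0.0).all()
        assert not report["flagged"].any()

    def test_noisy_dynamics_flagged(self):
        cfg = frozen_config(population=60, weeks=104)
        cfg.dynamics.mh_noise_sd = 3.0
        report = variability_check(run_simulation(cfg, 4), bounds=0.5)
        assert report.loc[report["patient_class"] == "moderate",
                          "flagged"].item()

    def test_per_class_bounds(self):
        cfg = frozen_config(population=60, weeks=104)
        cfg.dynamics.mh_noise_sd = 3.0
        report = variability_check(
            run_simulation(cfg, 4),
            bounds={"severe": 0.1, "serious": 0.1, "moderate": 99.0,
                    "mild": 99.0})
        assert not report.loc[report["patient_class"] == "moderate",
                              "flagged"].item()

    def test_matches_clamped_walk_oracle(self):
        """A pure noise walk's temporal SD must match a direct Monte-Carlo
        simulation of the same clamped walk within 10%."""
        sd = 2.0
        weeks = 104
        cfg = frozen_config(population=80, weeks=weeks)
        cfg.dynamics.mh_noise_sd = sd
        result = run_simulation(cfg, 12)
        model_sd = result.variability.loc[
            result.variability["patient_class"] == "moderate",
            "mean_temporal_sd"].item()

        # independent oracle: clamped uniform-step walk, same start and bounds
        rng = np.random.default_rng(999)
        n_walk = 3000
        scores = np.full(n_walk, 60.0)
        floor, ceil = 40.0, 100.0
        sds = np.zeros(n_walk)
        walks = np.zeros((weeks, n_walk))
        for w in range(weeks):
            steps = sd * (rng.random(n_walk) - 0.5) * math.sqrt(12.0)
            scores = np.clip(scores + steps, floor, ceil)
            walks[w] = scores
        oracle = walks.std(axis=0, ddof=0).mean()
        assert model_sd == pytest.approx(oracle, rel=0.10)
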