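"""The two care-coordination intervention experiments.

Each experiment sweeps one system lever in 1-percentage-point steps —
the referral Handoff Success Rate over −15..+20 points, or the Patient
Appointment Compliance Rate over −10..+20 points — runs replicated
simulations at every step with common random numbers, and summarises the
output measures as percent changes against the sweep's own delta = 0
baseline.  Band summaries report the min/max response over an expert-panel
band of lever shifts (e.g. +5..+15 points for handoffs).

Output measures per run:

* ``on_medication_share`` — % of living patients on medication (final-year
  mean); the handoff experiment's primary care measure, reported as a
  percentage-point change.
* ``private_residence`` — mean final-year count of patients living in a
  private residence; the compliance experiment's primary measure, reported
  as a percent change.
* total and crisis-attributable incarceration / hospitalization costs over
  the full run, reported as percent reductions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import ConfigError, ModelConfig
from .engine import run_simulation

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "handoff_outcomes",
           "compliance_outcomes", "HANDOFF_LEVER", "COMPLIANCE_LEVER",
           "plot_sweep"]

HANDOFF_LEVER = "handoff_success_rate"
COMPLIANCE_LEVER = "patient_appointment_compliance_rate"

#: published sweep ranges, in percentage points of the lever
DEFAULT_RANGES = {HANDOFF_LEVER: (-15, 20), COMPLIANCE_LEVER: (-10, 20)}

_MEASURES = {
    "on_medication_share": "on_medication_share",
    "private_residence": "mean_env_private_residence_final_year",
    "incarceration_cost": "cost_incarceration",
    "hospitalization_cost": "cost_hospitalization",
    "crisis_incarceration_cost": "cost_incarceration_crisis",
    "crisis_hospitalization_cost": "cost_hospitalization_crisis",
    "crisis_count": "annual_crises",
    "attendance_rate": "attendance_rate",
    "lost_share": "lost_share",
}


@dataclass
class SweepSpec:
    """One lever sweep: which lever, which delta grid, how many replications.

    Replications can be allocated unevenly: deltas inside ``band`` (and the
    delta = 0 baseline) run ``band_replications`` replicates when that is set
    higher than ``replications``, concentrating simulation effort where the
    band summaries are computed.
    """

    lever: str
    base_config: ModelConfig
    start: int = None
    stop: int = None
    step: int = 1
    replications: int = 30
    base_seed: int = 7_000_000
    band: tuple = None          # (low, high) delta band of primary interest
    band_replications: int = None

    def __post_init__(self):
        if self.lever not in (HANDOFF_LEVER, COMPLIANCE_LEVER):
            raise ConfigError(f"unknown sweep lever {self.lever!r}")
        default = DEFAULT_RANGES[self.lever]
        if self.start is None:
            self.start = default[0]
        if self.stop is None:
            self.stop = default[1]
        if self.step <= 0:
            raise ConfigError("sweep step must be positive")
        if self.band_replications is None:
            self.band_replications = self.replications

    @property
    def deltas(self) -> list:
        out = list(range(self.start, self.stop + 1, self.step))
        if 0 not in out:
            out.append(0)  # the baseline row is always present
        return sorted(out)

    def replications_for(self, delta: int) -> int:
        if self.band is not None and (
                delta == 0 or self.band[0] <= delta <= self.band[1]):
            return max(self.band_replications, self.replications)
        return self.replications


@dataclass
class SweepResult:
    """Per-delta replicate outcomes and derived percent-change curves."""

    lever: str
    runs: pd.DataFrame          # one row per (delta, replication)
    aggregated: pd.DataFrame    # one row per delta: mean and se per measure
    changes: pd.DataFrame       # percent / point changes vs the delta=0 row
    replications: int = 0
    base_rate: float = float("nan")


def _shift_lever(cfg: ModelConfig, lever: str, delta_points: int) -> ModelConfig:
    new = cfg.copy()
    base = getattr(new.levers, lever)
    setattr(new.levers, lever, min(max(base + delta_points / 100.0, 0.0), 1.0))
    return new


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the sweep with common random numbers across deltas.

    Replication ``r`` uses the same seed at every delta, and each patient
    draws from a seed-and-id-keyed substream, so the delta = 0 rows of two
    sweeps with the same seeds are identical run-for-run and cross-delta
    contrasts are tightly paired.
    """
    cfg0 = spec.base_config
    rows = []
    cache: dict = {}  # clamped deltas share the same effective rate and seed
    for delta in spec.deltas:
        cfg = _shift_lever(cfg0, spec.lever, delta)
        rate = getattr(cfg.levers, spec.lever)
        for r in range(spec.replications_for(delta)):
            key = (round(rate, 9), r)
            summary = cache.get(key)
            if summary is None:
                summary = run_simulation(cfg, spec.base_seed + r).summary
                cache[key] = summary
            row = {"delta": delta, "replication": r}
            for name, key2 in _MEASURES.items():
                row[name] = summary.get(key2, float("nan"))
            rows.append(row)
    runs = pd.DataFrame(rows)
    agg_rows = []
    for delta, grp in runs.groupby("delta"):
        row = {"delta": delta}
        for name in _MEASURES:
            vals = grp[name].to_numpy(dtype=float)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_se"] = (float(vals.std(ddof=1) / math.sqrt(len(vals)))
                                 if len(vals) > 1 else float("nan"))
        agg_rows.append(row)
    aggregated = pd.DataFrame(agg_rows).sort_values("delta").reset_index(drop=True)
    baseline = aggregated.loc[aggregated["delta"] == 0].iloc[0]

    ch_rows = []
    for _, row in aggregated.iterrows():
        ch = {"delta": row["delta"]}
        # point change for the population share; percent change otherwise
        ch["on_medication_share_change_points"] = (
            row["on_medication_share_mean"] - baseline["on_medication_share_mean"])
        for name in ("private_residence", "crisis_count", "attendance_rate"):
            ch[f"{name}_change_pct"] = _pct_change(
                baseline[f"{name}_mean"], row[f"{name}_mean"])
        for name in ("incarceration_cost", "hospitalization_cost",
                     "crisis_incarceration_cost", "crisis_hospitalization_cost"):
            ch[f"{name}_reduction_pct"] = -_pct_change(
                baseline[f"{name}_mean"], row[f"{name}_mean"])
        ch_rows.append(ch)
    changes = pd.DataFrame(ch_rows)
    return SweepResult(lever=spec.lever, runs=runs, aggregated=aggregated,
                       changes=changes, replications=spec.replications,
                       base_rate=getattr(cfg0.levers, spec.lever))


def _pct_change(base: float, value: float) -> float:
    if base == 0:
        return 0.0 if value == 0 else float("nan")
    return (value - base) / base * 100.0


def _band_slice(result: SweepResult, band) -> pd.DataFrame:
    low, high = band
    deltas = result.changes["delta"]
    if low < deltas.min() or high > deltas.max():
        raise ValueError(f"band {band} outside swept range "
                         f"[{deltas.min()}, {deltas.max()}]")
    sl = result.changes[(deltas >= low) & (deltas <= high)]
    if sl.empty:
        raise ValueError(f"band {band} contains no swept delta")
    return sl


def handoff_outcomes(result: SweepResult, band=(5, 15)) -> dict:
    """Min/max over the band of the handoff experiment's three measures:
    percentage-point change in the on-medication share, and percent
    reductions in incarceration and hospitalization costs."""
    sl = _band_slice(result, band)
    out = {"band": tuple(band)}
    for key, col in (
        ("medication_share_points", "on_medication_share_change_points"),
        ("incarceration_cost_reduction_pct", "incarceration_cost_reduction_pct"),
        ("hospitalization_cost_reduction_pct", "hospitalization_cost_reduction_pct"),
    ):
        out[f"{key}_min"] = float(sl[col].min())
        out[f"{key}_max"] = float(sl[col].max())
    return out


def compliance_outcomes(result: SweepResult, band=(3, 12)) -> dict:
    """Min/max over the band of the compliance experiment's three measures:
    percent change in private-residence occupancy, and percent reductions in
    the two crisis-attributable cost categories."""
    sl = _band_slice(result, band)
    out = {"band": tuple(band)}
    for key, col in (
        ("private_residence_pct", "private_residence_change_pct"),
        ("crisis_incarceration_cost_reduction_pct",
         "crisis_incarceration_cost_reduction_pct"),
        ("crisis_hospitalization_cost_reduction_pct",
         "crisis_hospitalization_cost_reduction_pct"),
    ):
        out[f"{key}_min"] = float(sl[col].min())
        out[f"{key}_max"] = float(sl[col].max())
    return out


def plot_sweep(result: SweepResult, path=None):
    """Two-panel summary of a sweep: the primary care measure and the two
    cost-reduction curves against the lever shift."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ch = result.changes
    if result.lever == HANDOFF_LEVER:
        ax1.plot(ch["delta"], ch["on_medication_share_change_points"], "o-")
        ax1.set_ylabel("on-medication share (pp change)")
        cost_cols = ("incarceration_cost_reduction_pct",
                     "hospitalization_cost_reduction_pct")
    else:
        ax1.plot(ch["delta"], ch["private_residence_change_pct"], "o-")
        ax1.set_ylabel("private residence (% change)")
        cost_cols = ("crisis_incarceration_cost_reduction_pct",
                     "crisis_hospitalization_cost_reduction_pct")
    for col in cost_cols:
        ax2.plot(ch["delta"], ch[col], "o-",
                 label=col.replace("_reduction_pct", "").replace("_", " "))
    ax2.set_ylabel("cost reduction (%)")
    ax2.legend(fontsize=7)
    for ax in (ax1, ax2):
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"{result.lever} shift (points)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
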