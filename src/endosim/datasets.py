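"""Synthetic calibration, ground-truth and validation-proxy datasets.

No public accessions exist for the daily endoderm-induction time courses, so
the pipeline fits synthetic calibration datasets that reproduce the reported
qualitative features of the two induction conditions over days 0-5:

* growth (live count, day-4 normalized): Condition A shows a proliferation
  lag with the live count declining until day 3 and a roughly linear rise
  after; in Condition B the majority of growth happens before day 3;
* cumulative cell death (day-4 normalized): approximately linear in time;
* Sox17+ fraction: concave quadratic through zero at day 0 with a peak of
  ~19-23% at days 2-3 (0.19 at day 3 for Condition A, 0.23 at day 2 for
  Condition B by default);
* CXCR4+ fraction: roughly constant until day 2, then a pronounced drop,
  followed by an approximately linear rise that is steeper for Condition B.

The exact intercepts, plateau levels and slopes are generator configuration
with documented defaults; only the features above are contractual.

The module also wraps the simulator to produce ground-truth datasets at known
parameters (for recovery tests) and computes fraction-of-maximum proxy curves
for the undifferentiated and mesendoderm populations, the quantities compared
against Oct4 and Brachyury expression in validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import TrajectorySet, simulate
from .mechanisms import MechanismConfig, get_mechanism
from .params import ModelParams, SimulationSettings

__all__ = [
    "ExperimentalDataset",
    "CONDITION_DEFAULTS",
    "generate_calibration_data",
    "generate_ground_truth",
    "validation_proxy",
    "UndefinedNormalizationError",
]


class UndefinedNormalizationError(ValueError):
    """A series with zero maximum (or zero day-4 value) cannot be normalized."""


#: Default curve shapes per induction condition.  ``sox_peak``/``sox_tpeak``
#: place the quadratic Sox17 maximum; ``cx_*`` set the CXCR4 plateau, the
#: post-drop level and the linear-rise slope (per day); ``growth`` and
#: ``death`` are the day-4-normalized live and cumulative-dead series.
CONDITION_DEFAULTS: dict[str, dict] = {
    "A": dict(
        sox_peak=0.19, sox_tpeak=3.0,
        cx_plateau=0.15, cx_low=0.03, cx_slope=0.04,
        growth=(0.95, 0.89, 0.83, 0.78, 1.00, 1.22),
        death=(0.0, 0.25, 0.50, 0.75, 1.00, 1.25),
    ),
    "B": dict(
        sox_peak=0.23, sox_tpeak=2.0,
        cx_plateau=0.15, cx_low=0.02, cx_slope=0.09,
        growth=(0.52, 0.68, 0.86, 0.98, 1.00, 1.04),
        death=(0.0, 0.25, 0.50, 0.75, 1.00, 1.25),
    ),
}

DAYS = np.arange(6, dtype=float)


@dataclass
class ExperimentalDataset:
    """A daily (days 0-5) endoderm-induction time course.

    ``growth`` and ``death`` are day-4 normalized (equal to 1 at day 4);
    marker columns are fractions on [0, 1].  ``provenance`` distinguishes
    calibration curves from simulator-generated ground truth.
    """

    condition: str
    days: np.ndarray
    growth: np.ndarray
    death: np.ndarray
    frac_sox17: np.ndarray
    frac_cxcr4: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None
    provenance: str = "calibration"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "growth_norm": self.growth,
                "death_norm": self.death,
                "frac_sox17": self.frac_sox17,
                "frac_cxcr4": self.frac_cxcr4,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the table plus a JSON sidecar (condition, noise, seed,
        provenance) next to it."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "condition": self.condition,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "provenance": self.provenance,
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExperimentalDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(
            condition=sidecar.get("condition", "?"),
            days=frame["day"].to_numpy(float),
            growth=frame["growth_norm"].to_numpy(float),
            death=frame["death_norm"].to_numpy(float),
            frac_sox17=frame["frac_sox17"].to_numpy(float),
            frac_cxcr4=frame["frac_cxcr4"].to_numpy(float),
            noise_sd=sidecar.get("noise_sd", 0.0),
            seed=sidecar.get("seed"),
            provenance=sidecar.get("provenance", "calibration"),
            metadata=sidecar.get("metadata", {}),
        )


def generate_calibration_data(
    condition: str,
    noise_sd: float = 0.0,
    seed: int | None = None,
    overrides: dict | None = None,
) -> ExperimentalDataset:
    """Deterministic nominal calibration curves, optionally with per-point
    Gaussian noise.

    With ``noise_sd = 0`` repeated calls are bit-identical.  With noise, each
    point receives independent N(0, noise_sd) perturbations, after which
    fractions are clipped to [0, 1], the cumulative death series is made
    nondecreasing, and growth/death are renormalized so the day-4 value is
    exactly 1.
    """
    if condition not in CONDITION_DEFAULTS:
        raise ValueError(f"condition must be 'A' or 'B', got {condition!r}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    cfg = dict(CONDITION_DEFAULTS[condition])
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ValueError(f"unknown calibration overrides: {sorted(unknown)}")
        cfg.update(overrides)

    t = DAYS
    tp = cfg["sox_tpeak"]
    sox = np.clip(cfg["sox_peak"] * (1.0 - ((t - tp) / tp) ** 2), 0.0, 1.0)
    cx = np.where(t <= 2.0, cfg["cx_plateau"], cfg["cx_low"] + cfg["cx_slope"] * (t - 2.0))
    growth = np.asarray(cfg["growth"], float).copy()
    death = np.asarray(cfg["death"], float).copy()

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sox = np.clip(sox + rng.normal(0.0, noise_sd, 6), 0.0, 1.0)
        cx = np.clip(cx + rng.normal(0.0, noise_sd, 6), 0.0, 1.0)
        growth = np.maximum(growth + rng.normal(0.0, noise_sd, 6), 1e-6)
        death = np.maximum.accumulate(np.maximum(death + rng.normal(0.0, noise_sd, 6), 0.0))
        growth = growth / growth[4]
        if death[4] <= 0:
            death[4] = 1e-6
        death = death / death[4]

    return ExperimentalDataset(
        condition=condition,
        days=t.copy(),
        growth=growth,
        death=death,
        frac_sox17=sox,
        frac_cxcr4=np.clip(cx, 0.0, 1.0),
        noise_sd=noise_sd,
        seed=seed,
        provenance="calibration",
        metadata={"curve_config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}},
    )


def generate_ground_truth(
    params: ModelParams,
    mech: MechanismConfig | str,
    settings: SimulationSettings,
    condition: str = "A",
) -> ExperimentalDataset:
    """Simulate the model at known parameters and package the aggregated
    means as a dataset (day-4 normalized growth/death), for recovery tests.

    The generating parameter vector is recorded in ``metadata``.
    """
    mech = get_mechanism(mech)
    traj = simulate(params, mech, settings)
    growth = traj.day4_normalized_mean("live_count")
    dead_mean = traj.mean("cumulative_dead")
    j4 = np.flatnonzero(np.isclose(traj.days, 4.0))[0]
    if dead_mean[j4] == 0:
        raise UndefinedNormalizationError("no deaths by day 4; cannot normalize death series")
    death = dead_mean / dead_mean[j4]
    return ExperimentalDataset(
        condition=condition,
        days=traj.days.copy(),
        growth=growth,
        death=death,
        frac_sox17=traj.mean("frac_sox17"),
        frac_cxcr4=traj.mean("frac_cxcr4"),
        noise_sd=0.0,
        seed=settings.seed,
        provenance="ground-truth",
        metadata={"params": dict(params.flat_items()), "mechanism": mech.id},
    )


def validation_proxy(trajectories: TrajectorySet) -> pd.DataFrame:
    """Fraction-of-maximum curves of the undifferentiated (hESC) and
    mesendoderm live-population fractions.

    Each mean series is divided by its own maximum over days, mirroring the
    percent-of-maximum reporting of the Oct4/Brachyury validation read-out.
    """
    out = {"day": trajectories.days}
    for col, name in (("undifferentiated", "frac_hesc"), ("mesendoderm", "frac_mesendoderm")):
        series = trajectories.mean(name)
        peak = series.max()
        if peak <= 0:
            raise UndefinedNormalizationError(
                f"{name} series is identically zero; fraction-of-maximum undefined"
            )
        out[col] = series / peak
    return pd.DataFrame(out)
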