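"""Model parameters and simulation settings.

The stochastic differentiation model is controlled by two containers:

``ModelParams``
    The biological parameter vector: affinity thresholds and decay, commitment
    thresholds, cell-cycle and lifespan constants, propensity-update magnitudes
    (``nprog``) and the regime-transfer scale ``aa``.

``SimulationSettings``
    The numerical experiment: initial population size, number of stochastic
    replicate runs, time horizon and observation interval, and the RNG seed.

Both validate themselves eagerly and raise :class:`ConfigurationError` naming
the offending field, so bad configuration never reaches the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

from .mechanisms import Phenotype

__all__ = [
    "ConfigurationError",
    "ModelParams",
    "SimulationSettings",
    "PROPENSITY_INCREMENT",
    "SELECTION_FLOOR",
]


class ConfigurationError(ValueError):
    """A parameter or settings field violates a documented invariant."""


#: Base propensity increment per selected update (propensity units per G1 hour).
#: The per-lineage magnitude is ``PROPENSITY_INCREMENT * nprog[lineage]``, so the
#: tunable magnitude lives entirely in ``nprog`` and the commitment timescale in
#: ``x_com / (PROPENSITY_INCREMENT * nprog)`` G1 hours.
PROPENSITY_INCREMENT = 0.01

#: Exploration floor added to every competing lineage's selection weight so a
#: lineage with zero accumulated propensity can still be chosen.
SELECTION_FLOOR = 0.01


def _default_nprog_stage1() -> dict[Phenotype, float]:
    # MESENDODERM/VISCERAL_ENDODERM drive the two-stage scheme; the
    # DEFINITIVE_ENDODERM/MESODERM entries are read only by single-stage
    # (no-mesendoderm) mechanism variants.  Defaults deliberately avoid
    # x_com being an exact multiple of the increment, which would put the
    # commitment comparison on a floating-point boundary.
    return {
        Phenotype.MESENDODERM: 1.2,
        Phenotype.VISCERAL_ENDODERM: 0.6,
        Phenotype.DEFINITIVE_ENDODERM: 0.9,
        Phenotype.MESODERM: 0.9,
    }


def _default_nprog_stage2() -> dict[Phenotype, float]:
    return {
        Phenotype.DEFINITIVE_ENDODERM: 0.55,
        Phenotype.MESODERM: 2.6,
    }


@dataclass
class ModelParams:
    """Biological parameter vector of the population-based model.

    All times are in hours; affinity and propensity values are dimensionless.

    Parameters
    ----------
    a_min : float
        Affinity threshold. Crossing below it (while cycling in the active
        Ω regime) permanently unlocks proliferation and permanently blocks
        entry into the dormant A regime.
    a_0max : float
        Upper bound of the uniform initial-affinity draw for stage-1 cells.
    a_0max2 : float
        Upper bound of the re-initialized affinity drawn when a cell commits
        to mesendoderm (stage 2).
    x_com, x_com2 : float
        Lineage-propensity commitment thresholds for stage 1 / stage 2.
    d : float
        Multiplicative affinity decay per time step in the Ω regime
        (``a <- a / d``; must exceed 1).
    t_g1 : float
        Duration of the G1 phase within the cell cycle. Only in G1 can a cell
        update lineage propensities or transfer Ω -> A.
    t_cycle : float
        Total cell-cycle duration; a division opportunity arises each time the
        cycle position wraps.
    l_min, l_max : float
        Bounds of the uniform per-cell maximum-lifespan draw.
    w_max : float
        Upper bound of the per-cell proliferation-window draw (hours of
        proliferation competence before senescence).
    aa : float
        Scale factor of the Ω -> A transfer probability.
    n_scale : float
        Population scale of the crowding function
        ``f(N) = 1 / (1 + N / n_scale)`` applied to the destination-regime
        cell count in both transfer probabilities.  Sized well below the
        initial population so the dormant regime behaves as a
        capacity-limited niche rather than an unbounded reservoir.
    dt : float
        Simulation time step.
    nprog_stage1, nprog_stage2 : dict
        Per-lineage propensity-update magnitude factors for the two
        differentiation stages.
    """

    a_min: float = 0.04
    a_0max: float = 1.0
    a_0max2: float = 0.5
    x_com: float = 0.1
    x_com2: float = 0.1
    d: float = 1.07
    t_g1: float = 10.0
    t_cycle: float = 24.0
    l_min: float = 24.0
    l_max: float = 130.0
    w_max: float = 120.0
    aa: float = 0.4
    n_scale: float = 100.0
    dt: float = 1.0
    nprog_stage1: dict[Phenotype, float] = field(default_factory=_default_nprog_stage1)
    nprog_stage2: dict[Phenotype, float] = field(default_factory=_default_nprog_stage2)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.a_min < self.a_0max:
            raise ConfigurationError(
                f"require 0 < a_min < a_0max, got a_min={self.a_min}, a_0max={self.a_0max}"
            )
        if self.a_0max2 <= 0:
            raise ConfigurationError(f"a_0max2 must be > 0, got {self.a_0max2}")
        if self.d <= 1:
            raise ConfigurationError(f"d must be > 1 (affinity decay factor), got {self.d}")
        if not 0 < self.t_g1 <= self.t_cycle:
            raise ConfigurationError(
                f"require 0 < t_g1 <= t_cycle, got t_g1={self.t_g1}, t_cycle={self.t_cycle}"
            )
        if not 0 <= self.l_min < self.l_max:
            raise ConfigurationError(
                f"require 0 <= l_min < l_max, got l_min={self.l_min}, l_max={self.l_max}"
            )
        if self.w_max <= 0:
            raise ConfigurationError(f"w_max must be > 0, got {self.w_max}")
        if self.x_com <= 0:
            raise ConfigurationError(f"x_com must be > 0, got {self.x_com}")
        if self.x_com2 <= 0:
            raise ConfigurationError(f"x_com2 must be > 0, got {self.x_com2}")
        if self.aa < 0:
            raise ConfigurationError(f"aa must be >= 0, got {self.aa}")
        if self.n_scale <= 0:
            raise ConfigurationError(f"n_scale must be > 0, got {self.n_scale}")
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        for name, mapping in (("nprog_stage1", self.nprog_stage1), ("nprog_stage2", self.nprog_stage2)):
            for lin, v in mapping.items():
                if v < 0:
                    raise ConfigurationError(f"{name}[{Phenotype(lin).name}] must be >= 0, got {v}")

    # -- flat scalar view -------------------------------------------------
    # Used by the sensitivity analysis (one-at-a-time perturbation) and the
    # ensemble sampler, which both address parameters by name.

    _SCALARS = (
        "a_min", "a_0max", "a_0max2", "x_com", "x_com2", "d", "t_g1",
        "t_cycle", "l_min", "l_max", "w_max", "aa", "n_scale", "dt",
    )

    def flat_items(self) -> Iterator[tuple[str, float]]:
        """Yield every scalar parameter as a (name, value) pair.

        nprog entries are flattened as ``nprog1_<LINEAGE>`` / ``nprog2_<LINEAGE>``.
        """
        for name in self._SCALARS:
            yield name, float(getattr(self, name))
        for lin in sorted(self.nprog_stage1):
            yield f"nprog1_{Phenotype(lin).name}", float(self.nprog_stage1[lin])
        for lin in sorted(self.nprog_stage2):
            yield f"nprog2_{Phenotype(lin).name}", float(self.nprog_stage2[lin])

    def with_value(self, name: str, value: float) -> "ModelParams":
        """Return a copy with one flat-named scalar replaced."""
        if name.startswith("nprog1_") or name.startswith("nprog2_"):
            stage_attr = "nprog_stage1" if name[5] == "1" else "nprog_stage2"
            lin = Phenotype[name[7:]]
            mapping = dict(getattr(self, stage_attr))
            if lin not in mapping:
                raise ConfigurationError(f"unknown nprog entry {name!r}")
            mapping[lin] = value
            return replace(self, **{stage_attr: mapping})
        if name not in self._SCALARS:
            raise ConfigurationError(f"unknown parameter {name!r}")
        return replace(self, **{name: value})

    def perturbable_names(self) -> list[str]:
        """Parameters eligible for one-at-a-time perturbation.

        Every flat scalar except ``dt``: scaling the integrator step changes
        the time grid itself, so observation days would no longer align
        between nominal and perturbed simulations.
        """
        return [n for n, _ in self.flat_items() if n != "dt"]


@dataclass
class SimulationSettings:
    """Numerical settings of one stochastic simulation experiment."""

    n_initial: int = 1000
    n_runs: int = 100
    horizon: float = 120.0
    observation_interval: float = 24.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_initial < 1:
            raise ConfigurationError(f"n_initial must be >= 1, got {self.n_initial}")
        if self.n_runs < 1:
            raise ConfigurationError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.observation_interval <= 0:
            raise ConfigurationError(
                f"observation_interval must be > 0, got {self.observation_interval}"
            )
        n = self.horizon / self.observation_interval
        if self.horizon <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "horizon must be a positive multiple of observation_interval, "
                f"got horizon={self.horizon}, observation_interval={self.observation_interval}"
            )
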