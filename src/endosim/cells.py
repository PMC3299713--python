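"""Single-cell state and the per-cell update rules.

This module is the contract surface of the stochastic model at the level of
one cell: regime transfer, affinity decay, propensity updating, commitment,
aging/death and division.  Each operation is a pure function returning new
:class:`CellState` objects.  The production simulator (:mod:`endosim.engine`)
applies the same rules vectorized over whole populations; the scalar forms
here are the readable reference used in unit tests and documentation.

Biology in brief: every cell carries an affinity value ``a`` that decays
multiplicatively while the cell is in the active Ω regime and is frozen in the
dormant A regime.  High-affinity cells can shelter in A (no aging, no cycling,
no differentiation); once ``a`` drops below ``a_min`` the cell can never enter
A again and instead becomes proliferation-competent.  Differentiation is a
race of per-lineage propensity accumulators updated during G1 in Ω; crossing
the commitment threshold irreversibly fixes the phenotype.  Committing to
mesendoderm starts a second stage with re-initialized affinity and a fresh
endoderm-versus-mesoderm race.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .mechanisms import (
    MechanismConfig,
    Phenotype,
    TERMINAL,
    get_mechanism,
    proliferation_allowed,
)
from .params import (
    ModelParams,
    PROPENSITY_INCREMENT,
    SELECTION_FLOOR,
    SimulationSettings,
)

__all__ = [
    "Regime",
    "CellState",
    "ContractViolationError",
    "init_population",
    "update_affinity",
    "transfer_step",
    "propensity_update",
    "commit_cell",
    "death_and_proliferation_step",
    "crowding",
]


class Regime(Enum):
    OMEGA = "OMEGA"
    A = "A"


class ContractViolationError(RuntimeError):
    """An operation was invoked on a cell violating its precondition."""


@dataclass
class CellState:
    """One simulated cell."""

    regime: Regime = Regime.OMEGA
    a_value: float = 1.0
    age: float = 0.0
    life_span: float = 100.0
    cycle_position: float = 0.0
    proliferation_competent: bool = False
    proliferation_clock: float = 0.0
    proliferation_window: float = 100.0
    phenotype: Phenotype = Phenotype.HESC
    stage: int = 1
    propensities: dict[Phenotype, float] = field(default_factory=dict)

    @property
    def committed(self) -> bool:
        """Committed at the current stage (i.e. of terminal phenotype);
        hESC and mesendoderm are the uncommitted pools of stages 1 and 2."""
        return self.phenotype in TERMINAL


def _in_g1(cell: CellState, params: ModelParams) -> bool:
    return cell.cycle_position < params.t_g1


def crowding(n_destination: float, params: ModelParams) -> float:
    """Crowding factor ``f(N) = 1 / (1 + N / n_scale)`` of the destination
    regime; decreasing in the destination count, 1 when empty."""
    return 1.0 / (1.0 + n_destination / params.n_scale)


def init_population(
    settings: SimulationSettings,
    params: ModelParams,
    rng: np.random.Generator,
    mech: MechanismConfig | str = "ME+/CX-/EU",
) -> list[CellState]:
    """Create the initial population: all hESC, stage 1, in Ω, age 0.

    Affinity is uniform on (0, a_0max]; lifespan uniform on [l_min, l_max];
    proliferation window uniform on (0, w_max]; cycle position uniform on
    [0, t_cycle).  Propensities start at zero over the stage-1 lineage set of
    the mechanism.
    """
    params.validate()
    settings.validate()
    mech = get_mechanism(mech)
    slots = mech.lineage_slots(1)
    cells = []
    for _ in range(settings.n_initial):
        cells.append(
            CellState(
                regime=Regime.OMEGA,
                a_value=params.a_0max * (1.0 - rng.random()),
                age=0.0,
                life_span=rng.uniform(params.l_min, params.l_max),
                cycle_position=params.t_cycle * rng.random(),
                proliferation_competent=False,
                proliferation_clock=0.0,
                proliferation_window=params.w_max * (1.0 - rng.random()),
                phenotype=Phenotype.HESC,
                stage=1,
                propensities={lin: 0.0 for lin in slots},
            )
        )
    return cells


def update_affinity(cell: CellState, params: ModelParams) -> CellState:
    """One time step of affinity dynamics.

    In A the affinity is unaltered.  In Ω it decays by the factor ``d``; the
    first time it falls below ``a_min`` the cell is latched
    proliferation-competent permanently (and can never re-enter A).
    """
    if cell.regime is Regime.A:
        return cell
    a = cell.a_value / params.d
    competent = cell.proliferation_competent or a < params.a_min
    return replace(cell, a_value=a, proliferation_competent=competent)


def transfer_step(
    cell: CellState,
    n_omega: int,
    n_a: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> CellState:
    """Attempt a regime transfer for one time step.

    Ω -> A only during G1 and only while ``a >= a_min``, with probability
    ``min(1, aa * (a / a_0max) * f(n_a))``.  On transfer the uncommitted
    propensities collapse to their arithmetic mean.  A -> Ω with probability
    ``min(1, (a_min / a) * f(n_omega))``: the lower the affinity, the sooner a
    dormant cell rejoins the active pool.
    """
    if cell.regime is Regime.OMEGA:
        if cell.a_value < params.a_min or not _in_g1(cell, params):
            return cell
        p = min(1.0, params.aa * (cell.a_value / params.a_0max) * crowding(n_a, params))
        if rng.random() < p:
            props = cell.propensities
            if not cell.committed and props:
                mean = sum(props.values()) / len(props)
                props = {lin: mean for lin in props}
            return replace(cell, regime=Regime.A, propensities=props)
        return cell
    q = min(1.0, (params.a_min / cell.a_value) * crowding(n_omega, params))
    if rng.random() < q:
        return replace(cell, regime=Regime.OMEGA)
    return cell


def propensity_update(
    cell: CellState,
    params: ModelParams,
    mech: MechanismConfig | str,
    rng: np.random.Generator,
) -> CellState:
    """One propensity-update step for an uncommitted cell.

    No-op unless the cell is in Ω and in G1.  Otherwise exactly one competing
    lineage is selected with probability proportional to
    ``propensity + SELECTION_FLOOR`` and incremented by
    ``PROPENSITY_INCREMENT * nprog[lineage]``.  Propensities never decrease
    in Ω.  Commitment itself is a separate step (:func:`commit_cell`).
    """
    if cell.committed:
        raise ContractViolationError("propensity_update called on a committed cell")
    if cell.regime is not Regime.OMEGA or not _in_g1(cell, params):
        return cell
    mech = get_mechanism(mech)
    slots = mech.lineage_slots(cell.stage)
    nprog = params.nprog_stage1 if cell.stage == 1 else params.nprog_stage2
    weights = np.array([cell.propensities.get(lin, 0.0) + SELECTION_FLOOR for lin in slots])
    u = rng.random() * weights.sum()
    chosen = slots[int(np.searchsorted(np.cumsum(weights), u, side="right"))]
    props = dict(cell.propensities)
    props[chosen] = props.get(chosen, 0.0) + PROPENSITY_INCREMENT * nprog[chosen]
    return replace(cell, propensities=props)


def commit_cell(
    cell: CellState,
    lineage: Phenotype,
    params: ModelParams,
    rng: np.random.Generator,
) -> CellState:
    """Commit a cell whose propensity for ``lineage`` reached the stage
    threshold.

    Mesendoderm commitment opens stage 2: the affinity is redrawn uniformly
    on (0, a_0max2], proliferation competence and clock reset, and the
    propensity race restarts at zero over {definitive endoderm, mesoderm}.
    Terminal lineages freeze the propensity map and phenotype permanently.
    """
    threshold = params.x_com if cell.stage == 1 else params.x_com2
    if cell.propensities.get(lineage, 0.0) < threshold:
        raise ContractViolationError(
            f"commitment to {lineage.name} below threshold "
            f"({cell.propensities.get(lineage, 0.0)} < {threshold})"
        )
    if lineage is Phenotype.MESENDODERM:
        return replace(
            cell,
            phenotype=Phenotype.MESENDODERM,
            stage=2,
            a_value=params.a_0max2 * (1.0 - rng.random()),
            proliferation_competent=False,
            proliferation_clock=0.0,
            propensities={Phenotype.DEFINITIVE_ENDODERM: 0.0, Phenotype.MESODERM: 0.0},
        )
    return replace(cell, phenotype=lineage)


def death_and_proliferation_step(
    cell: CellState,
    params: ModelParams,
    mech: MechanismConfig | str,
    rng: np.random.Generator,
) -> list[CellState]:
    """Aging, death and division for one time step.

    Returns ``[]`` if the cell died, ``[cell]`` if unchanged/aged, and
    ``[cell, daughter]`` on division.

    In A the cell is frozen: it neither ages, cycles, nor divides.  In Ω the
    cell ages by ``dt`` and dies when age exceeds its lifespan.  Division
    requires the cycle position wrapping past ``t_cycle`` while the cell is
    proliferation-competent, within its proliferation window (senescence
    limit), and of a phenotype the mechanism allows to proliferate.  The
    daughter inherits phenotype, stage, propensities and affinity; age and
    cycle restart at zero and lifespan/window are freshly drawn.
    """
    if cell.regime is Regime.A:
        return [cell]
    mech = get_mechanism(mech)
    age = cell.age + params.dt
    if age > cell.life_span:
        return []
    clock = cell.proliferation_clock + (params.dt if cell.proliferation_competent else 0.0)
    cyc = cell.cycle_position + params.dt
    divide = False
    if cyc >= params.t_cycle:
        cyc -= params.t_cycle
        divide = (
            cell.proliferation_competent
            and clock <= cell.proliferation_window
            and proliferation_allowed(cell.phenotype, mech)
        )
    mother = replace(cell, age=age, proliferation_clock=clock, cycle_position=cyc)
    if not divide:
        return [mother]
    daughter = replace(
        mother,
        age=0.0,
        cycle_position=0.0,
        proliferation_clock=0.0,
        life_span=rng.uniform(params.l_min, params.l_max),
        proliferation_window=params.w_max * (1.0 - rng.random()),
        propensities=dict(mother.propensities),
    )
    return [mother, daughter]
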