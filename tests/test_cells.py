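"""Single-cell rule contracts: initialization, affinity, transfers,
propensity competition, commitment, death and division."""

import dataclasses

import numpy as np
import pytest

from endosim import (
    CellState,
    ModelParams,
    Phenotype,
    Regime,
    SimulationSettings,
    commit_cell,
    death_and_proliferation_step,
    init_population,
    propensity_update,
    transfer_step,
    update_affinity,
)
from endosim.cells import ContractViolationError


class TestInitPopulation:
    def test_initial_state_contract(self, params, rng):
        settings = SimulationSettings(n_initial=500, n_runs=1, seed=0)
        cells = init_population(settings, params, rng)
        assert len(cells) == 500
        for c in cells:
            assert c.phenotype is Phenotype.HESC
            assert c.regime is Regime.OMEGA
            assert c.stage == 1
            assert c.age == 0.0
            assert 0.0 < c.a_value <= params.a_0max
            assert params.l_min <= c.life_span <= params.l_max
            assert 0.0 < c.proliferation_window <= params.w_max
            assert 0.0 <= c.cycle_position < params.t_cycle
            assert all(v == 0.0 for v in c.propensities.values())
            assert not c.proliferation_competent

    def test_seed_determinism(self, params):
        settings = SimulationSettings(n_initial=100, n_runs=1, seed=0)
        a = init_population(settings, params, np.random.default_rng(42))
        b = init_population(settings, params, np.random.default_rng(42))
        c = init_population(settings, params, np.random.default_rng(43))
        assert [x.a_value for x in a] == [x.a_value for x in b]
        assert sorted(x.a_value for x in a) != sorted(x.a_value for x in c)


class TestUpdateAffinity:
    def test_unaltered_in_a_regime(self, params):
        cell = CellState(regime=Regime.A, a_value=0.5)
        p = dataclasses.replace(params, d=1.1)
        assert update_affinity(cell, p).a_value == 0.5

    def test_closed_form_decay_in_omega(self, params):
        p = dataclasses.replace(params, d=2.0)
        cell = CellState(regime=Regime.OMEGA, a_value=1.0)
        for _ in range(3):
            cell = update_affinity(cell, p)
        assert cell.a_value == pytest.approx(0.125)

    def test_competence_latch_is_permanent(self, params):
        cell = CellState(regime=Regime.OMEGA, a_value=params.a_min * 1.5)
        p = dataclasses.replace(params, d=2.0)
        while not cell.proliferation_competent:
            cell = update_affinity(cell, p)
        # latched: stays competent even if the affinity threshold later drops
        p2 = dataclasses.replace(params, a_min=1e-9)
        for _ in range(5):
            cell = update_affinity(cell, p2)
            assert cell.proliferation_competent


class TestTransferStep:
    def test_no_a_entry_below_threshold(self, params, rng):
        cell = CellState(regime=Regime.OMEGA, a_value=params.a_min / 2, cycle_position=0.0)
        for _ in range(200):
            assert transfer_step(cell, 10, 10, params, rng).regime is Regime.OMEGA

    def test_no_transfer_outside_g1(self, params, rng):
        p = dataclasses.replace(params, aa=1e9)  # would otherwise transfer surely
        cell = CellState(regime=Regime.OMEGA, a_value=0.5, cycle_position=params.t_g1)
        for _ in range(50):
            assert transfer_step(cell, 10, 0, p, rng).regime is Regime.OMEGA

    def test_propensity_averaging_on_entry(self, params, rng):
        p = dataclasses.replace(params, aa=1e9)  # p = 1 with empty destination
        cell = CellState(
            regime=Regime.OMEGA,
            a_value=0.5,
            cycle_position=0.0,
            propensities={Phenotype.MESENDODERM: 0.2, Phenotype.VISCERAL_ENDODERM: 0.4},
        )
        out = transfer_step(cell, 100, 0, p, rng)
        assert out.regime is Regime.A
        assert out.propensities == {
            Phenotype.MESENDODERM: pytest.approx(0.3),
            Phenotype.VISCERAL_ENDODERM: pytest.approx(0.3),
        }

    def test_certain_return_at_threshold_affinity(self, params, rng):
        # q = (a_min / a) * f(n_omega) = 1 when a = a_min and the Omega regime is empty
        cell = CellState(regime=Regime.A, a_value=params.a_min)
        out = transfer_step(cell, 0, 5, params, rng)
        assert out.regime is Regime.OMEGA


class TestPropensityUpdate:
    def test_frozen_in_a_regime(self, params, rng):
        cell = CellState(regime=Regime.A, a_value=0.5, cycle_position=0.0,
                         propensities={Phenotype.MESENDODERM: 0.1,
                                       Phenotype.VISCERAL_ENDODERM: 0.2})
        out = propensity_update(cell, params, "ME+/CX-/EU", rng)
        assert out.propensities == cell.propensities

    def test_zero_magnitude_never_advances(self, params, rng):
        p = dataclasses.replace(
            params,
            nprog_stage1={lin: 0.0 for lin in params.nprog_stage1},
            nprog_stage2={lin: 0.0 for lin in params.nprog_stage2},
        )
        cell = CellState(regime=Regime.OMEGA, a_value=0.5, cycle_position=0.0,
                         propensities={Phenotype.MESENDODERM: 0.0,
                                       Phenotype.VISCERAL_ENDODERM: 0.0})
        for _ in range(100):
            cell = propensity_update(cell, p, "ME+/CX-/EU", rng)
        assert all(v == 0.0 for v in cell.propensities.values())

    def test_leader_selected_preferentially(self, params, rng):
        # weights (0.9*x_com + eps) vs eps: the leader should win ~99% of updates
        base = {Phenotype.MESENDODERM: 0.9 * params.x_com,
                Phenotype.VISCERAL_ENDODERM: 0.0}
        wins = 0
        for _ in range(300):
            cell = CellState(regime=Regime.OMEGA, a_value=0.5, cycle_position=0.0,
                             propensities=dict(base))
            out = propensity_update(cell, params, "ME+/CX-/EU", rng)
            if out.propensities[Phenotype.MESENDODERM] > base[Phenotype.MESENDODERM]:
                wins += 1
        assert wins > 200

    def test_committed_cell_rejected(self, params, rng):
        cell = CellState(regime=Regime.OMEGA, phenotype=Phenotype.MESODERM)
        with pytest.raises(ContractViolationError):
            propensity_update(cell, params, "ME+/CX-/EU", rng)


class TestCommitCell:
    def test_below_threshold_rejected(self, params, rng):
        cell = CellState(propensities={Phenotype.MESENDODERM: 0.5 * params.x_com})
        with pytest.raises(ContractViolationError):
            commit_cell(cell, Phenotype.MESENDODERM, params, rng)

    def test_mesendoderm_reinitializes_stage_two(self, params, rng):
        cell = CellState(
            a_value=0.9,
            proliferation_competent=True,
            proliferation_clock=30.0,
            propensities={Phenotype.MESENDODERM: params.x_com,
                          Phenotype.VISCERAL_ENDODERM: 0.4},
        )
        out = commit_cell(cell, Phenotype.MESENDODERM, params, rng)
        assert out.phenotype is Phenotype.MESENDODERM
        assert out.stage == 2
        assert 0.0 < out.a_value <= params.a_0max2
        assert not out.proliferation_competent
        assert out.propensities == {Phenotype.DEFINITIVE_ENDODERM: 0.0,
                                    Phenotype.MESODERM: 0.0}

    def test_terminal_commitment_is_absorbing(self, params, rng):
        cell = CellState(stage=2,
                         propensities={Phenotype.MESODERM: params.x_com2,
                                       Phenotype.DEFINITIVE_ENDODERM: 0.1})
        out = commit_cell(cell, Phenotype.MESODERM, params, rng)
        assert out.phenotype is Phenotype.MESODERM
        with pytest.raises(ContractViolationError):
            propensity_update(out, params, "ME+/CX-/EU", rng)


class TestDeathAndProliferation:
    def test_a_regime_is_frozen(self, params, rng):
        cell = CellState(regime=Regime.A, age=50.0, life_span=10.0)
        for _ in range(200):  # would long be dead in Omega
            (cell,) = death_and_proliferation_step(cell, params, "ME+/CX-/EU", rng)
        assert cell.age == 50.0

    def test_death_past_lifespan(self, params, rng):
        cell = CellState(regime=Regime.OMEGA, age=10.0, life_span=10.5)
        assert death_and_proliferation_step(cell, params, "ME+/CX-/EU", rng) == []

    def test_noncompetent_cell_never_divides(self, params, rng):
        cell = CellState(regime=Regime.OMEGA, a_value=1.0, age=0.0, life_span=1e6,
                         cycle_position=0.0, proliferation_competent=False)
        for _ in range(int(3 * params.t_cycle)):
            out = death_and_proliferation_step(cell, params, "ME+/CX-/EU", rng)
            assert len(out) == 1
            cell = out[0]

    @pytest.mark.parametrize(
        "mech,divides", [("ME+/CX+/A", True), ("ME+/CX-/EU", False), ("ME+/CX-/U", False)]
    )
    def test_mesoderm_division_gated_by_scope(self, params, rng, mech, divides):
        cell = CellState(
            regime=Regime.OMEGA, a_value=0.01, age=0.0, life_span=1e6,
            cycle_position=params.t_cycle - 0.5, proliferation_competent=True,
            proliferation_clock=0.0, proliferation_window=1e6,
            phenotype=Phenotype.MESODERM,
        )
        out = death_and_proliferation_step(cell, params, mech, rng)
        assert (len(out) == 2) is divides
        if divides:
            daughter = out[1]
            assert daughter.age == 0.0
            assert daughter.cycle_position == 0.0
            assert daughter.phenotype is Phenotype.MESODERM
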