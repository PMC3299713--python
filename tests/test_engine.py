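"""Population-simulator behavior: bookkeeping, determinism, degenerate
populations, and agreement between the compiled kernel and the checked
reference implementation."""

import dataclasses
import logging

import numpy as np
import pytest

from endosim import ModelParams, Phenotype, SimulationSettings, simulate, simulate_run


def zero_nprog(params):
    return dataclasses.replace(
        params,
        nprog_stage1={lin: 0.0 for lin in params.nprog_stage1},
        nprog_stage2={lin: 0.0 for lin in params.nprog_stage2},
    )


@pytest.mark.parametrize("checked", [False, True])
def test_conservation_and_shapes(params, tiny_settings, checked):
    traj = simulate(params, "ME+/CX-/EU", tiny_settings, check_invariants=checked)
    assert traj.n_obs == 6
    assert np.allclose(traj.days, np.arange(6))
    # live + cumulative dead - divisions = initial, every run, every day
    assert (traj.live + traj.cumulative_dead - traj.divisions
            == tiny_settings.n_initial).all()
    assert (np.diff(traj.cumulative_dead, axis=1) >= 0).all()
    assert (traj.frac_sox17 >= 0).all() and (traj.frac_sox17 <= 1).all()
    assert (traj.frac_cxcr4 >= 0).all() and (traj.frac_cxcr4 <= 1).all()
    fracs = np.stack([traj.output(f"frac_{p.name.lower()}") for p in Phenotype])
    occupied = traj.live > 0
    assert np.allclose(fracs.sum(axis=0)[occupied], 1.0)


@pytest.mark.parametrize("checked", [False, True])
def test_same_seed_bit_identical(params, tiny_settings, checked):
    t1 = simulate(params, "ME+/CX-/EU", tiny_settings, check_invariants=checked)
    t2 = simulate(params, "ME+/CX-/EU", tiny_settings, check_invariants=checked)
    assert (t1.live == t2.live).all()
    assert (t1.phenotype_counts == t2.phenotype_counts).all()
    assert np.array_equal(t1.frac_cxcr4, t2.frac_cxcr4)


def test_different_seeds_differ(params, tiny_settings):
    other = dataclasses.replace(tiny_settings, seed=tiny_settings.seed + 1)
    t1 = simulate(params, "ME+/CX-/EU", tiny_settings)
    t2 = simulate(params, "ME+/CX-/EU", other)
    assert not (t1.live == t2.live).all()


def test_zero_update_magnitude_blocks_all_commitment(params, tiny_settings):
    traj = simulate(zero_nprog(params), "ME+/CX-/EU", tiny_settings)
    assert (traj.frac_sox17 == 0).all()
    assert (traj.frac_cxcr4 == 0).all()
    assert (traj.output("frac_hesc")[traj.live > 0] == 1.0).all()


def test_no_death_all_scope_population_nondecreasing(params, tiny_settings):
    p = dataclasses.replace(params, l_max=1e7, l_min=1e6)
    traj = simulate(p, "ME+/CX+/A", tiny_settings)
    assert (np.diff(traj.live, axis=1) >= 0).all()
    assert (traj.cumulative_dead == 0).all()


def test_extinct_run_zero_filled_with_warning(params, caplog):
    # lifespans shorter than one day kill every cell before the first
    # snapshot; aa = 0 so none can hide (unaging) in the dormant regime
    p = dataclasses.replace(params, l_min=1.0, l_max=2.0, aa=0.0)
    settings = SimulationSettings(n_initial=50, n_runs=3, seed=0)
    with caplog.at_level(logging.WARNING, logger="endosim.engine"):
        traj = simulate(p, "ME+/CX-/EU", settings)
    assert (traj.live[:, -1] == 0).all()
    assert (traj.frac_sox17[:, -1] == 0).all()
    assert (traj.live + traj.cumulative_dead - traj.divisions == 50).all()
    assert any("extinct" in r.message for r in caplog.records)


def test_kernel_agrees_with_checked_reference(params):
    """The compiled kernel and the instrumented numpy path implement the same
    rules; their aggregated outputs must agree within Monte-Carlo error."""
    settings = SimulationSettings(n_initial=500, n_runs=40, seed=11)
    fast = simulate(params, "ME+/CX-/EU", settings)
    ref = simulate(params, "ME+/CX-/EU", settings, check_invariants=True)
    for name, tol in [("frac_sox17", 0.03), ("frac_cxcr4", 0.03), ("frac_hesc", 0.03)]:
        assert np.abs(fast.mean(name) - ref.mean(name)).max() < tol, name
    assert np.abs(fast.mean("live_count") / ref.mean("live_count") - 1).max() < 0.05


def test_simulate_run_single_replicate(params, rng):
    settings = SimulationSettings(n_initial=200, n_runs=1, seed=3)
    traj = simulate_run(params, "ME+/CX-/EU", settings, rng)
    assert traj.n_runs == 1
    assert (traj.live + traj.cumulative_dead - traj.divisions == 200).all()
    again = simulate_run(params, "ME+/CX-/EU", settings, np.random.default_rng(1234))
    assert (traj.live == again.live).all()  # same generator state -> identical


def test_aggregation_helpers(params, tiny_settings):
    traj = simulate(params, "ME+/CX-/EU", tiny_settings)
    assert traj.mean("live_count").shape == (6,)
    assert traj.sd("frac_cxcr4").shape == (6,)
    assert traj.day_sample("frac_cxcr4", 5.0).shape == (tiny_settings.n_runs,)
    g = traj.day4_normalized_mean("live_count")
    assert g[4] == pytest.approx(1.0)
    frame = traj.to_frame()
    assert list(frame["run_id"].unique()) == ["mean", "sd"]
    assert {"day", "live_count", "cumulative_dead", "frac_sox17", "frac_cxcr4",
            "frac_hesc", "frac_mesendoderm", "frac_visceral_endoderm",
            "frac_definitive_endoderm", "frac_mesoderm"} <= set(frame.columns)
    with pytest.raises(KeyError):
        traj.output("nope")


def test_invalid_grid_rejected(params):
    from endosim import ConfigurationError

    with pytest.raises(ConfigurationError):
        SimulationSettings(n_initial=10, n_runs=1, horizon=100.0,
                           observation_interval=24.0)
    bad_dt = dataclasses.replace(params, dt=7.0)  # 24 h not a multiple of 7
    with pytest.raises(ConfigurationError):
        simulate(bad_dt, "ME+/CX-/EU", SimulationSettings(n_initial=10, n_runs=1, seed=0))
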