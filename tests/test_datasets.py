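"""Synthetic calibration curves, ground-truth wrapping and validation proxies."""

import numpy as np
import pytest

from endosim import (
    ModelParams,
    SimulationSettings,
    generate_calibration_data,
    generate_ground_truth,
    simulate,
    trajectory_error,
    validation_proxy,
)
from endosim.datasets import UndefinedNormalizationError
from endosim.engine import TrajectorySet


class TestCalibrationData:
    @pytest.mark.parametrize("condition,peak,tpeak", [("A", 0.19, 3), ("B", 0.23, 2)])
    def test_sox17_quadratic_peak(self, condition, peak, tpeak):
        ds = generate_calibration_data(condition, noise_sd=0.0)
        assert ds.frac_sox17[0] == 0.0
        assert ds.frac_sox17.max() == pytest.approx(peak)
        assert int(np.argmax(ds.frac_sox17)) == tpeak
        assert 0.19 <= ds.frac_sox17.max() <= 0.23

    @pytest.mark.parametrize("condition", ["A", "B"])
    def test_cxcr4_plateau_drop_then_rise(self, condition):
        ds = generate_calibration_data(condition, noise_sd=0.0)
        cx = ds.frac_cxcr4
        assert cx[0] == cx[1] == cx[2]  # flat until day 2
        assert cx[3] < cx[2]  # pronounced drop after day 2
        assert cx[5] > cx[4] > cx[3]  # then an approximately linear rise
    def test_condition_b_rise_steeper(self):
        a = generate_calibration_data("A").frac_cxcr4
        b = generate_calibration_data("B").frac_cxcr4
        assert (b[5] - b[3]) > (a[5] - a[3])

    def test_growth_shapes(self):
        a = generate_calibration_data("A").growth
        assert (np.diff(a[:4]) < 0).all()  # proliferation lag until day 3
        assert a[5] > a[4] > a[3]
        b = generate_calibration_data("B").growth
        assert (b[3] - b[0]) > (b[5] - b[3])  # most growth before day 3

    def test_death_linear_and_day4_normalized(self):
        for cond in "AB":
            ds = generate_calibration_data(cond)
            assert np.allclose(np.diff(ds.death), ds.death[1] - ds.death[0])
            assert ds.death[4] == pytest.approx(1.0)
            assert ds.growth[4] == pytest.approx(1.0)
            assert (np.diff(ds.death) >= 0).all()

    def test_noise_free_determinism(self):
        d1 = generate_calibration_data("A")
        d2 = generate_calibration_data("A")
        assert np.array_equal(d1.frac_sox17, d2.frac_sox17)
        assert np.array_equal(d1.growth, d2.growth)

    def test_noisy_data_respects_ranges(self):
        ds = generate_calibration_data("A", noise_sd=0.05, seed=3)
        again = generate_calibration_data("A", noise_sd=0.05, seed=3)
        assert np.array_equal(ds.frac_cxcr4, again.frac_cxcr4)
        assert ((ds.frac_sox17 >= 0) & (ds.frac_sox17 <= 1)).all()
        assert (np.diff(ds.death) >= 0).all()
        assert ds.death[4] == pytest.approx(1.0)
        assert ds.growth[4] == pytest.approx(1.0)
        assert not np.array_equal(
            ds.frac_sox17, generate_calibration_data("A").frac_sox17
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_calibration_data("C")
        with pytest.raises(ValueError):
            generate_calibration_data("A", noise_sd=-0.1)
        with pytest.raises(ValueError, match="unknown calibration overrides"):
            generate_calibration_data("A", overrides={"nope": 1})

    def test_csv_round_trip(self, tmp_path):
        from endosim import ExperimentalDataset

        ds = generate_calibration_data("B", noise_sd=0.02, seed=9)
        path = tmp_path / "cal.csv"
        ds.to_csv(path)
        back = ExperimentalDataset.from_csv(path)
        assert back.condition == "B"
        assert back.noise_sd == 0.02
        assert np.allclose(back.frac_sox17, ds.frac_sox17)
        assert back.provenance == "calibration"


class TestGroundTruth:
    def test_wraps_simulator_means(self, params):
        settings = SimulationSettings(n_initial=300, n_runs=8, seed=2)
        ds = generate_ground_truth(params, "ME+/CX-/EU", settings)
        traj = simulate(params, "ME+/CX-/EU", settings)  # same seed -> same sim
        assert np.allclose(ds.frac_sox17, traj.mean("frac_sox17"))
        assert np.allclose(ds.frac_cxcr4, traj.mean("frac_cxcr4"))
        assert ds.growth[4] == pytest.approx(1.0)
        assert ds.provenance == "ground-truth"
        assert ds.metadata["params"]["a_min"] == params.a_min
        # self-consistency: the generating simulation scores an exact zero
        assert trajectory_error(traj, ds) == pytest.approx(0.0, abs=1e-12)


def _constant_traj(hesc_frac=0.5, me_frac=0.25):
    days = np.arange(6.0)
    live = np.full((1, 6), 100, dtype=int)
    counts = np.zeros((1, 6, 5), dtype=int)
    counts[0, :, 0] = int(100 * hesc_frac)
    counts[0, :, 1] = int(100 * me_frac)
    counts[0, :, 4] = 100 - counts[0, 0, 0] - counts[0, 0, 1]
    return TrajectorySet(
        days=days, live=live, cumulative_dead=np.zeros((1, 6), int),
        divisions=np.zeros((1, 6), int), phenotype_counts=counts,
        frac_sox17=np.zeros((1, 6)), frac_cxcr4=np.zeros((1, 6)),
        mechanism="ME+/CX-/EU", n_initial=100,
    )


class TestValidationProxy:
    def test_constant_series_normalizes_to_one(self):
        proxy = validation_proxy(_constant_traj())
        assert np.allclose(proxy["undifferentiated"], 1.0)
        assert np.allclose(proxy["mesendoderm"], 1.0)

    def test_unique_maximum_day(self):
        traj = _constant_traj()
        traj.phenotype_counts[0, 1, 1] = 80  # mesendoderm spike at day 1
        proxy = validation_proxy(traj)
        assert proxy["mesendoderm"][1] == pytest.approx(1.0)
        assert (proxy["mesendoderm"].drop(1) < 1.0).all()

    def test_all_zero_series_rejected(self):
        traj = _constant_traj(hesc_frac=0.0, me_frac=0.0)
        with pytest.raises(UndefinedNormalizationError):
            validation_proxy(traj)
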