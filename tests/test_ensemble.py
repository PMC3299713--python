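"""Parameter-space sampling, the marker error functional, and the
sklearn-style ensemble fitting surface."""

import numpy as np
import pytest
from sklearn.base import clone

from endosim import (
    ConfigurationError,
    EnsembleFitter,
    ModelParams,
    ParameterSpace,
    SimulationSettings,
    generate_calibration_data,
    run_ensemble,
    sample_parameter_space,
    trajectory_error,
)
from endosim.datasets import ExperimentalDataset
from endosim.ensemble import AlignmentError


class TestParameterSpace:
    def test_default_space_sensitive_names(self):
        me = ParameterSpace.default(ModelParams(), "ME+/CX-/EU")
        assert {"a_min", "a_0max", "x_com", "d", "t_g1", "l_max", "aa",
                "a_0max2", "x_com2"} <= set(me.names)
        assert "nprog2_MESODERM" in me.names
        no_me = ParameterSpace.default(ModelParams(), "ME-/CX-/EU")
        assert "x_com2" not in no_me.names
        assert "nprog1_DEFINITIVE_ENDODERM" in no_me.names

    def test_bounds_validation(self):
        with pytest.raises(ConfigurationError):
            ParameterSpace(bounds={"a_min": (0.5, 0.1)})
        with pytest.raises(ConfigurationError):
            ParameterSpace(bounds={"not_a_param": (0.0, 1.0)})

    def test_to_params_resolves_cross_constraints(self):
        space = ParameterSpace.default()
        p = space.to_params({"a_min": 0.4, "a_0max": 0.2})
        assert p.a_min < p.a_0max
        p = space.to_params({"t_g1": 23.0})
        assert p.t_g1 <= p.t_cycle

    def test_sampling_contract(self):
        space = ParameterSpace.default()
        m = sample_parameter_space(space, 200, seed=4)
        assert m.shape == (200, len(space.names))
        for name in space.names:
            lo, hi = space.bounds[name]
            assert ((m[name] >= lo) & (m[name] <= hi)).all()
        again = sample_parameter_space(space, 200, seed=4)
        assert m.equals(again)
        assert not m.equals(sample_parameter_space(space, 200, seed=5))


class TestTrajectoryError:
    def test_zero_on_identical_curves(self):
        ds = generate_calibration_data("A")
        assert trajectory_error(ds, ds) == 0.0

    def test_constant_offset(self):
        ds = generate_calibration_data("A")
        shifted = ExperimentalDataset(
            condition="A", days=ds.days, growth=ds.growth, death=ds.death,
            frac_sox17=ds.frac_sox17 + 0.1, frac_cxcr4=ds.frac_cxcr4 + 0.1,
        )
        # each residual contributes 0.01 in both outputs: mean stays 0.01
        assert trajectory_error(shifted, ds) == pytest.approx(0.01)

    def test_day_mismatch_rejected(self):
        ds = generate_calibration_data("A")
        truncated = ExperimentalDataset(
            condition="A", days=ds.days[:5], growth=ds.growth[:5],
            death=ds.death[:5], frac_sox17=ds.frac_sox17[:5],
            frac_cxcr4=ds.frac_cxcr4[:5],
        )
        with pytest.raises(AlignmentError):
            trajectory_error(ds, truncated)

    def test_invariant_to_growth_rescaling(self):
        # only marker fractions enter the fit; growth/death are verification
        ds = generate_calibration_data("A")
        rescaled = ExperimentalDataset(
            condition="A", days=ds.days, growth=ds.growth * 7.0,
            death=ds.death * 0.1, frac_sox17=ds.frac_sox17,
            frac_cxcr4=ds.frac_cxcr4,
        )
        assert trajectory_error(rescaled, ds) == 0.0


@pytest.fixture(scope="module")
def fitted():
    data = generate_calibration_data("A")
    return EnsembleFitter(
        mechanism="ME+/CX-/EU", n_samples=12, n_initial=120, n_runs=4,
        random_state=0,
    ).fit(data)


class TestEnsembleFitter:
    def test_result_invariants(self, fitted):
        assert fitted.errors_.shape == (12,)
        assert (fitted.errors_ >= 0).all()
        assert fitted.best_index_ == int(np.argmin(fitted.errors_))
        assert fitted.best_error_ == fitted.errors_.min()
        np.testing.assert_array_equal(
            fitted.accepted_, fitted.errors_ <= fitted.threshold
        )
        assert fitted.samples_.shape[0] == 12

    def test_predict_curves(self, fitted):
        pred = fitted.predict()
        assert list(pred["day"]) == [0, 1, 2, 3, 4, 5]
        assert pred["growth_norm"][4] == pytest.approx(1.0)
        fr = pred[[c for c in pred.columns if c.startswith("frac_")]]
        assert ((fr >= 0) & (fr <= 1.0 + 1e-9)).all().all()

    def test_sklearn_protocol(self, fitted):
        ps = fitted.get_params()
        assert ps["n_samples"] == 12
        cloned = clone(fitted)
        assert cloned.get_params()["mechanism"] == "ME+/CX-/EU"
        assert not hasattr(cloned, "errors_")
        assert fitted.score() == -fitted.best_error_

    def test_verification_held_out_selection(self, fitted):
        # verification scores exist per sample and the validated sample is an
        # accepted one (growth/death never enter the fitted error)
        assert fitted.verification_.shape == (12,)
        assert (fitted.verification_[np.isfinite(fitted.verification_)] >= 0).all()
        if fitted.accepted_.any():
            assert fitted.accepted_[fitted.validated_index_]
            masked = np.where(fitted.accepted_, fitted.verification_, np.inf)
            assert fitted.validated_index_ == int(np.argmin(masked))
        pred = fitted.predict(which="validated")
        assert len(pred) == 6
        with pytest.raises(ValueError):
            fitted.predict(which="bogus")

    def test_marker_only_data_falls_back_to_best(self):
        ds = generate_calibration_data("A")
        frame = ds.to_frame()[["day", "frac_sox17", "frac_cxcr4"]]
        f = EnsembleFitter(n_samples=4, n_initial=60, n_runs=2,
                           random_state=2).fit(frame)
        assert np.isnan(f.verification_).all()
        assert f.validated_index_ == f.best_index_

    def test_infinite_threshold_accepts_everything(self):
        data = generate_calibration_data("A")
        f = EnsembleFitter(n_samples=5, n_initial=80, n_runs=2,
                           threshold=np.inf, random_state=1).fit(data)
        assert f.accepted_.all()
        assert f.envelope_ is not None
        assert set(f.envelope_["output"]) == {
            "growth_norm", "death_norm", "frac_sox17", "frac_cxcr4"}

    def test_functional_wrapper(self):
        data = generate_calibration_data("A")
        res = run_ensemble(
            None, "ME+/CX-/EU",
            SimulationSettings(n_initial=80, n_runs=2, seed=0),
            data, n_samples=5, threshold=0.05, seed=3,
        )
        assert res.errors.shape == (5,)
        assert res.best_error == res.errors.min()
        assert (res.errors[res.accepted] <= res.threshold).all()
        assert res.metadata["scale"] == "desk"

    def test_reproducible_under_seed(self):
        data = generate_calibration_data("A")
        kw = dict(n_samples=4, n_initial=60, n_runs=2, random_state=9)
        e1 = EnsembleFitter(**kw).fit(data).errors_
        e2 = EnsembleFitter(**kw).fit(data).errors_
        np.testing.assert_array_equal(e1, e2)
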