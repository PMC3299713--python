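"""Ensemble parameter estimation and mechanism ranking.

Biological parameters are notoriously "sloppy": many parameter combinations
describe the data equally well, so rather than a point estimate the method
draws random parameter vectors from a bounded hyper-space of the sensitive
parameters, simulates each one, and keeps the ensemble of vectors whose
least-squares mismatch with the observed differentiation dynamics falls under
an error threshold.  The fit uses the Sox17/CXCR4 marker fractions only;
growth and cumulative-death dynamics are held out and used to verify the
surviving mechanisms qualitatively.

The error functional is the mean of squared residuals over days and the two
marker outputs (fractions on the 0-1 scale),

    E = (1 / 2T) * sum_days [ (sox_sim - sox_obs)^2 + (cx_sim - cx_obs)^2 ],

so the published acceptance thresholds (0.025 / 0.05 / 0.1) live on a
scale-free fraction^2 axis.  Day 0 is included whenever the dataset has it.

The public surface follows the scikit-learn estimator idiom:
:class:`EnsembleFitter` (one mechanism) and :class:`MechanismRanker` (all 12)
are configured in ``__init__``, do all the work in ``fit(data)`` and expose
results as trailing-underscore attributes; :func:`run_ensemble` and
:func:`rank_mechanisms` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import ExperimentalDataset
from .engine import TrajectorySet, simulate
from .mechanisms import (
    MechanismConfig,
    Phenotype,
    enumerate_mechanisms,
    get_mechanism,
)
from .params import ConfigurationError, ModelParams, SimulationSettings

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSpace",
    "sample_parameter_space",
    "trajectory_error",
    "AlignmentError",
    "EnsembleResult",
    "EnsembleFitter",
    "run_ensemble",
    "MechanismRanker",
    "rank_mechanisms",
]


class AlignmentError(ValueError):
    """Simulated and observed series do not share the same observation days."""


# ---------------------------------------------------------------------------
# parameter space


@dataclass
class ParameterSpace:
    """Box bounds for the sampled (sensitive) parameters; everything else is
    held fixed at the ``base`` nominal vector.

    Parameter names are the flat scalar names of :class:`ModelParams`
    (``nprog1_MESENDODERM`` etc.).  Cross-parameter invariants that a box
    cannot express are resolved in :meth:`to_params`: a sampled ``a_min`` is
    capped just below the sampled ``a_0max``, and ``t_g1`` just below
    ``t_cycle``.
    """

    bounds: dict[str, tuple[float, float]]
    base: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known = {n for n, _ in self.base.flat_items()}
        for name, (lo, hi) in self.bounds.items():
            if name not in known:
                raise ConfigurationError(f"unknown sampled parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(
                    f"bounds for {name!r} must be finite with lower < upper, got ({lo}, {hi})"
                )

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def to_params(self, row) -> ModelParams:
        """Substitute one sampled row (mapping name -> value) into the base
        vector, resolving cross-field constraints before validation."""
        base = self.base
        kwargs = {name: getattr(base, name) for name in ModelParams._SCALARS}
        nprog1 = dict(base.nprog_stage1)
        nprog2 = dict(base.nprog_stage2)
        from .mechanisms import Phenotype

        for name, v in dict(row).items():
            v = float(v)
            if name.startswith("nprog1_"):
                nprog1[Phenotype[name[7:]]] = v
            elif name.startswith("nprog2_"):
                nprog2[Phenotype[name[7:]]] = v
            elif name in kwargs:
                kwargs[name] = v
            else:
                raise ConfigurationError(f"unknown sampled parameter {name!r}")
        # box bounds cannot encode these pairwise orderings
        if kwargs["a_min"] >= kwargs["a_0max"]:
            kwargs["a_min"] = 0.95 * kwargs["a_0max"]
        if kwargs["t_g1"] > kwargs["t_cycle"]:
            kwargs["t_g1"] = kwargs["t_cycle"]
        if kwargs["l_max"] <= kwargs["l_min"]:
            kwargs["l_max"] = kwargs["l_min"] + 1.0
        return ModelParams(nprog_stage1=nprog1, nprog_stage2=nprog2, **kwargs)

    @classmethod
    def default(
        cls,
        base: ModelParams | None = None,
        mech: MechanismConfig | str = "ME+/CX-/EU",
        span: float = 10.0,
    ) -> "ParameterSpace":
        """Default space: the sensitive parameter classes (affinity threshold
        and bounds, commitment thresholds, decay factor, G1 duration,
        lifespan upper bound, propensity magnitudes, transfer scale), each
        bounded a factor ``span`` either side of its nominal value, capped by
        the structural invariants.  Stage-2 parameters are included only for
        mechanisms with a mesendoderm intermediate.
        """
        base = base or ModelParams()
        mech = get_mechanism(mech)
        b: dict[str, tuple[float, float]] = {}

        def around(value, lo_cap=None, hi_cap=None):
            lo, hi = value / span, value * span
            if lo_cap is not None:
                lo = max(lo, lo_cap)
            if hi_cap is not None:
                hi = min(hi, hi_cap)
            return (lo, hi)

        b["a_min"] = around(base.a_min)
        b["a_0max"] = around(base.a_0max)
        b["x_com"] = around(base.x_com)
        # the decay acts through (d - 1); spanning d itself would allow d <= 1
        b["d"] = (1.0 + (base.d - 1.0) / span, 1.0 + (base.d - 1.0) * span)
        b["t_g1"] = around(base.t_g1, hi_cap=base.t_cycle)
        b["l_max"] = around(base.l_max, lo_cap=base.l_min + 1.0)
        b["aa"] = around(base.aa)
        if mech.include_mesendoderm:
            b["a_0max2"] = around(base.a_0max2)
            b["x_com2"] = around(base.x_com2)
            for lin in (Phenotype.MESENDODERM, Phenotype.VISCERAL_ENDODERM):
                b[f"nprog1_{lin.name}"] = around(base.nprog_stage1[lin])
            for lin in (Phenotype.DEFINITIVE_ENDODERM, Phenotype.MESODERM):
                b[f"nprog2_{lin.name}"] = around(base.nprog_stage2[lin])
        else:
            for lin in (
                Phenotype.DEFINITIVE_ENDODERM,
                Phenotype.VISCERAL_ENDODERM,
                Phenotype.MESODERM,
            ):
                b[f"nprog1_{lin.name}"] = around(base.nprog_stage1[lin])
        return cls(bounds=b, base=base)


def sample_parameter_space(
    space: ParameterSpace, n_samples: int, seed=None
) -> pd.DataFrame:
    """Independent uniform draws per dimension; reproducible under ``seed``."""
    space.validate()
    if n_samples < 1:
        raise ConfigurationError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in space.names:
        lo, hi = space.bounds[name]
        cols[name] = rng.uniform(lo, hi, n_samples)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# error functional


def _marker_curves(sim) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(sim, TrajectorySet):
        return sim.days, sim.mean("frac_sox17"), sim.mean("frac_cxcr4")
    # anything with days / frac_sox17 / frac_cxcr4 attributes (e.g. a dataset)
    return (
        np.asarray(sim.days, float),
        np.asarray(sim.frac_sox17, float),
        np.asarray(sim.frac_cxcr4, float),
    )


def trajectory_error(sim, data: ExperimentalDataset) -> float:
    """Mean squared marker residual between a simulation (or dataset) and the
    observed differentiation dynamics.

    Only the Sox17 and CXCR4 fractions enter; growth and death series are
    excluded from the fit by construction (they serve as verification).
    """
    days_s, sox_s, cx_s = _marker_curves(sim)
    days_d = np.asarray(data.days, float)
    if days_s.shape != days_d.shape or not np.allclose(days_s, days_d):
        raise AlignmentError(
            f"observation days differ: simulated {days_s}, observed {days_d}"
        )
    r = (sox_s - np.asarray(data.frac_sox17, float)) ** 2
    r = r + (cx_s - np.asarray(data.frac_cxcr4, float)) ** 2
    return float(r.sum() / (2.0 * days_d.size))


# ---------------------------------------------------------------------------
# ensemble fitting


@dataclass
class EnsembleResult:
    """Outcome of one random-sampling ensemble fit."""

    samples: pd.DataFrame
    errors: np.ndarray
    threshold: float
    accepted: np.ndarray
    best_index: int
    best_params: ModelParams
    best_error: float
    envelope: pd.DataFrame | None
    trajectories: dict
    metadata: dict

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


def _coerce_dataset(X) -> ExperimentalDataset:
    if isinstance(X, ExperimentalDataset):
        return X
    if isinstance(X, pd.DataFrame):
        nan = np.full(len(X), np.nan)
        return ExperimentalDataset(
            condition=str(X.attrs.get("condition", "?")),
            days=X["day"].to_numpy(float),
            growth=X["growth_norm"].to_numpy(float) if "growth_norm" in X else nan,
            death=X["death_norm"].to_numpy(float) if "death_norm" in X else nan,
            frac_sox17=X["frac_sox17"].to_numpy(float),
            frac_cxcr4=X["frac_cxcr4"].to_numpy(float),
        )
    raise TypeError(
        "expected an ExperimentalDataset or a DataFrame with columns "
        "day/frac_sox17/frac_cxcr4"
    )


class EnsembleFitter(BaseEstimator):
    """Random-sampling ensemble least-squares fit of one mechanism.

    Parameters
    ----------
    mechanism : str or MechanismConfig, default "ME+/CX-/EU"
        Candidate mechanism to fit.
    space : ParameterSpace, optional
        Sampled-parameter bounds; defaults to
        ``ParameterSpace.default(base_params, mechanism)``.
    n_samples : int, default 500
        Number of random parameter vectors (the published analysis used
        10000; 500 is the desk-scale default).
    threshold : float, default 0.025
        Ensemble acceptance threshold on the marker error.
    n_initial, n_runs, horizon, observation_interval :
        Simulation settings per sample (desk-scale defaults 1000 cells /
        100 runs; the published operating point is 9000 / 4000).
    base_params : ModelParams, optional
        Nominal vector for the non-sampled parameters.
    random_state : int, default 0
        Master seed; sampling and every per-sample simulation derive
        independent child streams from it.

    Attributes
    ----------
    samples_ : DataFrame of sampled parameter vectors (n_samples x n_dims).
    errors_ : ndarray of per-sample marker errors.
    accepted_ : boolean mask, ``errors_ <= threshold``.
    best_index_, best_params_, best_error_ : the least-squares winner.
    trajectories_ : per-sample day-mean curves (keys ``live``, ``dead``,
        ``frac_sox17``, ``frac_cxcr4``, ``phenotype_fracs``).
    envelope_ : per-day min/max band of the accepted simulations for each
        output (None if nothing was accepted).
    verification_ : per-sample mean-squared deviation of the held-out
        day-4-normalized growth and cumulative-death curves (NaN when the
        dataset carries no growth/death series).  Never part of the fit.
    validated_index_, validated_params_ : among the accepted samples, the one
        whose held-out growth/death curves agree best with the data.  The
        marker error cannot distinguish the unstained pools (idle
        undifferentiated cells versus mesoderm), so model *predictions* about
        those pools are read from this verified member of the ensemble; if
        nothing was accepted (or no growth/death data exist) it falls back to
        the best-error sample.
    """

    def __init__(
        self,
        mechanism="ME+/CX-/EU",
        space: ParameterSpace | None = None,
        n_samples: int = 500,
        threshold: float = 0.025,
        n_initial: int = 1000,
        n_runs: int = 100,
        horizon: float = 120.0,
        observation_interval: float = 24.0,
        base_params: ModelParams | None = None,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.mechanism = mechanism
        self.space = space
        self.n_samples = n_samples
        self.threshold = threshold
        self.n_initial = n_initial
        self.n_runs = n_runs
        self.horizon = horizon
        self.observation_interval = observation_interval
        self.base_params = base_params
        self.random_state = random_state
        self.verbose = verbose

    # -- internal helpers ------------------------------------------------
    def _settings(self, seed: int) -> SimulationSettings:
        return SimulationSettings(
            n_initial=self.n_initial,
            n_runs=self.n_runs,
            horizon=self.horizon,
            observation_interval=self.observation_interval,
            seed=seed,
        )

    def fit(self, X, y=None):
        """Sample the parameter space, simulate every vector and score it
        against the marker dynamics in ``X``."""
        data = _coerce_dataset(X)
        mech = get_mechanism(self.mechanism)
        base = self.base_params or ModelParams()
        space = self.space or ParameterSpace.default(base, mech)

        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_samples + 1)
        samples = sample_parameter_space(space, self.n_samples, children[0])

        n_days = data.days.size
        live = np.zeros((self.n_samples, n_days))
        dead = np.zeros((self.n_samples, n_days))
        sox = np.zeros((self.n_samples, n_days))
        cx = np.zeros((self.n_samples, n_days))
        phen = np.zeros((self.n_samples, n_days, 5))
        errors = np.zeros(self.n_samples)

        for i in range(self.n_samples):
            p = space.to_params(samples.iloc[i])
            seed = int(children[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
            traj = simulate(p, mech, self._settings(seed))
            live[i] = traj.mean("live_count")
            dead[i] = traj.mean("cumulative_dead")
            sox[i] = traj.mean("frac_sox17")
            cx[i] = traj.mean("frac_cxcr4")
            for ph in Phenotype:
                phen[i, :, ph] = traj.mean(f"frac_{ph.name.lower()}")
            errors[i] = trajectory_error(traj, data)
            if self.verbose and (i + 1) % 50 == 0:
                logger.info(
                    "mechanism %s: %d/%d samples, best error %.4g",
                    mech.id, i + 1, self.n_samples, errors[: i + 1].min(),
                )

        self.samples_ = samples
        self.errors_ = errors
        self.accepted_ = errors <= self.threshold
        self.best_index_ = int(np.argmin(errors))
        self.best_params_ = space.to_params(samples.iloc[self.best_index_])
        self.best_error_ = float(errors[self.best_index_])
        self.trajectories_ = {
            "days": data.days.copy(),
            "live": live,
            "dead": dead,
            "frac_sox17": sox,
            "frac_cxcr4": cx,
            "phenotype_fracs": phen,
        }
        self.space_ = space
        self.verification_ = self._verification(data)
        if self.accepted_.any() and np.isfinite(self.verification_).any():
            masked = np.where(self.accepted_, self.verification_, np.inf)
            self.validated_index_ = int(np.argmin(masked))
        else:
            self.validated_index_ = self.best_index_
        self.validated_params_ = space.to_params(samples.iloc[self.validated_index_])
        self.envelope_ = self._envelope(data)
        self.metadata_ = {
            "mechanism": mech.id,
            "n_samples": self.n_samples,
            "n_runs": self.n_runs,
            "n_initial": self.n_initial,
            "threshold": self.threshold,
            "random_state": self.random_state,
            "scale": "desk" if self.n_samples < 10000 else "paper",
            "n_accepted": int(self.accepted_.sum()),
        }
        if not self.accepted_.any():
            logger.warning(
                "mechanism %s: no parameter sample met the error threshold %g "
                "(best error %.4g); result returned with an empty ensemble",
                mech.id, self.threshold, self.best_error_,
            )
        return self

    def _verification(self, data: ExperimentalDataset) -> np.ndarray:
        growth_obs = np.asarray(data.growth, float)
        death_obs = np.asarray(data.death, float)
        n = self.n_samples
        if not (np.isfinite(growth_obs).all() and np.isfinite(death_obs).all()):
            return np.full(n, np.nan)
        t = self.trajectories_
        live4 = t["live"][:, 4]
        dead4 = t["dead"][:, 4]
        out = np.full(n, np.inf)
        ok = (live4 > 0) & (dead4 > 0)
        growth = t["live"][ok] / live4[ok, None]
        death = t["dead"][ok] / dead4[ok, None]
        out[ok] = 0.5 * (
            np.mean((growth - growth_obs) ** 2, axis=1)
            + np.mean((death - death_obs) ** 2, axis=1)
        )
        return out

    def _envelope(self, data: ExperimentalDataset) -> pd.DataFrame | None:
        if not self.accepted_.any():
            return None
        t = self.trajectories_
        acc = self.accepted_
        live4 = np.where(t["live"][:, 4:5] > 0, t["live"][:, 4:5], 1)
        dead4 = np.where(t["dead"][:, 4:5] > 0, t["dead"][:, 4:5], 1)
        curves = {
            "growth_norm": t["live"] / live4,
            "death_norm": t["dead"] / dead4,
            "frac_sox17": t["frac_sox17"],
            "frac_cxcr4": t["frac_cxcr4"],
        }
        rows = []
        for name, arr in curves.items():
            sub = arr[acc]
            for j, day in enumerate(t["days"]):
                rows.append(
                    {"day": float(day), "output": name,
                     "lo": float(sub[:, j].min()), "hi": float(sub[:, j].max()),
                     "best": float(arr[self.best_index_, j])}
                )
        return pd.DataFrame(rows)

    def predict(self, X=None, which: str = "best") -> pd.DataFrame:
        """Day-mean curves (markers, phenotype fractions and day-4-normalized
        growth/death) of the best-error sample (``which="best"``) or of the
        verification-selected accepted sample (``which="validated"``)."""
        if which not in ("best", "validated"):
            raise ValueError(f"which must be 'best' or 'validated', got {which!r}")
        t = self.trajectories_
        i = self.best_index_ if which == "best" else self.validated_index_
        out = pd.DataFrame({"day": t["days"]})
        out["frac_sox17"] = t["frac_sox17"][i]
        out["frac_cxcr4"] = t["frac_cxcr4"][i]
        for ph in Phenotype:
            out[f"frac_{ph.name.lower()}"] = t["phenotype_fracs"][i, :, ph]
        live4 = t["live"][i, 4] or 1.0
        dead4 = t["dead"][i, 4] or 1.0
        out["growth_norm"] = t["live"][i] / live4
        out["death_norm"] = t["dead"][i] / dead4
        return out

    def score(self, X=None, y=None) -> float:
        """Negative best marker error (higher is better, sklearn convention)."""
        return -self.best_error_

    def result(self) -> EnsembleResult:
        return EnsembleResult(
            samples=self.samples_,
            errors=self.errors_,
            threshold=self.threshold,
            accepted=self.accepted_,
            best_index=self.best_index_,
            best_params=self.best_params_,
            best_error=self.best_error_,
            envelope=self.envelope_,
            trajectories=self.trajectories_,
            metadata=self.metadata_,
        )


def run_ensemble(
    space: ParameterSpace | None,
    mech,
    settings: SimulationSettings,
    data,
    n_samples: int = 500,
    threshold: float = 0.025,
    seed: int = 0,
) -> EnsembleResult:
    """Functional wrapper over :class:`EnsembleFitter`."""
    fitter = EnsembleFitter(
        mechanism=mech,
        space=space,
        n_samples=n_samples,
        threshold=threshold,
        n_initial=settings.n_initial,
        n_runs=settings.n_runs,
        horizon=settings.horizon,
        observation_interval=settings.observation_interval,
        random_state=seed,
    )
    fitter.fit(data)
    return fitter.result()


# ---------------------------------------------------------------------------
# mechanism ranking


class MechanismRanker(BaseEstimator):
    """Fit every candidate mechanism and rank them by minimum ensemble error.

    The ranking uses the marker fit only; for each mechanism a verification
    score is also reported: the mean-squared deviation between the best fit's
    day-4-normalized growth and cumulative-death curves and the observed
    ones.  Verification is reported, never fitted.

    Attributes
    ----------
    ranking_ : DataFrame (mechanism, min_error, n_accepted,
        growth_verification, death_verification), sorted by min_error.
    results_ : dict mechanism id -> EnsembleResult.
    best_mechanism_ : id of the minimum-error mechanism.
    """

    def __init__(
        self,
        mechanisms=None,
        n_samples: int = 500,
        threshold: float = 0.025,
        n_initial: int = 1000,
        n_runs: int = 100,
        horizon: float = 120.0,
        observation_interval: float = 24.0,
        base_params: ModelParams | None = None,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.mechanisms = mechanisms
        self.n_samples = n_samples
        self.threshold = threshold
        self.n_initial = n_initial
        self.n_runs = n_runs
        self.horizon = horizon
        self.observation_interval = observation_interval
        self.base_params = base_params
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y=None):
        data = _coerce_dataset(X)
        mechs = [get_mechanism(m) for m in (self.mechanisms or enumerate_mechanisms())]
        children = np.random.SeedSequence(self.random_state).spawn(len(mechs))
        self.results_ = {}
        rows = []
        for mech, child in zip(mechs, children):
            fitter = EnsembleFitter(
                mechanism=mech,
                n_samples=self.n_samples,
                threshold=self.threshold,
                n_initial=self.n_initial,
                n_runs=self.n_runs,
                horizon=self.horizon,
                observation_interval=self.observation_interval,
                base_params=self.base_params,
                random_state=int(child.generate_state(1)[0] & 0x7FFFFFFF),
                verbose=self.verbose,
            ).fit(data)
            res = fitter.result()
            self.results_[mech.id] = res
            best = fitter.predict()
            gv = dv = np.nan
            if np.isfinite(np.asarray(data.growth, float)).all():
                gv = float(np.mean((best["growth_norm"].to_numpy() - data.growth) ** 2))
            if np.isfinite(np.asarray(data.death, float)).all():
                dv = float(np.mean((best["death_norm"].to_numpy() - data.death) ** 2))
            rows.append(
                {"mechanism": mech.id, "min_error": res.best_error,
                 "n_accepted": res.n_accepted,
                 "growth_verification": gv, "death_verification": dv}
            )
            if self.verbose:
                logger.info("mechanism %s: min error %.4g", mech.id, res.best_error)
        self.ranking_ = (
            pd.DataFrame(rows).sort_values("min_error").reset_index(drop=True)
        )
        self.best_mechanism_ = str(self.ranking_.iloc[0]["mechanism"])
        return self


def rank_mechanisms(
    data,
    settings: SimulationSettings,
    mechanisms=None,
    n_samples: int = 500,
    threshold: float = 0.025,
    seed: int = 0,
) -> MechanismRanker:
    """Functional wrapper over :class:`MechanismRanker` (returns it fitted)."""
    ranker = MechanismRanker(
        mechanisms=mechanisms,
        n_samples=n_samples,
        threshold=threshold,
        n_initial=settings.n_initial,
        n_runs=settings.n_runs,
        horizon=settings.horizon,
        observation_interval=settings.observation_interval,
        random_state=seed,
    )
    return ranker.fit(data)
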