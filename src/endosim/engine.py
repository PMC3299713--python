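"""Vectorized population simulator.

The simulator evolves struct-of-arrays populations (one numpy array per cell
attribute, runs batched side by side and tagged by a run index) in fixed time
steps.  Each step applies, in order: affinity decay with the competence latch,
regime transfers in both directions, propensity updating with immediate
commitment, then aging/death and cycle-gated division.  These are exactly the
single-cell rules of :mod:`endosim.cells`, applied to every live cell at once.

Observables are recorded every ``observation_interval`` hours into a
:class:`TrajectorySet`: per-run live counts, cumulative dead, division totals,
per-phenotype counts and the Sox17/CXCR4 marker fractions.  The bookkeeping
maintains the conservation identity

    live(t) + cumulative_dead(t) - total_divisions(t) = n_initial

for every run at every snapshot.

Reproducibility: ``simulate`` derives all randomness from ``settings.seed``
through a :class:`numpy.random.SeedSequence`; repeated calls with the same
inputs are bit-identical.  Runs inside a batch share one stream (they advance
synchronously); batches of runs are split deterministically by population
size only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mechanisms import (
    MechanismConfig,
    Phenotype,
    allowed_mask,
    get_mechanism,
    marker_fraction_arrays,
)
from .params import (
    ModelParams,
    PROPENSITY_INCREMENT,
    SELECTION_FLOOR,
    SimulationSettings,
    ConfigurationError,
)

logger = logging.getLogger(__name__)

__all__ = ["TrajectorySet", "simulate", "simulate_run"]

_OUTPUT_NAMES = (
    "live_count",
    "cumulative_dead",
    "divisions",
    "frac_sox17",
    "frac_cxcr4",
    "frac_hesc",
    "frac_mesendoderm",
    "frac_visceral_endoderm",
    "frac_definitive_endoderm",
    "frac_mesoderm",
)

_PHEN_OUTPUT = {
    "frac_hesc": Phenotype.HESC,
    "frac_mesendoderm": Phenotype.MESENDODERM,
    "frac_visceral_endoderm": Phenotype.VISCERAL_ENDODERM,
    "frac_definitive_endoderm": Phenotype.DEFINITIVE_ENDODERM,
    "frac_mesoderm": Phenotype.MESODERM,
}


@dataclass
class TrajectorySet:
    """Daily observables of a batch of stochastic runs.

    Arrays are indexed ``[run, observation]`` (phenotype counts additionally
    by :class:`~endosim.mechanisms.Phenotype`).  ``normalized_to_day4``
    records whether the growth/death series have been divided by their day-4
    value (raw simulations set it False; normalization helpers set it True
    on the curves they return).
    """

    days: np.ndarray
    live: np.ndarray
    cumulative_dead: np.ndarray
    divisions: np.ndarray
    phenotype_counts: np.ndarray
    frac_sox17: np.ndarray
    frac_cxcr4: np.ndarray
    mechanism: str
    n_initial: int
    normalized_to_day4: bool = False

    # -- shapes ----------------------------------------------------------
    @property
    def n_runs(self) -> int:
        return self.live.shape[0]

    @property
    def n_obs(self) -> int:
        return self.live.shape[1]

    # -- access ----------------------------------------------------------
    def output(self, name: str) -> np.ndarray:
        """Per-run array (n_runs, n_obs) of a named observable."""
        if name == "live_count":
            return self.live
        if name == "cumulative_dead":
            return self.cumulative_dead
        if name == "divisions":
            return self.divisions
        if name == "frac_sox17":
            return self.frac_sox17
        if name == "frac_cxcr4":
            return self.frac_cxcr4
        if name in _PHEN_OUTPUT:
            denom = np.where(self.live > 0, self.live, 1)
            return np.where(
                self.live > 0,
                self.phenotype_counts[:, :, _PHEN_OUTPUT[name]] / denom,
                0.0,
            )
        raise KeyError(f"unknown output {name!r}; valid: {_OUTPUT_NAMES}")

    def mean(self, name: str) -> np.ndarray:
        """Mean over runs, per observation day."""
        return self.output(name).mean(axis=0)

    def sd(self, name: str) -> np.ndarray:
        """Run-to-run standard deviation, per observation day."""
        return self.output(name).std(axis=0, ddof=0)

    def day_sample(self, name: str, day: float) -> np.ndarray:
        """Per-run sample of an observable at one observation day."""
        j = np.flatnonzero(np.isclose(self.days, day))
        if j.size == 0:
            raise KeyError(f"day {day} not among observation days {self.days}")
        return self.output(name)[:, j[0]]

    def day4_normalized_mean(self, name: str) -> np.ndarray:
        """Mean curve divided by its day-4 value (the figure convention for
        growth and death series)."""
        m = self.mean(name)
        j = np.flatnonzero(np.isclose(self.days, 4.0))
        if j.size == 0:
            raise KeyError("day 4 is not an observation day; cannot normalize")
        ref = m[j[0]]
        if ref == 0:
            raise ZeroDivisionError(f"day-4 value of {name!r} is zero; cannot normalize")
        return m / ref

    def to_frame(self, include_runs: bool = False) -> pd.DataFrame:
        """Tidy table with one row per day for the run mean and sd (and,
        optionally, per run), in the documented CSV column order."""
        cols = ["frac_sox17", "frac_cxcr4"] + list(_PHEN_OUTPUT)
        rows = []

        def emit(run_id, live, dead, extract):
            for j, day in enumerate(self.days):
                row = {"day": float(day), "run_id": run_id,
                       "live_count": live[j], "cumulative_dead": dead[j]}
                row.update({c: extract(c)[j] for c in cols})
                rows.append(row)

        emit("mean", self.mean("live_count"), self.mean("cumulative_dead"), self.mean)
        emit("sd", self.sd("live_count"), self.sd("cumulative_dead"), self.sd)
        if include_runs:
            for r in range(self.n_runs):
                emit(r, self.live[r], self.cumulative_dead[r],
                     lambda c, r=r: self.output(c)[r])
        return pd.DataFrame(rows)


class _InvariantViolation(AssertionError):
    pass


def _simulate_batch(
    params: ModelParams,
    mech: MechanismConfig,
    n_runs: int,
    n_initial: int,
    steps: int,
    obs_every: int,
    rng: np.random.Generator,
    check: bool = False,
):
    """Evolve ``n_runs`` independent populations side by side; return the
    per-run observation arrays (live, dead, divisions, phenotype counts).

    Performance notes: cell attributes are float32/int8 struct-of-arrays.
    Ages, cycle positions and clocks are frozen in the dormant A regime; the
    A-resident set is typically small, so the loop advances those counters
    globally and repairs the A subset by index instead of masking full-array
    writes.  The proliferation clock (hours spent competent) is derived as
    ``age - latch_age`` because a competent cell can never re-enter A, so
    after the latch it ages every step.
    """
    R = n_runs
    f32 = np.float32
    dt = f32(params.dt)
    inv_d = f32(1.0 / params.d)
    d_ = f32(params.d)
    a_min = f32(params.a_min)
    t_g1 = f32(params.t_g1)
    t_cycle = f32(params.t_cycle)
    allowed = allowed_mask(mech)
    me_on = mech.include_mesendoderm
    slots1 = np.array([int(p) for p in mech.lineage_slots(1)], dtype=np.int8)
    nprog1 = np.array(
        [params.nprog_stage1[p] for p in mech.lineage_slots(1)], dtype=f32
    )
    m1 = slots1.size
    if me_on:
        slots2 = np.array([int(p) for p in mech.lineage_slots(2)], dtype=np.int8)
        nprog2 = np.array(
            [params.nprog_stage2[p] for p in mech.lineage_slots(2)], dtype=f32
        )

    def _uniform_open(scale: float, k: int) -> np.ndarray:
        # uniform on (0, scale]
        return (scale * (1.0 - rng.random(k, dtype=f32))).astype(f32, copy=False)

    def _lifespans(k: int) -> np.ndarray:
        return (
            params.l_min + (params.l_max - params.l_min) * rng.random(k, dtype=f32)
        ).astype(f32, copy=False)

    n = R * n_initial
    run = np.repeat(np.arange(R, dtype=np.int32), n_initial)
    in_a = np.zeros(n, bool)
    a = _uniform_open(params.a_0max, n)
    age = np.zeros(n, f32)
    life = _lifespans(n)
    cyc = (params.t_cycle * rng.random(n, dtype=f32)).astype(f32, copy=False)
    latch_age = np.zeros(n, f32)
    window = _uniform_open(params.w_max, n)
    comp = np.zeros(n, bool)
    phen = np.zeros(n, np.int8)
    stage = np.ones(n, np.int8)
    props = np.zeros((n, 3), f32)

    dead_cnt = np.zeros(R, np.int64)
    div_cnt = np.zeros(R, np.int64)

    n_obs = steps // obs_every + 1
    live_o = np.zeros((R, n_obs), np.int64)
    dead_o = np.zeros((R, n_obs), np.int64)
    div_o = np.zeros((R, n_obs), np.int64)
    phen_o = np.zeros((R, n_obs, 5), np.int64)

    def record(j: int) -> None:
        live_o[:, j] = np.bincount(run, minlength=R)
        phen_o[:, j, :] = np.bincount(
            run.astype(np.int64) * 5 + phen, minlength=R * 5
        ).reshape(R, 5)
        dead_o[:, j] = dead_cnt
        div_o[:, j] = div_cnt

    def verify() -> None:
        if not (a > 0).all():
            raise _InvariantViolation("a_value must stay > 0")
        if in_a.any() and not (a[in_a] >= a_min).all():
            raise _InvariantViolation("cell observed in regime A with a < a_min")
        if in_a.any() and (comp[in_a]).any():
            raise _InvariantViolation("proliferation-competent cell in regime A")
        unc1 = (phen <= 1) & (stage == 1)
        if unc1.any() and not (props[unc1, :m1] < params.x_com).all():
            raise _InvariantViolation("uncommitted stage-1 propensity at/above x_com")
        if me_on:
            unc2 = (phen == 1) & (stage == 2)
            if unc2.any() and not (props[unc2, :2] < params.x_com2).all():
                raise _InvariantViolation("uncommitted stage-2 propensity at/above x_com2")
        live_r = np.bincount(run, minlength=R)
        if not (live_r + dead_cnt - div_cnt == n_initial).all():
            raise _InvariantViolation("conservation live + dead - divisions != n_initial")

    record(0)
    for step in range(1, steps + 1):
        # occupancy at step start (destination counts for both transfer directions)
        idx_a = np.flatnonzero(in_a)
        cnt_a = np.bincount(run[idx_a], minlength=R)
        cnt_o = np.bincount(run, minlength=R) - cnt_a

        # 1. affinity decay + permanent competence latch (Omega only).
        # A-regime cells are repaired by index; they all have a >= a_min so
        # the latch comparison cannot fire for them.
        a *= inv_d
        if idx_a.size:
            a[idx_a] *= d_
        below = a < a_min
        newly = below & ~comp
        if newly.any():
            comp |= below
            latch_age[newly] = age[newly]

        # 2. regime transfers; G1 gating uses the cycle position entering the
        # step, occupancy is the step-start census for both directions
        g1 = cyc < t_g1
        if params.aa > 0:
            cand = g1 & ~below
            cand[idx_a] = False
            idx = np.flatnonzero(cand)
            if idx.size:
                f = 1.0 / (1.0 + cnt_a[run[idx]] / params.n_scale)
                p = params.aa * (a[idx] / params.a_0max) * f
                moved = idx[rng.random(idx.size) < p]
                if moved.size:
                    in_a[moved] = True
                    unc = moved[phen[moved] <= 1]
                    if unc.size:
                        s1 = unc[stage[unc] == 1]
                        if s1.size:
                            props[s1, :m1] = props[s1, :m1].mean(axis=1, keepdims=True)
                        if me_on:
                            s2 = unc[stage[unc] == 2]
                            if s2.size:
                                props[s2, :2] = props[s2, :2].mean(axis=1, keepdims=True)
        if idx_a.size:
            f = 1.0 / (1.0 + cnt_o[run[idx_a]] / params.n_scale)
            q = (a_min / a[idx_a]) * f
            back = idx_a[rng.random(idx_a.size) < q]
            in_a[back] = False

        # 3. propensity update and immediate commitment (Omega, G1, uncommitted)
        upd = g1 & (phen <= 1)
        idx_a_now = np.flatnonzero(in_a)
        upd[idx_a_now] = False
        ids_all = np.flatnonzero(upd)
        if ids_all.size:
            s1mask = stage[ids_all] == 1
            groups = [(ids_all[s1mask], m1, slots1, nprog1, f32(params.x_com))]
            if me_on:
                groups.append(
                    (ids_all[~s1mask], 2, slots2, nprog2, f32(params.x_com2))
                )
            for ids, m, slots, nprog, thr in groups:
                if not ids.size:
                    continue
                w = props[ids, :m] + f32(SELECTION_FLOOR)
                c = np.cumsum(w, axis=1)
                u = rng.random(ids.size, dtype=f32) * c[:, -1]
                sel = np.minimum((u[:, None] >= c).sum(axis=1), m - 1)
                props[ids, sel] += f32(PROPENSITY_INCREMENT) * nprog[sel]
                crossed = props[ids, sel] >= thr
                if crossed.any():
                    cids = ids[crossed]
                    lin = slots[sel[crossed]]
                    term = lin != Phenotype.MESENDODERM
                    phen[cids[term]] = lin[term]
                    if me_on and (~term).any():
                        mids = cids[~term]
                        phen[mids] = Phenotype.MESENDODERM
                        stage[mids] = 2
                        a[mids] = _uniform_open(params.a_0max2, mids.size)
                        comp[mids] = False
                        latch_age[mids] = 0.0
                        props[mids, :] = 0.0

        # 4. aging, death, cycling and division (Omega only; A is frozen, so
        # the global increments are undone on the A subset)
        age += dt
        if idx_a_now.size:
            age[idx_a_now] -= dt
        dying = age > life  # cannot fire for A residents: their age is frozen
        if dying.any():
            dead_cnt += np.bincount(run[dying], minlength=R)
            keep = ~dying
            run, in_a, a, age, life = run[keep], in_a[keep], a[keep], age[keep], life[keep]
            cyc, latch_age, window, comp = (
                cyc[keep], latch_age[keep], window[keep], comp[keep]
            )
            phen, stage, props = phen[keep], stage[keep], props[keep]
            idx_a_now = np.flatnonzero(in_a)
        cyc += dt
        if idx_a_now.size:
            cyc[idx_a_now] -= dt
        w_idx = np.flatnonzero(cyc >= t_cycle)
        if w_idx.size:
            cyc[w_idx] -= t_cycle
            ok = (
                comp[w_idx]
                & (age[w_idx] - latch_age[w_idx] <= window[w_idx])
                & allowed[phen[w_idx]]
            )
            d_idx = w_idx[ok]
            if d_idx.size:
                k = d_idx.size
                div_cnt += np.bincount(run[d_idx], minlength=R)
                run = np.concatenate([run, run[d_idx]])
                in_a = np.concatenate([in_a, np.zeros(k, bool)])
                a = np.concatenate([a, a[d_idx]])
                age = np.concatenate([age, np.zeros(k, f32)])
                life = np.concatenate([life, _lifespans(k)])
                cyc = np.concatenate([cyc, np.zeros(k, f32)])
                latch_age = np.concatenate([latch_age, np.zeros(k, f32)])
                window = np.concatenate([window, _uniform_open(params.w_max, k)])
                comp = np.concatenate([comp, comp[d_idx]])
                phen = np.concatenate([phen, phen[d_idx]])
                stage = np.concatenate([stage, stage[d_idx]])
                props = np.concatenate([props, props[d_idx]])

        if check:
            verify()
        if step % obs_every == 0:
            record(step // obs_every)

    return live_o, dead_o, div_o, phen_o


def _resolve_grid(params: ModelParams, settings: SimulationSettings) -> tuple[int, int]:
    steps = round(settings.horizon / params.dt)
    if abs(steps * params.dt - settings.horizon) > 1e-9 or steps < 1:
        raise ConfigurationError(
            f"horizon {settings.horizon} is not a positive multiple of dt {params.dt}"
        )
    obs_every = round(settings.observation_interval / params.dt)
    if abs(obs_every * params.dt - settings.observation_interval) > 1e-9 or obs_every < 1:
        raise ConfigurationError(
            f"observation_interval {settings.observation_interval} is not a "
            f"positive multiple of dt {params.dt}"
        )
    return steps, obs_every


def simulate(
    params: ModelParams,
    mech: MechanismConfig | str,
    settings: SimulationSettings,
    check_invariants: bool = False,
    max_batch_cells: int = 1_500_000,
) -> TrajectorySet:
    """Run ``settings.n_runs`` stochastic replicates and collect per-run daily
    observables.

    Replicates are evolved in batches; the batch split depends only on
    ``n_initial`` so results are a pure function of
    ``(params, mech, settings)``.  The default path is the compiled per-cell
    kernel (:mod:`endosim._kernel`); ``check_invariants=True`` switches to
    the instrumented vectorized reference implementation, which asserts the
    conservation and regime invariants after every step (slower, meant for
    tests).  The two paths implement identical rules but draw random numbers
    in different orders, so each is reproducible under its seed without being
    bitwise identical to the other.
    """
    from ._kernel import run_kernel

    mech = get_mechanism(mech)
    params.validate()
    settings.validate()
    steps, obs_every = _resolve_grid(params, settings)

    runs_per_chunk = max(1, max_batch_cells // max(1, settings.n_initial))
    n_chunks = -(-settings.n_runs // runs_per_chunk)
    children = np.random.SeedSequence(settings.seed).spawn(n_chunks)

    slots1 = np.array([int(p) for p in mech.lineage_slots(1)], dtype=np.int8)
    nprog1 = np.array([params.nprog_stage1[p] for p in mech.lineage_slots(1)], float)
    if mech.include_mesendoderm:
        slots2 = np.array([int(p) for p in mech.lineage_slots(2)], dtype=np.int8)
        nprog2 = np.array([params.nprog_stage2[p] for p in mech.lineage_slots(2)], float)
    else:  # inert placeholders; stage 2 is unreachable without mesendoderm
        slots2 = np.array([3, 4], dtype=np.int8)
        nprog2 = np.zeros(2)

    pieces = []
    done = 0
    for child in children:
        r = min(runs_per_chunk, settings.n_runs - done)
        if check_invariants:
            pieces.append(
                _simulate_batch(
                    params, mech, r, settings.n_initial, steps, obs_every,
                    np.random.default_rng(child), check=True,
                )
            )
        else:
            seed32 = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            pieces.append(
                run_kernel(
                    seed32, r, settings.n_initial, steps, obs_every,
                    params.a_min, params.a_0max, params.a_0max2,
                    params.x_com, params.x_com2, params.d,
                    params.t_g1, params.t_cycle, params.l_min, params.l_max,
                    params.w_max, params.aa, params.n_scale, params.dt,
                    SELECTION_FLOOR, PROPENSITY_INCREMENT,
                    slots1, nprog1, slots2, nprog2,
                    mech.include_mesendoderm, allowed_mask(mech),
                )
            )
        done += r
    live, dead, divs, phen = (np.concatenate(arrs, axis=0) for arrs in zip(*pieces))

    sox, cx = marker_fraction_arrays(phen, live, mech)
    n_extinct = int((live[:, -1] == 0).sum())
    if n_extinct:
        logger.warning(
            "%d of %d runs went extinct before the horizon; their remaining "
            "marker observations are zero-filled", n_extinct, settings.n_runs,
        )
    days = np.arange(live.shape[1]) * settings.observation_interval / 24.0
    return TrajectorySet(
        days=days,
        live=live,
        cumulative_dead=dead,
        divisions=divs,
        phenotype_counts=phen,
        frac_sox17=sox,
        frac_cxcr4=cx,
        mechanism=mech.id,
        n_initial=settings.n_initial,
    )


def simulate_run(
    params: ModelParams,
    mech: MechanismConfig | str,
    settings: SimulationSettings,
    rng: np.random.Generator,
    check_invariants: bool = False,
) -> TrajectorySet:
    """One stochastic run using a caller-provided generator.

    Equivalent to a batch of size one; :func:`simulate` is the aggregating
    front end.
    """
    mech = get_mechanism(mech)
    params.validate()
    settings.validate()
    steps, obs_every = _resolve_grid(params, settings)
    live, dead, divs, phen = _simulate_batch(
        params, mech, 1, settings.n_initial, steps, obs_every, rng,
        check=check_invariants,
    )
    sox, cx = marker_fraction_arrays(phen, live, mech)
    if live[0, -1] == 0:
        logger.warning(
            "run went extinct before the horizon; remaining marker "
            "observations are zero-filled"
        )
    days = np.arange(live.shape[1]) * settings.observation_interval / 24.0
    return TrajectorySet(
        days=days,
        live=live,
        cumulative_dead=dead,
        divisions=divs,
        phenotype_counts=phen,
        frac_sox17=sox,
        frac_cxcr4=cx,
        mechanism=mech.id,
        n_initial=settings.n_initial,
    )
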