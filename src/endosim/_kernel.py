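"""Compiled per-cell simulation kernel.

This is the production integrator behind :func:`endosim.engine.simulate`: a
numba-jitted loop over cells and time steps implementing exactly the rules of
:mod:`endosim.cells` (affinity decay and latch, regime transfers with
crowding, G1-gated propensity competition with immediate commitment, aging,
death and windowed division).  Cells interact only through the per-run regime
occupancy census taken at the start of each step, so the per-cell evaluation
order does not change the dynamics.

The kernel consumes numba's global legacy RNG (seeded per call), so its draw
sequence differs from the numpy reference path in
:mod:`endosim.engine`; the two implementations are equal in distribution and
are cross-validated in the test suite, but are not bitwise identical to each
other.  Each path on its own is exactly reproducible under its seed.

Dead cells are tombstoned rather than compacted (the total slot count is
bounded by the initial population plus total divisions), which keeps the loop
allocation-free except for capacity doubling when divisions outgrow the
arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def run_kernel(
    seed,
    R,
    n_initial,
    steps,
    obs_every,
    a_min,
    a_0max,
    a_0max2,
    x_com,
    x_com2,
    d,
    t_g1,
    t_cycle,
    l_min,
    l_max,
    w_max,
    aa,
    n_scale,
    dt,
    eps,
    delta,
    slots1,
    nprog1,
    slots2,
    nprog2,
    me_on,
    allowed,
):  # pragma: no cover - exercised through engine.simulate
    np.random.seed(seed)
    inv_d = 1.0 / d
    m1 = slots1.shape[0]

    cap = R * n_initial + 16
    run = np.empty(cap, np.int32)
    alive = np.zeros(cap, np.uint8)
    in_a = np.zeros(cap, np.uint8)
    a = np.empty(cap, np.float64)
    age = np.zeros(cap, np.float64)
    life = np.empty(cap, np.float64)
    cyc = np.empty(cap, np.float64)
    latch = np.zeros(cap, np.float64)
    window = np.empty(cap, np.float64)
    comp = np.zeros(cap, np.uint8)
    phen = np.zeros(cap, np.int8)
    stage = np.ones(cap, np.int8)
    props = np.zeros((cap, 3), np.float64)

    count = R * n_initial
    for i in range(count):
        run[i] = i // n_initial
        alive[i] = 1
        a[i] = a_0max * (1.0 - np.random.random())
        life[i] = l_min + (l_max - l_min) * np.random.random()
        cyc[i] = t_cycle * np.random.random()
        window[i] = w_max * (1.0 - np.random.random())

    dead_cnt = np.zeros(R, np.int64)
    div_cnt = np.zeros(R, np.int64)
    cnt_a = np.zeros(R, np.int64)
    cnt_o = np.zeros(R, np.int64)

    n_obs = steps // obs_every + 1
    live_o = np.zeros((R, n_obs), np.int64)
    dead_o = np.zeros((R, n_obs), np.int64)
    div_o = np.zeros((R, n_obs), np.int64)
    phen_o = np.zeros((R, n_obs, 5), np.int64)

    # observation 0: the initial census
    for i in range(count):
        if alive[i]:
            live_o[run[i], 0] += 1
            phen_o[run[i], 0, phen[i]] += 1

    for step in range(1, steps + 1):
        # Guarantee capacity for the worst case (every live cell divides)
        # before entering the cell loop: rebinding arrays inside the hot loop
        # would force pointer reloads on every access.
        if cap < 2 * count + 16:
            newcap = 2 * (2 * count + 16)
            run_n = np.empty(newcap, np.int32); run_n[:cap] = run; run = run_n
            alive_n = np.zeros(newcap, np.uint8); alive_n[:cap] = alive; alive = alive_n
            in_a_n = np.zeros(newcap, np.uint8); in_a_n[:cap] = in_a; in_a = in_a_n
            a_n = np.empty(newcap, np.float64); a_n[:cap] = a; a = a_n
            age_n = np.zeros(newcap, np.float64); age_n[:cap] = age; age = age_n
            life_n = np.empty(newcap, np.float64); life_n[:cap] = life; life = life_n
            cyc_n = np.empty(newcap, np.float64); cyc_n[:cap] = cyc; cyc = cyc_n
            latch_n = np.zeros(newcap, np.float64); latch_n[:cap] = latch; latch = latch_n
            window_n = np.empty(newcap, np.float64); window_n[:cap] = window; window = window_n
            comp_n = np.zeros(newcap, np.uint8); comp_n[:cap] = comp; comp = comp_n
            phen_n = np.zeros(newcap, np.int8); phen_n[:cap] = phen; phen = phen_n
            stage_n = np.ones(newcap, np.int8); stage_n[:cap] = stage; stage = stage_n
            props_n = np.zeros((newcap, 3), np.float64); props_n[:cap] = props; props = props_n
            cap = newcap

        # per-run regime occupancy at step start
        for r in range(R):
            cnt_a[r] = 0
            cnt_o[r] = 0
        for i in range(count):
            if alive[i]:
                if in_a[i]:
                    cnt_a[run[i]] += 1
                else:
                    cnt_o[run[i]] += 1

        n_start = count
        for i in range(n_start):
            if not alive[i]:
                continue
            r = run[i]
            if in_a[i]:
                # dormant: frozen unless it transfers back to Omega
                q = (a_min / a[i]) * (1.0 / (1.0 + cnt_o[r] / n_scale))
                if np.random.random() < q:
                    in_a[i] = 0
                else:
                    continue
            else:
                # active: affinity decay + permanent competence latch
                a[i] *= inv_d
                if a[i] < a_min and comp[i] == 0:
                    comp[i] = 1
                    latch[i] = age[i]
                # Omega -> A, G1-gated, impossible once below a_min
                if aa > 0.0 and cyc[i] < t_g1 and a[i] >= a_min:
                    p = aa * (a[i] / a_0max) * (1.0 / (1.0 + cnt_a[r] / n_scale))
                    if np.random.random() < p:
                        in_a[i] = 1
                        if phen[i] <= 1:
                            m = m1 if stage[i] == 1 else 2
                            s = 0.0
                            for j in range(m):
                                s += props[i, j]
                            mval = s / m
                            for j in range(m):
                                props[i, j] = mval
                        continue  # frozen for the rest of the step

            # propensity competition (Omega, G1, uncommitted) + commitment
            if cyc[i] < t_g1 and phen[i] <= 1:
                if stage[i] == 1:
                    m = m1
                    thr = x_com
                else:
                    m = 2
                    thr = x_com2
                tot = 0.0
                for j in range(m):
                    tot += props[i, j] + eps
                u = np.random.random() * tot
                sel = m - 1
                acc = 0.0
                for j in range(m):
                    acc += props[i, j] + eps
                    if u < acc:
                        sel = j
                        break
                if stage[i] == 1:
                    props[i, sel] += delta * nprog1[sel]
                    lin = slots1[sel]
                else:
                    props[i, sel] += delta * nprog2[sel]
                    lin = slots2[sel]
                if props[i, sel] >= thr:
                    if me_on and lin == 1:
                        # mesendoderm: stage 2 opens with re-initialized state
                        phen[i] = 1
                        stage[i] = 2
                        a[i] = a_0max2 * (1.0 - np.random.random())
                        comp[i] = 0
                        latch[i] = 0.0
                        props[i, 0] = 0.0
                        props[i, 1] = 0.0
                        props[i, 2] = 0.0
                    else:
                        phen[i] = lin

            # aging, death, cycling, division
            age[i] += dt
            if age[i] > life[i]:
                alive[i] = 0
                dead_cnt[r] += 1
                continue
            cyc[i] += dt
            if cyc[i] >= t_cycle:
                cyc[i] -= t_cycle
                if (
                    comp[i] == 1
                    and age[i] - latch[i] <= window[i]
                    and allowed[phen[i]]
                ):
                    j = count
                    count += 1
                    div_cnt[r] += 1
                    run[j] = r
                    alive[j] = 1
                    in_a[j] = 0
                    a[j] = a[i]
                    age[j] = 0.0
                    life[j] = l_min + (l_max - l_min) * np.random.random()
                    cyc[j] = 0.0
                    latch[j] = 0.0
                    window[j] = w_max * (1.0 - np.random.random())
                    comp[j] = comp[i]
                    phen[j] = phen[i]
                    stage[j] = stage[i]
                    props[j, 0] = props[i, 0]
                    props[j, 1] = props[i, 1]
                    props[j, 2] = props[i, 2]

        if step % obs_every == 0:
            o = step // obs_every
            for i in range(count):
                if alive[i]:
                    live_o[run[i], o] += 1
                    phen_o[run[i], o, phen[i]] += 1
            for r in range(R):
                dead_o[r, o] = dead_cnt[r]
                div_o[r, o] = div_cnt[r]

    return live_o, dead_o, div_o, phen_o
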