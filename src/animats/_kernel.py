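"""Numba kernels for trial simulation.

Dynamics contract (shared by the logged and the score-only driver):

* one serial-order permutation per trial, reused every timestep;
* each timestep iterates animats in that order: sense the live occupancy
  (already-moved animats are seen at their new positions), update the
  brain via the precompiled full-state lookup table, then apply the motor
  action;
* forward into a wall, or into an occupied cell under blocking, realizes
  no movement;
* a crossing is logged when an animat enters a non-gate cell whose room
  differs from the room of the last non-gate cell it occupied (it came
  through a gate); the event carries the traversed gate's reward tag.

State packing: bit ``u`` of an animat's state integer is unit ``u``
(sensors first, then memory, then motors). The lookup table maps a full
state to the packed next states of the non-sensor units.
"""

import numpy as np
from numba import njit

# orientation 0=up, 1=right, 2=down, 3=left (up = decreasing y)
_DX = np.array([0, 1, 0, -1], dtype=np.int64)
_DY = np.array([-1, 0, 1, 0], dtype=np.int64)

# sensor sides as orientation offsets: front=+0, left=+3, right=+1 (mod 4)
SIDE_OFFSETS = {"front": 0, "left": 3, "right": 1}
KIND_CODES = {"wall": 0, "agent": 1, "universal": 2}

GATE_ROOM = -2


@njit(cache=True)
def _advance(
    wall, room, grew, occ, xs, ys, ors, sts, cur_room, on_gate,
    order, lookup, s_kind, s_off, n_mem, blocking,
    sens_out, act_out, cross_out,
):
    """Advance every animat by one timestep, serially in ``order``."""
    n_sensors = s_kind.shape[0]
    smask = (np.uint32(1) << n_sensors) - np.uint32(1)
    for k in range(order.shape[0]):
        a = order[k]
        x = xs[a]
        y = ys[a]
        o = ors[a]
        sbits = np.uint32(0)
        for si in range(n_sensors):
            d = (o + s_off[si]) & 3
            nx = x + _DX[d]
            ny = y + _DY[d]
            kind = s_kind[si]
            fire = False
            if kind == 0:
                fire = wall[ny, nx]
            elif kind == 1:
                fire = occ[ny, nx] > 0
            else:
                fire = wall[ny, nx] or occ[ny, nx] > 0
            if fire:
                sbits |= np.uint32(1) << si
        st = (sts[a] & ~smask) | sbits
        ns = lookup[st]
        sts[a] = np.uint32(ns) << n_sensors
        m0 = (ns >> n_mem) & 1
        m1 = (ns >> (n_mem + 1)) & 1
        act = np.int8(0)
        cross = np.int8(0)
        if m0 == 1 and m1 == 1:
            nx = x + _DX[o]
            ny = y + _DY[o]
            if not wall[ny, nx] and not (blocking and occ[ny, nx] > 0):
                occ[y, x] -= 1
                occ[ny, nx] += 1
                xs[a] = nx
                ys[a] = ny
                act = np.int8(2)
                r = room[ny, nx]
                if r == GATE_ROOM:
                    on_gate[a] = np.int8(2) if grew[ny, nx] else np.int8(1)
                elif r != cur_room[a]:
                    cross = on_gate[a]
                    cur_room[a] = r
                    on_gate[a] = np.int8(0)
                else:
                    on_gate[a] = np.int8(0)
        elif m0 == 1:
            ors[a] = (o + 3) & 3
            act = np.int8(1)
        elif m1 == 1:
            ors[a] = (o + 1) & 3
            act = np.int8(1)
        sens_out[a] = sbits
        act_out[a] = act
        cross_out[a] = cross


@njit(cache=True)
def simulate_logged(
    wall, room, grew, sx, sy, so, order,
    lookup, s_kind, s_off, n_mem, blocking, T,
):
    """Run one trial and return the full per-timestep log arrays."""
    n = sx.shape[0]
    xs = sx.copy()
    ys = sy.copy()
    ors = so.copy()
    sts = np.zeros(n, dtype=np.uint32)
    cur_room = np.empty(n, dtype=np.int32)
    on_gate = np.zeros(n, dtype=np.int8)
    occ = np.zeros(wall.shape, dtype=np.int16)
    for a in range(n):
        cur_room[a] = room[ys[a], xs[a]]
        occ[ys[a], xs[a]] += 1

    log_x = np.zeros((T + 1, n), dtype=np.int16)
    log_y = np.zeros((T + 1, n), dtype=np.int16)
    log_o = np.zeros((T + 1, n), dtype=np.int8)
    log_state = np.zeros((T + 1, n), dtype=np.uint32)
    log_sens = np.zeros((T, n), dtype=np.uint8)
    log_act = np.zeros((T, n), dtype=np.int8)
    log_cross = np.zeros((T, n), dtype=np.int8)
    log_coll = np.zeros((T + 1, n), dtype=np.bool_)

    log_x[0] = xs
    log_y[0] = ys
    log_o[0] = ors
    for a in range(n):
        log_coll[0, a] = occ[ys[a], xs[a]] > 1

    sens = np.zeros(n, dtype=np.uint8)
    act = np.zeros(n, dtype=np.int8)
    cross = np.zeros(n, dtype=np.int8)
    for t in range(1, T + 1):
        _advance(
            wall, room, grew, occ, xs, ys, ors, sts, cur_room, on_gate,
            order, lookup, s_kind, s_off, n_mem, blocking, sens, act, cross,
        )
        log_x[t] = xs
        log_y[t] = ys
        log_o[t] = ors
        log_state[t] = sts
        log_sens[t - 1] = sens
        log_act[t - 1] = act
        log_cross[t - 1] = cross
        for a in range(n):
            log_coll[t, a] = occ[ys[a], xs[a]] > 1
    return log_x, log_y, log_o, log_state, log_sens, log_act, log_cross, log_coll


@njit(cache=True)
def score_events(cross, coll, reward, penalty, penalty_active, refractory, cap):
    """Per-animat fitness from crossing/collision event arrays.

    ``cross[t-1, a]`` is 0/1/2 for the step into time ``t`` (1..T);
    ``coll[t, a]`` marks co-occupancy at time ``t`` (0..T). A crossing on
    a rewarding gate earns the reward iff no crossing of any kind happened
    within the ``refractory`` window before it; rewarded crossings are
    capped at ``cap``.
    """
    T, n = cross.shape
    f = np.zeros(n, dtype=np.float64)
    for a in range(n):
        last = -(10**9)
        rewarded = 0
        for s in range(T):
            c = cross[s, a]
            if c != 0:
                t = s + 1
                if c == 2 and t - last > refractory:
                    rewarded += 1
                last = t
        if rewarded > cap:
            rewarded = cap
        score = reward * rewarded
        if penalty_active:
            ncoll = 0
            for t in range(coll.shape[0]):
                if coll[t, a]:
                    ncoll += 1
            score -= penalty * ncoll
        f[a] = score
    return f


@njit(cache=True)
def evaluate_trials(
    wall, room, grew, starts_x, starts_y, orients, orders, picks,
    lookup, s_kind, s_off, n_mem, blocking, T,
    reward, penalty, penalty_active, refractory, cap,
):
    """Score-only batch driver: one picked animat's fitness per trial.

    ``starts_x`` etc. are (n_trials, group_size) arrays of pre-drawn
    placements; ``picks`` selects the focal animat of each trial (Eq-style
    ``f(rand(A))``). Dynamics are identical to :func:`simulate_logged`.
    """
    R, n = starts_x.shape
    scores = np.empty(R, dtype=np.float64)
    occ = np.zeros(wall.shape, dtype=np.int16)
    sens = np.zeros(n, dtype=np.uint8)
    act = np.zeros(n, dtype=np.int8)
    cross = np.zeros(n, dtype=np.int8)
    cur_room = np.empty(n, dtype=np.int32)
    on_gate = np.zeros(n, dtype=np.int8)
    last_cross = np.empty(n, dtype=np.int64)
    rewarded = np.empty(n, dtype=np.int64)
    ncoll = np.empty(n, dtype=np.int64)
    for r in range(R):
        xs = starts_x[r].copy()
        ys = starts_y[r].copy()
        ors = orients[r].copy()
        order = orders[r]
        sts = np.zeros(n, dtype=np.uint32)
        for a in range(n):
            cur_room[a] = room[ys[a], xs[a]]
            on_gate[a] = 0
            occ[ys[a], xs[a]] += 1
            last_cross[a] = -(10**9)
            rewarded[a] = 0
            ncoll[a] = 0
        for a in range(n):
            if occ[ys[a], xs[a]] > 1:
                ncoll[a] += 1
        for t in range(1, T + 1):
            _advance(
                wall, room, grew, occ, xs, ys, ors, sts, cur_room, on_gate,
                order, lookup, s_kind, s_off, n_mem, blocking, sens, act, cross,
            )
            for a in range(n):
                c = cross[a]
                if c != 0:
                    if c == 2 and t - last_cross[a] > refractory:
                        rewarded[a] += 1
                    last_cross[a] = t
                if occ[ys[a], xs[a]] > 1:
                    ncoll[a] += 1
        p = picks[r]
        rew = rewarded[p]
        if rew > cap:
            rew = cap
        score = reward * rew
        if penalty_active:
            score -= penalty * ncoll[p]
        scores[r] = score
        for a in range(n):
            occ[ys[a], xs[a]] = 0
    return scores
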