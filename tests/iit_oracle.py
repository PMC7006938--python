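"""Independent brute-force oracle for integrated information.

A deliberately naive re-implementation of the cause-effect analysis used
by ``animats.complexity``: plain nested loops over every mechanism,
purview and partition, no connectivity pruning, no memoization, and its
own LP assembly for the earth mover's distances. It shares only the
mathematical definitions (repertoires, EMD with Hamming ground metric,
unidirectional cuts, transport-based concept-structure distance), so
agreement between the two code paths is a meaningful check.

Systems are given as (node_probs, state): ``node_probs[s, j]`` is the
probability node ``j`` is on at t+1 given joint state ``s`` at t.
"""

from itertools import chain, combinations

import numpy as np
from scipy.optimize import linprog


def _popcount(x: int) -> int:
    return bin(x).count("1")


def emd(p, q) -> float:
    """EMD between distributions over m-bit states, Hamming ground metric."""
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    if np.max(np.abs(p - q)) < 1e-12:
        return 0.0
    n = p.size
    cost = []
    rows_i = []
    cols_j = []
    for i in range(n):
        for j in range(n):
            cost.append(_popcount(i ^ j))
    a_eq = []
    for i in range(n):
        row = [0.0] * (n * n)
        for j in range(n):
            row[i * n + j] = 1.0
        a_eq.append(row)
    for j in range(n):
        row = [0.0] * (n * n)
        for i in range(n):
            row[i * n + j] = 1.0
        a_eq.append(row)
    res = linprog(
        cost, A_eq=a_eq, b_eq=list(p) + list(q), bounds=(0, None), method="highs"
    )
    assert res.success, res.message
    return float(res.fun)


def _all_subsets(items):
    items = tuple(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def effect_rep(node_p, k, mech, y, purview):
    """Product over purview nodes of p(node | mechanism = y)."""
    if not purview:
        return np.ones(1)
    match = [
        s
        for s in range(2**k)
        if all(((s >> j) & 1) == b for j, b in zip(mech, y))
    ]
    rep = np.ones(2 ** len(purview))
    for idx, node in enumerate(purview):
        p1 = sum(node_p[s, node] for s in match) / len(match)
        for v in range(2 ** len(purview)):
            rep[v] *= p1 if ((v >> idx) & 1) else (1.0 - p1)
    return rep


def cause_rep(node_p, k, mech, y, purview):
    """Normalized product of per-mechanism-node likelihoods over purview states."""
    if not purview:
        return np.ones(1)
    if not mech:
        return np.full(2 ** len(purview), 1.0 / 2 ** len(purview))
    rep = np.ones(2 ** len(purview))
    for v in range(2 ** len(purview)):
        for node, bit in zip(mech, y):
            total = 0.0
            count = 0
            for s in range(2**k):
                ok = all(
                    ((s >> pn) & 1) == ((v >> idx) & 1)
                    for idx, pn in enumerate(purview)
                )
                if ok:
                    p1 = node_p[s, node]
                    total += p1 if bit else (1.0 - p1)
                    count += 1
            rep[v] *= total / count
    tot = rep.sum()
    if tot < 1e-12:
        return None
    return rep / tot


def _rep(node_p, k, mech, y, purview, direction):
    if direction == "effect":
        return effect_rep(node_p, k, mech, y, purview)
    return cause_rep(node_p, k, mech, y, purview)


def _combine(rep1, pv1, rep2, pv2, purview):
    full = np.ones(2 ** len(purview))
    for v in range(2 ** len(purview)):
        for rep, pv in ((rep1, pv1), (rep2, pv2)):
            if not pv:
                continue
            sub = 0
            for idx_part, node in enumerate(pv):
                bit = (v >> purview.index(node)) & 1
                sub |= bit << idx_part
            full[v] *= rep[sub]
    return full


def phi_direction(node_p, k, mech, y, direction):
    """Max over all purviews of min over all partitions of the EMD."""
    best = 0.0
    best_purview = ()
    best_rep = None
    for purview in _all_subsets(range(k)):
        if not purview:
            continue
        whole = _rep(node_p, k, mech, y, purview, direction)
        if whole is None:
            continue
        min_d = np.inf
        for m1 in _all_subsets(mech):
            m2 = tuple(j for j in mech if j not in m1)
            y1 = tuple(b for j, b in zip(mech, y) if j in m1)
            y2 = tuple(b for j, b in zip(mech, y) if j in m2)
            for v1 in _all_subsets(purview):
                v2 = tuple(v for v in purview if v not in v1)
                if (not m1 and not v1) or (not m2 and not v2):
                    continue
                r1 = _rep(node_p, k, m1, y1, v1, direction)
                r2 = _rep(node_p, k, m2, y2, v2, direction)
                if r1 is None or r2 is None:
                    continue
                d = emd(whole, _combine(r1, v1, r2, v2, purview))
                min_d = min(min_d, d)
        if np.isfinite(min_d) and min_d > best + 1e-12:
            best = min_d
            best_purview = purview
            best_rep = whole
    return best, best_purview, best_rep


def small_phi(node_p, k, mech, y):
    pc, _, _ = phi_direction(node_p, k, mech, y, "cause")
    pe, _, _ = phi_direction(node_p, k, mech, y, "effect")
    return min(pc, pe)


def _expand(rep, purview, k):
    if rep is None or not purview:
        return np.full(2**k, 1.0 / 2**k)
    full = np.empty(2**k)
    for s in range(2**k):
        sub = 0
        for idx, node in enumerate(purview):
            sub |= ((s >> node) & 1) << idx
        full[s] = rep[sub]
    return full / 2 ** (k - len(purview))


def constellation(node_p, k, state):
    concepts = []
    for mech in _all_subsets(range(k)):
        if not mech:
            continue
        y = tuple(state[j] for j in mech)
        pc, pvc, repc = phi_direction(node_p, k, mech, y, "cause")
        pe, pve, repe = phi_direction(node_p, k, mech, y, "effect")
        phi = min(pc, pe)
        if phi > 1e-12:
            concepts.append(
                (mech, phi, _expand(repc, pvc, k), _expand(repe, pve, k))
            )
    return concepts


def _cut_system(node_p, k, part_from, part_to):
    new_p = np.array(node_p, float)
    for j in part_to:
        for s in range(2**k):
            total = 0.0
            n_assign = 2 ** len(part_from)
            for assign in range(n_assign):
                s2 = s
                for bi, b in enumerate(part_from):
                    bit = (assign >> bi) & 1
                    s2 = (s2 & ~(1 << b)) | (bit << b)
                total += node_p[s2, j]
            new_p[s, j] = total / n_assign
    return new_p


def _null_concept(node_p, k):
    cause = np.full(2**k, 1.0 / 2**k)
    effect = effect_rep(node_p, k, (), (), tuple(range(k)))
    return cause, effect


def _transport(supply, demand, cost):
    ns, nd = len(supply), len(demand)
    if sum(supply) < 1e-12:
        return 0.0
    c = [cost[i][j] for i in range(ns) for j in range(nd)]
    a_eq = []
    for i in range(ns):
        row = [0.0] * (ns * nd)
        for j in range(nd):
            row[i * nd + j] = 1.0
        a_eq.append(row)
    for j in range(nd):
        row = [0.0] * (ns * nd)
        for i in range(ns):
            row[i * nd + j] = 1.0
        a_eq.append(row)
    res = linprog(
        c, A_eq=a_eq, b_eq=list(supply) + list(demand), bounds=(0, None),
        method="highs",
    )
    assert res.success, res.message
    return float(res.fun)


def constellation_distance(intact, cut, node_p, k):
    null = _null_concept(node_p, k)
    src = [(c[2], c[3]) for c in intact] + [null]
    dst = [(c[2], c[3]) for c in cut] + [null]
    supply = [c[1] for c in intact]
    demand = [c[1] for c in cut]
    diff = sum(supply) - sum(demand)
    supply.append(max(0.0, -diff))
    demand.append(max(0.0, diff))
    cost = [
        [emd(ci[0], cj[0]) + emd(ci[1], cj[1]) for cj in dst] for ci in src
    ]
    return _transport(supply, demand, cost)


def big_phi(node_p, state):
    k = int(np.log2(node_p.shape[0]))
    intact = constellation(node_p, k, state)
    if not intact:
        return 0.0, 0
    if k == 1:
        # no bipartition into two non-empty parts exists
        return 0.0, len(intact)
    phi = np.inf
    for part1 in _all_subsets(range(k)):
        part2 = tuple(j for j in range(k) if j not in part1)
        if not part1 or not part2:
            continue
        cut_p = _cut_system(node_p, k, part1, part2)
        cut_c = constellation(cut_p, k, state)
        phi = min(phi, constellation_distance(intact, cut_c, node_p, k))
    return float(phi), len(intact)
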