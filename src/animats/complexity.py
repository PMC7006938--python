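"""Integrated information (Phi) of evolved Markov brains.

The analysis follows the cause-effect framework of integrated information
theory (IIT 3.0): for a candidate set ``S`` of computational units in a
particular state, every mechanism (non-empty subset of ``S``) is assessed
for how irreducibly it constrains the past (cause) and future (effect)
states of purviews within ``S``; the minimum over the two directions of
the maximally irreducible purview's distance-to-partition is the
mechanism's integrated information "small phi". Mechanisms with positive
small phi are the system's concepts. "Big Phi" is the minimal damage any
unidirectional system cut does to the whole concept structure, and
``Phi^Max`` maximizes big Phi over candidate subsets and (here) over every
brain state visited during one trial.

Conventions pinned by this implementation (the published analysis
delegates them to the IIT reference formulation):

* probabilities are interventional: sensors are clamped to their observed
  state, units outside the candidate set are frozen as background, and
  cause repertoires use a uniform perturbation prior;
* repertoire distances are earth mover's distances with Hamming ground
  metric over purview state space;
* system cuts are unidirectional (connections from one part to the other
  are noised); the concept-structure distance is a minimum-cost transport
  of small-phi mass between the intact and the cut concept sets, with
  repertoires expanded to the full candidate set (uniform over
  non-purview units) and surplus mass routed to the null concept (the
  unconstrained repertoire pair);
* candidate subsystems exclude sensor units; memory and motor units are
  eligible; a single-unit candidate set admits no bipartition and is
  assigned Phi = 0;
* ties between equally integrated subsets resolve to the
  lexicographically smallest unit set.

Purview/partition searches are exhaustive; exact evaluation is guarded to
candidate sets of at most 8 units and brains of at most 10 units overall
(larger brains report "not computed", mirroring the infeasibility of the
measure for big architectures).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from ._emd import emd_hamming, hamming_matrix, transport_cost
from .brain import MarkovBrain, step
from .engine import TrialLog

__all__ = [
    "CandidateSystem",
    "Concept",
    "PhiResult",
    "condition_tpm",
    "small_phi",
    "big_phi",
    "phi_max_over_lifetime",
]

EXACT_SUBSET_LIMIT = 8
MAX_BRAIN_UNITS = 10
_ATOL = 1e-12


class SubsetSizeError(ValueError):
    """Candidate set exceeds the exhaustive-search guard."""


@dataclass(frozen=True)
class CandidateSystem:
    """A conditioned subsystem: node TPMs with everything else clamped.

    ``nodes`` are brain unit ids (sorted ascending); node ``j`` occupies
    bit ``j`` of a system state index. ``node_probs[s, j]`` is the
    probability that node ``j`` is 1 at ``t+1`` given system state ``s``
    at ``t`` (deterministic brains yield 0/1 entries; cuts introduce
    fractional values).
    """

    nodes: tuple[int, ...]
    state: tuple[int, ...]
    node_probs: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.nodes)
        if self.node_probs.shape != (2**k, k):
            raise ValueError("node_probs must have shape (2**k, k)")
        self.node_probs.setflags(write=False)

    @property
    def size(self) -> int:
        return len(self.nodes)

    def effective_inputs(self) -> np.ndarray:
        """(k, k) bool: entry [i, j] true iff node i's state can change node j."""
        k = self.size
        eff = np.zeros((k, k), dtype=bool)
        states = np.arange(2**k)
        for i in range(k):
            flipped = states ^ (1 << i)
            eff[i] = np.any(
                self.node_probs[states] != self.node_probs[flipped], axis=0
            )
        return eff

    def with_cut(self, part_from: Sequence[int], part_to: Sequence[int]) -> "CandidateSystem":
        """Noise the connections from ``part_from`` into ``part_to``.

        Every node in ``part_to`` sees its inputs from ``part_from``
        marginalized uniformly (indices are system-internal).
        """
        k = self.size
        p = np.array(self.node_probs, dtype=np.float64)
        from_bits = list(part_from)
        n_from = len(from_bits)
        if n_from and part_to:
            states = np.arange(2**k)
            acc = np.zeros((2**k, len(part_to)), dtype=np.float64)
            for assign in range(2**n_from):
                s = states
                for bi, b in enumerate(from_bits):
                    bit = (assign >> bi) & 1
                    s = (s & ~(1 << b)) | (bit << b)
                acc += self.node_probs[np.asarray(s)][:, list(part_to)]
            p[:, list(part_to)] = acc / 2**n_from
        return CandidateSystem(self.nodes, self.state, p)

    @property
    def state_index(self) -> int:
        idx = 0
        for j, bit in enumerate(self.state):
            idx |= int(bit) << j
        return idx


@dataclass(frozen=True)
class Concept:
    """A mechanism with positive integrated information.

    Repertoires are stored over the full candidate set (expanded with the
    uniform distribution over non-purview units).
    """

    mechanism: tuple[int, ...]
    phi: float
    cause_purview: tuple[int, ...]
    effect_purview: tuple[int, ...]
    cause_repertoire: np.ndarray
    effect_repertoire: np.ndarray


@dataclass(frozen=True)
class PhiResult:
    """Phi^Max over candidate subsets (and, optionally, visited states)."""

    phi_max: float
    subset: tuple[int, ...]
    state: tuple[int, ...]
    n_concepts: int
    per_state: tuple = ()
    not_computed: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# conditioning


def condition_tpm(
    brain: MarkovBrain,
    subset: Sequence[int],
    sensor_state: Sequence[int],
    background_state: dict[int, int] | None = None,
) -> CandidateSystem:
    """Interventional node TPMs of ``subset`` with the rest clamped.

    ``subset`` lists non-sensor brain units; ``sensor_state`` clamps the
    sensors; ``background_state`` freezes non-member non-sensor units
    (default 0). Member units are perturbed into every one of their
    ``2**k`` joint states.
    """
    nodes = tuple(sorted(subset))
    if not nodes:
        raise ValueError("subset must be non-empty")
    if len(nodes) > EXACT_SUBSET_LIMIT:
        raise SubsetSizeError(
            f"candidate set of {len(nodes)} units exceeds the "
            f"{EXACT_SUBSET_LIMIT}-unit exhaustive-search guard"
        )
    arch = brain.arch
    sensors = set(arch.sensor_units)
    if any(u in sensors for u in nodes):
        raise ValueError("candidate sets contain computational units only")
    background = dict(background_state or {})
    base = np.zeros(arch.n_units, dtype=np.uint8)
    base[: arch.n_sensors] = np.asarray(sensor_state, dtype=np.uint8)
    for unit, val in background.items():
        base[unit] = val
    k = len(nodes)
    probs = np.zeros((2**k, k), dtype=np.float64)
    current = np.zeros(k, dtype=np.uint8)
    for s in range(2**k):
        cur = base.copy()
        for j, unit in enumerate(nodes):
            cur[unit] = (s >> j) & 1
        nxt = step(brain, cur, cur[: arch.n_sensors])
        for j, unit in enumerate(nodes):
            probs[s, j] = nxt[unit]
    return CandidateSystem(nodes, tuple(int(b) for b in current), probs)


def system_at_state(brain: MarkovBrain, subset: Sequence[int], full_state: int) -> CandidateSystem:
    """Condition on one packed full brain state (unit u in bit u)."""
    arch = brain.arch
    nodes = tuple(sorted(subset))
    sensor_state = [(full_state >> u) & 1 for u in arch.sensor_units]
    background = {
        u: (full_state >> u) & 1
        for u in arch.non_sensor_units
        if u not in nodes
    }
    sys_ = condition_tpm(brain, nodes, sensor_state, background)
    state = tuple((full_state >> u) & 1 for u in nodes)
    return CandidateSystem(sys_.nodes, state, np.array(sys_.node_probs))


# ---------------------------------------------------------------------------
# repertoires


def _subsets(items: Sequence[int], include_empty: bool = False) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = [()] if include_empty else []
    items = tuple(items)
    for r in range(1, len(items) + 1):
        out.extend(combinations(items, r))
    return out


def _mech_mask_states(k: int, mech: tuple[int, ...], y: tuple[int, ...]) -> np.ndarray:
    """Indices of system states consistent with mechanism state y."""
    states = np.arange(2**k)
    keep = np.ones(2**k, dtype=bool)
    for j, bit in zip(mech, y):
        keep &= ((states >> j) & 1) == bit
    return states[keep]


def effect_repertoire(
    sys_: CandidateSystem, mech: tuple[int, ...], y: tuple[int, ...],
    purview: tuple[int, ...],
) -> np.ndarray:
    """p(purview at t+1 | mechanism = y), non-mechanism inputs uniform.

    Factorizes over purview nodes (each conditioned independently), the
    standard virtual-element treatment for effect repertoires.
    """
    if not purview:
        return np.ones(1)
    rows = _mech_mask_states(sys_.size, mech, y)
    rep = np.ones(2 ** len(purview))
    states = np.arange(2 ** len(purview))
    for j, node in enumerate(purview):
        pj = sys_.node_probs[rows, node].mean()
        bit = (states >> j) & 1
        rep *= np.where(bit == 1, pj, 1.0 - pj)
    return rep


def cause_repertoire(
    sys_: CandidateSystem, mech: tuple[int, ...], y: tuple[int, ...],
    purview: tuple[int, ...],
) -> np.ndarray | None:
    """p(purview at t-1 | mechanism = y) under a uniform perturbation prior.

    Each mechanism node contributes the likelihood of its observed state
    given the purview state (non-purview past units marginalized
    uniformly); likelihoods multiply and the result is normalized. An
    all-zero repertoire (state unreachable) returns None.
    """
    if not purview:
        return np.ones(1)
    k = sys_.size
    n_v = len(purview)
    if not mech:
        return np.full(2**n_v, 1.0 / 2**n_v)
    states = np.arange(2**k)
    rep = np.ones(2**n_v)
    for node, bit in zip(mech, y):
        p1 = sys_.node_probs[:, node]
        like = p1 if bit == 1 else 1.0 - p1
        # average likelihood over states grouped by purview configuration
        group = np.zeros(2**k, dtype=np.int64)
        for j, v in enumerate(purview):
            group |= ((states >> v) & 1) << j
        sums = np.bincount(group, weights=like, minlength=2**n_v)
        counts = np.bincount(group, minlength=2**n_v)
        rep *= sums / counts
    total = rep.sum()
    if total <= _ATOL:
        return None
    return rep / total


def _repertoire(sys_, mech, y, purview, direction):
    if direction == "effect":
        return effect_repertoire(sys_, mech, y, purview)
    if not mech:
        return (
            np.full(2 ** len(purview), 1.0 / 2 ** len(purview))
            if purview
            else np.ones(1)
        )
    return cause_repertoire(sys_, mech, y, purview)


def _product_rep(rep1, pv1, rep2, pv2, purview):
    """Combine part repertoires onto the joint purview (sorted order)."""
    full = np.ones(2 ** len(purview))
    states = np.arange(2 ** len(purview))
    for rep, pv in ((rep1, pv1), (rep2, pv2)):
        if not pv:
            continue
        idx = np.zeros(2 ** len(purview), dtype=np.int64)
        for j_part, node in enumerate(pv):
            j_full = purview.index(node)
            idx |= ((states >> j_full) & 1) << j_part
        full *= rep[idx]
    return full


# ---------------------------------------------------------------------------
# small phi


def _mechanism_prunable(sys_, mech, eff, direction) -> bool:
    """A mechanism node with no connections in the tested direction makes
    the mechanism fully reducible (its factor splits off losslessly)."""
    for j in mech:
        if direction == "cause" and not eff[:, j].any():
            return True
        if direction == "effect" and not eff[j, :].any():
            return True
    return False


def _phi_direction(
    sys_: CandidateSystem,
    mech: tuple[int, ...],
    y: tuple[int, ...],
    direction: str,
    eff: np.ndarray,
) -> tuple[float, tuple[int, ...], np.ndarray | None]:
    """Max over purviews of the min-over-partitions repertoire distance.

    Returns (phi, core purview, core repertoire). Purviews are restricted
    to units actually connected to the mechanism (others factor out and
    give zero); iteration order is ascending size then lexicographic, and
    ties keep the first maximum.
    """
    if _mechanism_prunable(sys_, mech, eff, direction):
        return 0.0, (), None
    if direction == "cause":
        connected = [v for v in range(sys_.size) if any(eff[v, j] for j in mech)]
    else:
        connected = [v for v in range(sys_.size) if any(eff[j, v] for j in mech)]
    best_phi = 0.0
    best_purview: tuple[int, ...] = ()
    best_rep: np.ndarray | None = None
    mech_set = tuple(mech)
    for purview in _subsets(connected):
        whole = _repertoire(sys_, mech_set, y, purview, direction)
        if whole is None:
            continue
        min_d = np.inf
        for m1 in _subsets(mech_set, include_empty=True):
            y1 = tuple(b for j, b in zip(mech_set, y) if j in m1)
            m2 = tuple(j for j in mech_set if j not in m1)
            y2 = tuple(b for j, b in zip(mech_set, y) if j in m2)
            for r in range(len(purview) + 1):
                for v1 in combinations(purview, r):
                    v2 = tuple(v for v in purview if v not in v1)
                    if (not m1 and not v1) or (not m2 and not v2):
                        continue  # a part of (empty, empty) means no cut
                    rep1 = _repertoire(sys_, m1, y1, v1, direction)
                    rep2 = _repertoire(sys_, m2, y2, v2, direction)
                    if rep1 is None or rep2 is None:
                        continue
                    part = _product_rep(rep1, v1, rep2, v2, purview)
                    d = emd_hamming(whole, part)
                    if d < min_d:
                        min_d = d
                        if min_d <= _ATOL:
                            break
                if min_d <= _ATOL:
                    break
            if min_d <= _ATOL:
                break
        if np.isfinite(min_d) and min_d > best_phi + _ATOL:
            best_phi = float(min_d)
            best_purview = purview
            best_rep = whole
    return best_phi, best_purview, best_rep


def small_phi(
    sys_: CandidateSystem,
    mechanism: Sequence[int],
    state: Sequence[int] | None = None,
) -> dict:
    """Integrated information of one mechanism within the candidate set.

    ``mechanism`` holds system-internal node indices; ``state`` defaults
    to the system's current state restricted to the mechanism. Returns a
    dict with ``phi`` (min over cause/effect of the maximally irreducible
    purview's distance-to-partition) and the core purviews/repertoires.
    """
    mech = tuple(sorted(mechanism))
    if not mech:
        raise ValueError("mechanism must be non-empty")
    if state is None:
        y = tuple(sys_.state[j] for j in mech)
    else:
        y = tuple(int(b) for b in state)
    eff = sys_.effective_inputs()
    phi_c, pv_c, rep_c = _phi_direction(sys_, mech, y, "cause", eff)
    phi_e, pv_e, rep_e = _phi_direction(sys_, mech, y, "effect", eff)
    return {
        "phi": min(phi_c, phi_e),
        "phi_cause": phi_c,
        "phi_effect": phi_e,
        "cause_purview": pv_c,
        "effect_purview": pv_e,
        "cause_repertoire": rep_c,
        "effect_repertoire": rep_e,
    }


# ---------------------------------------------------------------------------
# big phi


def _expand_to_system(rep: np.ndarray | None, purview: tuple[int, ...], k: int) -> np.ndarray:
    """Expand a purview repertoire over all k units (uniform elsewhere)."""
    full = np.ones(2**k)
    states = np.arange(2**k)
    if rep is not None and purview:
        idx = np.zeros(2**k, dtype=np.int64)
        for j, node in enumerate(purview):
            idx |= ((states >> node) & 1) << j
        full = rep[idx]
    others = k - len(purview) if rep is not None else k
    return full / 2**others


def _constellation(sys_: CandidateSystem) -> list[Concept]:
    eff = sys_.effective_inputs()
    k = sys_.size
    concepts = []
    for mech in _subsets(range(k)):
        y = tuple(sys_.state[j] for j in mech)
        phi_c, pv_c, rep_c = _phi_direction(sys_, mech, y, "cause", eff)
        if phi_c <= _ATOL:
            continue
        phi_e, pv_e, rep_e = _phi_direction(sys_, mech, y, "effect", eff)
        phi = min(phi_c, phi_e)
        if phi <= _ATOL:
            continue
        concepts.append(
            Concept(
                mechanism=mech,
                phi=float(phi),
                cause_purview=pv_c,
                effect_purview=pv_e,
                cause_repertoire=_expand_to_system(rep_c, pv_c, k),
                effect_repertoire=_expand_to_system(rep_e, pv_e, k),
            )
        )
    return concepts


def _null_concept(sys_: CandidateSystem) -> tuple[np.ndarray, np.ndarray]:
    k = sys_.size
    cause = np.full(2**k, 1.0 / 2**k)
    effect = effect_repertoire(sys_, (), (), tuple(range(k)))
    return cause, effect


def _concept_distance(c1, c2, ham) -> float:
    dc = 0.0 if np.allclose(c1[0], c2[0], atol=_ATOL) else transport_cost(
        c1[0], c2[0], ham
    )
    de = 0.0 if np.allclose(c1[1], c2[1], atol=_ATOL) else transport_cost(
        c1[1], c2[1], ham
    )
    return dc + de


def _constellation_distance(
    intact: list[Concept], cut: list[Concept], sys_: CandidateSystem
) -> float:
    """Minimum-cost transport of small-phi mass between concept structures.

    Ground distance between two concepts is the sum of the EMDs between
    their expanded cause and effect repertoires; unbalanced mass is
    supplied by / delivered to the null concept.
    """
    ham = hamming_matrix(sys_.size)
    null = _null_concept(sys_)
    src = [(c.cause_repertoire, c.effect_repertoire) for c in intact]
    dst = [(c.cause_repertoire, c.effect_repertoire) for c in cut]
    supply = [c.phi for c in intact]
    demand = [c.phi for c in cut]
    diff = sum(supply) - sum(demand)
    src.append(null)
    dst.append(null)
    supply.append(max(0.0, -diff))
    demand.append(max(0.0, diff))
    cost = np.zeros((len(src), len(dst)))
    for i, ci in enumerate(src):
        for j, cj in enumerate(dst):
            cost[i, j] = _concept_distance(ci, cj, ham)
    return transport_cost(np.array(supply), np.array(demand), cost)


def big_phi(sys_: CandidateSystem) -> tuple[float, list[Concept]]:
    """Integrated information of the candidate set at its current state.

    Phi is the minimum over unidirectional bipartition cuts of the
    concept-structure distance between the intact and the cut system. A
    bipartition with no effective connections across it (feed-forward or
    disconnected systems always admit one) yields Phi = 0 immediately.
    """
    k = sys_.size
    concepts = _constellation(sys_)
    if not concepts:
        return 0.0, []
    if k == 1:
        # a lone unit has no parts to integrate across; no bipartition exists
        return 0.0, concepts
    eff = sys_.effective_inputs()
    cuts = []
    for part1 in _subsets(range(k)):
        part2 = tuple(j for j in range(k) if j not in part1)
        if not part2:
            continue
        crossing = any(eff[i, j] for i in part1 for j in part2)
        if not crossing:
            return 0.0, concepts  # cut severs nothing
        cuts.append((part1, part2))
    phi = np.inf
    for part1, part2 in cuts:
        cut_sys = sys_.with_cut(part1, part2)
        cut_concepts = _constellation(cut_sys)
        d = _constellation_distance(concepts, cut_concepts, sys_)
        if d < phi:
            phi = d
        if phi <= _ATOL:
            break
    return float(max(phi, 0.0)), concepts


# ---------------------------------------------------------------------------
# lifetime maximization


def phi_max_over_lifetime(
    brain: MarkovBrain,
    trial_log: TrialLog,
    *,
    animat: int | None = None,
    max_subset_size: int = 5,
) -> PhiResult:
    """Phi^Max over all visited brain states and candidate subsets.

    Visited states are taken from the trial log (one animat, or all
    clones pooled), deduplicated, and each is evaluated across every
    non-sensor subset of at most ``max_subset_size`` units; the overall
    maximum and the concept count of its subsystem are returned. Brains
    beyond the exact-mode guard report ``not_computed`` rather than an
    approximation.
    """
    arch = brain.arch
    if arch.n_units > MAX_BRAIN_UNITS:
        return PhiResult(
            phi_max=float("nan"),
            subset=(),
            state=(),
            n_concepts=0,
            not_computed=True,
            reason=(
                f"{arch.n_units} units exceed the {MAX_BRAIN_UNITS}-unit "
                "exact-mode guard"
            ),
        )
    states = trial_log.states
    if animat is not None:
        states = states[:, [animat]]
    visited = sorted({int(s) for s in states.ravel()})
    candidates = [
        tuple(sub)
        for r in range(1, min(max_subset_size, len(arch.non_sensor_units)) + 1)
        for sub in combinations(arch.non_sensor_units, r)
    ]
    best = (0.0, candidates[0], (), 0)
    per_state = []
    for full_state in visited:
        state_best = (0.0, candidates[0], 0)
        for subset in candidates:
            sys_ = system_at_state(brain, subset, full_state)
            phi, concepts = big_phi(sys_)
            if phi > state_best[0] + _ATOL:
                state_best = (phi, subset, len(concepts))
        per_state.append((full_state, *state_best))
        if state_best[0] > best[0] + _ATOL:
            best = (
                state_best[0],
                state_best[1],
                tuple((full_state >> u) & 1 for u in state_best[1]),
                state_best[2],
            )
    return PhiResult(
        phi_max=best[0],
        subset=best[1],
        state=best[2],
        n_concepts=best[3],
        per_state=tuple(per_state),
    )
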