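"""Integrated information: conditioning, small/big phi, lifetime maximum.

The heavy correctness check compares the package implementation against
the independent brute-force oracle in ``iit_oracle`` (separate code
path, no pruning) on systems of up to three units.
"""

from itertools import combinations

import numpy as np
import pytest

import iit_oracle as oracle
from animats.brain import ARCH_PRESETS, ArchitectureSpec, MarkovBrain
from animats.complexity import (
    CandidateSystem,
    SubsetSizeError,
    big_phi,
    condition_tpm,
    phi_max_over_lifetime,
    small_phi,
    system_at_state,
)
from animats.engine import InteractionRules, TrialConfig, run_trial_with_placement
from animats.fixtures import chain_brain, copy_loop_brain, idle_brain
from animats.genome import GateBlueprint
from animats.world import builtin_world

BASE = ARCH_PRESETS["baseline"]


def _sys(node_probs, state):
    k = int(np.log2(node_probs.shape[0]))
    return CandidateSystem(tuple(range(k)), tuple(state), np.asarray(node_probs, float))


def _mutual_copy():
    s = np.arange(4)
    return np.stack([(s >> 1) & 1, s & 1], axis=1).astype(float)


class TestConditionTpm:
    def test_gateless_brain_maps_to_zero(self):
        sys_ = condition_tpm(idle_brain(), BASE.memory_units[:3], [0, 0])
        assert (sys_.node_probs == 0).all()

    def test_copy_pair_conditioning_is_identity_on_the_pair(self):
        brain = copy_loop_brain()
        a, b = BASE.memory_units[:2]
        sys_ = condition_tpm(brain, (a, b), [0, 0])
        assert (sys_.node_probs == _mutual_copy()).all()

    def test_sensor_units_rejected_as_members(self):
        with pytest.raises(ValueError):
            condition_tpm(idle_brain(), (0, 2), [0, 0])

    def test_subset_size_guard(self):
        arch = ArchitectureSpec((("wall", "front"),), n_memory=8)
        with pytest.raises(SubsetSizeError):
            condition_tpm(idle_brain(arch), arch.non_sensor_units, [0])

    def test_clamped_background_equals_marginal_row_restriction(self):
        """Conditioning {A,B} with C frozen equals restricting the
        {A,B,C} system's rows to the frozen C value."""
        a, b, c = BASE.memory_units[:3]
        gates = (
            GateBlueprint((a, c), (b,), (0, 1, 1, 1)),  # B <- A or C
            GateBlueprint((b,), (a,), (0, 1)),
            GateBlueprint((c,), (c,), (0, 1)),
        )
        brain = MarkovBrain(BASE, gates)
        for c_val in (0, 1):
            small = condition_tpm(brain, (a, b), [0, 0], {c: c_val})
            big = condition_tpm(brain, (a, b, c), [0, 0])
            for s in range(4):
                big_row = s | (c_val << 2)
                assert (
                    small.node_probs[s] == big.node_probs[big_row, :2]
                ).all()


class TestSmallPhi:
    def test_unconnected_mechanism_is_fully_reducible(self):
        # a node with neither inputs nor outputs inside the system
        s = np.arange(4)
        p = np.stack([s & 1, np.zeros(4)], axis=1).astype(float)  # A self-loop, B inert
        res = small_phi(_sys(p, (0, 0)), [1])
        assert res["phi"] == 0.0

    def test_copy_loop_singletons_are_irreducible(self):
        sys_ = _sys(_mutual_copy(), (1, 0))
        assert small_phi(sys_, [0])["phi"] == pytest.approx(0.5)
        assert small_phi(sys_, [1])["phi"] == pytest.approx(0.5)

    def test_product_system_pair_mechanism_is_reducible(self):
        # two independent self-copying units: the joint mechanism splits
        s = np.arange(4)
        p = np.stack([s & 1, (s >> 1) & 1], axis=1).astype(float)
        assert small_phi(_sys(p, (0, 1)), [0, 1])["phi"] == 0.0


class TestBigPhi:
    def test_feed_forward_system_has_zero_phi(self):
        s = np.arange(4)
        p = np.stack([np.zeros(4), s & 1], axis=1).astype(float)  # A -> B chain
        phi, _ = big_phi(_sys(p, (1, 0)))
        assert phi == 0.0

    def test_disconnected_system_has_zero_phi(self):
        s = np.arange(4)
        p = np.stack([s & 1, (s >> 1) & 1], axis=1).astype(float)
        phi, _ = big_phi(_sys(p, (0, 1)))
        assert phi == 0.0

    def test_single_unit_self_loop_has_zero_phi(self):
        # a lone unit cannot be bipartitioned, even with a self-loop
        p = np.array([[0.0], [1.0]])
        phi, concepts = big_phi(CandidateSystem((5,), (1,), p))
        assert phi == 0.0
        assert len(concepts) == 1

    def test_mutual_copy_is_integrated_with_two_concepts(self):
        phi, concepts = big_phi(_sys(_mutual_copy(), (1, 0)))
        assert phi > 0
        assert len(concepts) == 2
        assert {c.mechanism for c in concepts} == {(0,), (1,)}


def _oracle_cases():
    rng = np.random.Generator(np.random.MT19937(99))
    cases = []
    # 1-unit systems: self-loop and inert
    cases.append(("self-loop", np.array([[0.0], [1.0]]), (1,)))
    cases.append(("inert", np.array([[0.0], [0.0]]), (0,)))
    # 2-unit: mutual copy, chain, AND-pair
    s2 = np.arange(4)
    cases.append(("copy-pair", _mutual_copy(), (1, 0)))
    cases.append(
        ("chain2", np.stack([np.zeros(4), s2 & 1], 1).astype(float), (1, 1))
    )
    both = ((s2 & 1) & ((s2 >> 1) & 1)).astype(float)
    cases.append(("and-pair", np.stack([both, both], 1), (1, 1)))
    # 3-unit: rotating copy loop plus two random deterministic systems
    s3 = np.arange(8)
    loop = np.stack([(s3 >> 2) & 1, s3 & 1, (s3 >> 1) & 1], 1).astype(float)
    cases.append(("loop3", loop, (1, 0, 1)))
    for i in range(2):
        p = rng.integers(0, 2, size=(8, 3)).astype(float)
        st = tuple(int(b) for b in rng.integers(0, 2, 3))
        cases.append((f"random3-{i}", p, st))
    return cases


@pytest.mark.parametrize(
    "label, node_p, state", _oracle_cases(), ids=[c[0] for c in _oracle_cases()]
)
def test_implementation_agrees_with_brute_force_oracle(label, node_p, state):
    """Small phi (every mechanism) and big Phi match the independent
    exhaustive oracle to 1e-9 on all systems of at most 3 units."""
    k = node_p.shape[1]
    sys_ = _sys(node_p, state)
    for r in range(1, k + 1):
        for mech in combinations(range(k), r):
            y = tuple(state[j] for j in mech)
            impl = small_phi(sys_, mech)["phi"]
            ref = oracle.small_phi(node_p, k, mech, y)
            assert impl == pytest.approx(ref, abs=1e-9), (label, mech)
    phi_impl, concepts = big_phi(sys_)
    phi_ref, n_ref = oracle.big_phi(node_p, state)
    assert phi_impl == pytest.approx(phi_ref, abs=1e-9), label
    assert len(concepts) == n_ref, label


class TestPhiMaxOverLifetime:
    def _short_log(self, brain, T=10):
        world = builtin_world("original")
        return run_trial_with_placement(
            world, brain, TrialConfig(T=T, group_size=1), InteractionRules(),
            [(5, 9)], [1],
        )

    def test_gateless_brain_has_zero_phi_and_no_concepts(self):
        brain = idle_brain()
        res = phi_max_over_lifetime(brain, self._short_log(brain))
        assert res.phi_max == 0.0
        assert res.n_concepts == 0
        assert not res.not_computed

    def test_feed_forward_chain_has_zero_phi(self):
        brain = chain_brain()
        res = phi_max_over_lifetime(brain, self._short_log(brain))
        assert res.phi_max == 0.0

    def test_copy_loop_brain_matches_direct_big_phi(self):
        brain = copy_loop_brain()
        log = self._short_log(brain, T=5)
        res = phi_max_over_lifetime(brain, log, max_subset_size=2)
        a, b = BASE.memory_units[:2]
        best = 0.0
        for full_state in {int(s) for s in log.states.ravel()}:
            sys_ = system_at_state(brain, (a, b), full_state)
            best = max(best, big_phi(sys_)[0])
        assert res.phi_max == pytest.approx(best)

    def test_more_states_never_decrease_the_maximum(self):
        brain = copy_loop_brain()
        short = self._short_log(brain, T=3)
        longer = self._short_log(brain, T=12)
        r_short = phi_max_over_lifetime(brain, short, max_subset_size=2)
        r_long = phi_max_over_lifetime(brain, longer, max_subset_size=2)
        assert r_long.phi_max >= r_short.phi_max - 1e-12

    def test_oversized_brain_reports_not_computed(self):
        arch = ARCH_PRESETS["bigbrain"]  # 12 units
        brain = idle_brain(arch)
        log = self._short_log(brain, T=3)
        res = phi_max_over_lifetime(brain, log)
        assert res.not_computed
        assert "exceed" in res.reason
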