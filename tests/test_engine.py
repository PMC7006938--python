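"""Trial dynamics, sensing, action resolution, and fitness scoring."""

import numpy as np
import pytest

from animats.brain import ARCH_PRESETS, MarkovBrain, step
from animats.engine import (
    GROUP_SIZES,
    EvalSetup,
    InteractionRules,
    TrialConfig,
    resolve_action,
    run_trial,
    run_trial_with_placement,
    score_animat,
    score_genome,
    sense,
)
from animats import _kernel
from animats.fixtures import (
    forward_brain,
    gate_oscillator_log,
    idle_brain,
    scripted_log,
    turn_brain,
)
from animats.genome import random_genome
from conftest import mt

BASE = ARCH_PRESETS["baseline"]
RULES = InteractionRules()


class TestResolveAction:
    @pytest.mark.parametrize(
        "bits, action",
        [((0, 0), "none"), ((1, 1), "forward"), ((1, 0), "turn_left"), ((0, 1), "turn_right")],
    )
    def test_motor_mapping(self, bits, action):
        assert resolve_action(bits) == action

    def test_four_turns_return_to_original_orientation(self, original_world):
        log = run_trial_with_placement(
            original_world, turn_brain("left"), TrialConfig(T=8, group_size=1),
            RULES, [(5, 5)], [0],
        )
        orients = log.orientation[:, 0].tolist()
        assert orients[1:5] == [3, 2, 1, 0]  # rotation group closes after 4 turns
        assert orients[5] == orients[1]


class TestSense:
    def test_wall_directly_ahead(self, original_world):
        occ = np.zeros((32, 32), dtype=np.int16)
        bits = sense(original_world, occ, (1, 5), 3, BASE)  # facing left wall
        assert bits.tolist() == [1, 0]

    def test_detection_range_is_one_cell(self, original_world):
        occ = np.zeros((32, 32), dtype=np.int16)
        bits = sense(original_world, occ, (3, 5), 3, BASE)  # wall two cells away
        assert bits.tolist() == [0, 0]

    def test_agent_sensor_sees_neighbor(self, original_world):
        occ = np.zeros((32, 32), dtype=np.int16)
        occ[5, 6] = 1
        bits = sense(original_world, occ, (5, 5), 1, BASE)  # facing right
        assert bits.tolist() == [0, 1]

    def test_universal_sensor_cannot_distinguish(self, original_world):
        arch = ARCH_PRESETS["w=a"]
        occ = np.zeros((32, 32), dtype=np.int16)
        occ[5, 6] = 1
        assert sense(original_world, occ, (5, 5), 1, arch).tolist() == [1]
        occ[5, 6] = 0
        assert sense(original_world, occ, (1, 5), 3, arch).tolist() == [1]

    def test_sides_are_relative_to_heading(self, original_world):
        arch = ARCH_PRESETS["3sides"]
        occ = np.zeros((32, 32), dtype=np.int16)
        occ[4, 5] = 1  # cell above (5,5)
        # facing right: the agent above is on the animat's left
        bits = sense(original_world, occ, (5, 5), 1, arch)
        assert bits.tolist() == [0, 0, 0, 0, 1, 0]


class TestTrialDynamics:
    def test_idle_brain_stays_put(self, original_world):
        log = run_trial(
            original_world, idle_brain(), TrialConfig(T=50, group_size=10),
            RULES, mt(3),
        )
        assert (log.x == log.x[0]).all() and (log.y == log.y[0]).all()
        assert not log.crossings.any()
        assert (log.actions == 0).all()

    def test_identical_seeds_give_bit_identical_logs(self, original_world):
        brain = MarkovBrain.from_genome(random_genome(4000, mt(5)), BASE)
        cfg = TrialConfig(T=100, group_size=20)
        a = run_trial(original_world, brain, cfg, RULES, mt(42))
        b = run_trial(original_world, brain, cfg, RULES, mt(42))
        for name in ("x", "y", "orientation", "states", "sensors", "actions", "crossings", "collisions"):
            assert (getattr(a, name) == getattr(b, name)).all()

    def test_single_animat_matches_pure_python_reference(self, original_world):
        """The kernel reproduces a step-by-step simulation built from the
        reference sense/step/action primitives."""
        brain = MarkovBrain.from_genome(random_genome(4000, mt(6)), BASE)
        start, orient = (5, 9), 1
        T = 60
        log = run_trial_with_placement(
            original_world, brain, TrialConfig(T=T, group_size=1), RULES,
            [start], [orient],
        )
        occ = np.zeros((32, 32), dtype=np.int16)
        x, y, o = start[0], start[1], orient
        state = np.zeros(BASE.n_units, dtype=np.uint8)
        for t in range(1, T + 1):
            bits = sense(original_world, occ, (x, y), o, BASE)
            state = step(brain, state, bits)
            action = resolve_action(tuple(state[list(BASE.motor_units)]))
            if action == "turn_left":
                o = (o + 3) % 4
            elif action == "turn_right":
                o = (o + 1) % 4
            elif action == "forward":
                dx, dy = [(0, -1), (1, 0), (0, 1), (-1, 0)][o][0], [(0, -1), (1, 0), (0, 1), (-1, 0)][o][1]
                if not original_world.is_wall(x + dx, y + dy):
                    x, y = x + dx, y + dy
            assert (log.x[t, 0], log.y[t, 0], log.orientation[t, 0]) == (x, y, o)

    def test_forward_walk_through_gate_logs_crossing(self, original_world):
        # the gate sits on the dividing wall; walk straight through it
        gx, gy = original_world.rewarding_gate_cells[0]
        log = run_trial_with_placement(
            original_world, forward_brain(), TrialConfig(T=10, group_size=1),
            RULES, [(gx - 1, gy)], [1],
        )
        crossings = np.nonzero(log.crossings[:, 0])[0]
        assert len(crossings) == 1
        assert log.crossings[crossings[0], 0] == 2  # rewarding gate

    def test_converging_animats_overlap_once_without_blocking(self, original_world):
        log = run_trial_with_placement(
            original_world, forward_brain(), TrialConfig(T=500, group_size=2),
            RULES, [(5, 5), (7, 5)], [1, 3],
        )
        assert int(log.collisions[:, 0].sum()) == 1
        assert int(log.collisions[:, 1].sum()) == 1
        assert not log.crossings.any()
        assert score_animat(log, 0, RULES) == pytest.approx(-0.075)

    def test_blocking_prevents_overlap(self, original_world):
        rules = InteractionRules(blocking=True)
        log = run_trial_with_placement(
            original_world, forward_brain(), TrialConfig(T=100, group_size=2),
            rules, [(5, 5), (7, 5)], [1, 3],
        )
        assert not log.collisions.any()
        for t in range(101):
            assert (log.x[t, 0], log.y[t, 0]) != (log.x[t, 1], log.y[t, 1])

    def test_blocking_occupancy_never_exceeds_one(self, original_world):
        rules = InteractionRules(blocking=True)
        log = run_trial(
            original_world, forward_brain(), TrialConfig(T=80, group_size=72),
            rules, mt(9),
        )
        for t in range(0, 81, 20):
            cells = list(zip(log.x[t], log.y[t]))
            assert len(set(cells)) == len(cells)

    def test_group_size_beyond_slots_rejected(self, original_world):
        with pytest.raises(ValueError, match="start slots"):
            run_trial(
                original_world, idle_brain(), TrialConfig(T=5, group_size=73),
                RULES, mt(0),
            )


class TestScoring:
    def test_idle_animat_scores_zero(self):
        assert score_animat(scripted_log(), 0, RULES) == 0.0

    def test_single_co_occupancy_timestep_costs_one_penalty(self):
        log = scripted_log(group_size=2, collisions=[(37, 0)])
        assert score_animat(log, 0, RULES) == pytest.approx(-0.075)
        assert score_animat(log, 1, RULES) == 0.0

    def test_refractory_blocks_second_crossing_and_resets(self):
        # crossings at t=10 and t=60: the second is inside the window,
        # and being a crossing it restarts the window itself
        log = scripted_log(crossings={(10, 0): 2, (60, 0): 2})
        assert score_animat(log, 0, RULES) == 1.0
        # a third crossing 90 steps after the unrewarded one is still blocked
        log = scripted_log(crossings={(10, 0): 2, (60, 0): 2, (150, 0): 2})
        assert score_animat(log, 0, RULES) == 1.0

    @pytest.mark.parametrize("spacing, expected", [(100, 1.0), (101, 2.0)])
    def test_refractory_window_boundary(self, spacing, expected):
        log = scripted_log(crossings={(10, 0): 2, (10 + spacing, 0): 2})
        assert score_animat(log, 0, RULES) == expected

    def test_non_rewarding_gate_crossings_never_score(self):
        log = scripted_log(crossings={(10, 0): 1, (200, 0): 1})
        assert score_animat(log, 0, RULES) == 0.0

    def test_reward_cap_limits_oscillator_to_four_points(self):
        log = gate_oscillator_log()
        assert sum(1 for _ in np.nonzero(log.crossings[:, 0])[0]) == 5
        assert score_animat(log, 0, RULES) == 4.0

    def test_score_bound_holds_for_random_brains(self, original_world):
        for seed in range(5):
            brain = MarkovBrain.from_genome(random_genome(5000, mt(seed)), BASE)
            log = run_trial(
                original_world, brain, TrialConfig(group_size=36), RULES, mt(seed),
            )
            for a in range(36):
                assert score_animat(log, a, RULES) <= 4.0

    def test_penalty_off_scores_are_nonnegative_reward_multiples(self, original_world):
        rules = InteractionRules(penalty_active=False)
        brain = forward_brain()
        log = run_trial(
            original_world, brain, TrialConfig(group_size=40), rules, mt(1),
        )
        for a in range(40):
            f = score_animat(log, a, rules)
            assert f >= 0 and f == int(f)

    def test_kernel_scorer_agrees_with_log_scorer(self, original_world):
        brain = MarkovBrain.from_genome(random_genome(5000, mt(21)), BASE)
        log = run_trial(
            original_world, brain, TrialConfig(T=200, group_size=30), RULES, mt(3),
        )
        kernel_scores = _kernel.score_events(
            log.crossings, log.collisions, RULES.reward, RULES.penalty,
            RULES.penalty_active, RULES.refractory, 4,
        )
        for a in range(30):
            assert kernel_scores[a] == pytest.approx(score_animat(log, a, RULES))


class TestScoreGenome:
    def test_idle_genome_scores_zero_with_distinct_starts(self, original_world):
        setup = EvalSetup(arch=BASE, trials=5, group_size=36)
        assert score_genome(original_world, idle_brain(), setup, mt(0)) == 0.0

    def test_deterministic_given_seed(self, original_world):
        g = random_genome(4000, mt(2))
        setup = EvalSetup(arch=BASE, trials=6, group_size=14)
        a = score_genome(original_world, g, setup, mt(5))
        b = score_genome(original_world, g, setup, mt(5))
        assert a == b

    def test_random_group_size_draws_from_vector(self, original_world):
        setup = EvalSetup(arch=BASE, trials=8, group_size="random")
        f = score_genome(original_world, idle_brain(), setup, mt(4))
        assert f == 0.0  # idle animats never collide from distinct slots
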