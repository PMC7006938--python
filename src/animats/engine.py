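"""Trial simulation and fitness scoring for clone groups.

One trial places ``group_size`` clones of a single genome on distinct
start slots, simulates ``T`` timesteps (default 500), and logs positions,
sensor/motor activity, gate crossings and co-occupancy events. An
animat's fitness is the reward (+1.0) for each crossing of a rewarding
gate outside the 100-step refractory window (capped at 4 rewarded
crossings per trial), minus the collision penalty (0.075) for every
timestep it shares a cell with another animat while the penalty rule is
active. A genome's fitness is the mean, over independently seeded trials,
of the score of one randomly picked clone per trial.

Taken literally, the reward rule would allow a fifth rewarded
crossing for a very early first crossing; the stated per-trial maximum is
4 points, which the default ``reward_cap`` enforces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .brain import ArchitectureSpec, MarkovBrain
from .genome import Genome
from .world import GridWorld

__all__ = [
    "GROUP_SIZES",
    "InteractionRules",
    "TrialConfig",
    "EvalSetup",
    "TrialLog",
    "sense",
    "resolve_action",
    "run_trial",
    "score_animat",
    "score_genome",
]

#: the 21 test group sizes; also the pool for the random-group-size setup
GROUP_SIZES = (1, 4, 7, 11, 14, 18, 22, 25, 29, 32, 36, 40, 43, 47, 50, 54, 58, 61, 65, 68, 72)

ACTIONS = ("none", "turn", "forward")


@dataclass(frozen=True)
class InteractionRules:
    """How animats affect each other during a trial."""

    penalty_active: bool = True
    penalty: float = 0.075
    blocking: bool = False
    reward: float = 1.0
    refractory: int = 100

    def __post_init__(self) -> None:
        if self.penalty < 0 or self.reward <= 0 or self.refractory < 0:
            raise ValueError("need penalty >= 0, reward > 0, refractory >= 0")


@dataclass(frozen=True)
class TrialConfig:
    T: int = 500
    group_size: int = 36
    reward_cap: int = 4

    def __post_init__(self) -> None:
        if self.T <= 0 or self.group_size < 1:
            raise ValueError("need T > 0 and group_size >= 1")


@dataclass(frozen=True)
class EvalSetup:
    """Everything needed to score a genome: architecture, rules, trials.

    ``group_size`` may be an int (fixed) or the string ``"random"``, in
    which case each trial's group size is drawn uniformly from
    ``group_size_vector`` (default: the 21-element test vector).
    """

    arch: ArchitectureSpec
    rules: InteractionRules = InteractionRules()
    trials: int = 30
    group_size: int | str = 36
    group_size_vector: tuple[int, ...] = GROUP_SIZES
    T: int = 500
    reward_cap: int = 4


@dataclass(frozen=True)
class TrialLog:
    """Complete per-timestep record of one trial.

    Arrays are indexed ``[t, a]``; positions/orientations/states/collisions
    cover times 0..T, while sensors/actions/crossings describe the step
    into time ``t`` and live in row ``t - 1`` (t = 1..T). ``crossings``
    holds 0 (none), 1 (through a non-rewarding gate) or 2 (rewarding
    gate). ``states`` packs the full binary brain state (unit u in bit u).
    """

    world_name: str
    T: int
    x: np.ndarray
    y: np.ndarray
    orientation: np.ndarray
    states: np.ndarray
    sensors: np.ndarray       # packed sensor bits, shape (T, N)
    actions: np.ndarray       # realized action codes 0/1/2, shape (T, N)
    crossings: np.ndarray     # (T, N)
    collisions: np.ndarray    # co-occupancy flags, (T+1, N)
    n_sensors: int

    @property
    def group_size(self) -> int:
        return int(self.x.shape[1])

    def sensor_bit(self, t: int, a: int, si: int) -> int:
        return (int(self.sensors[t, a]) >> si) & 1

    def any_sensor(self) -> np.ndarray:
        """(T, N) flags: did any sensor fire at that step."""
        return self.sensors > 0

    def moved(self) -> np.ndarray:
        """(T, N) flags: did the animat turn or move forward."""
        return self.actions > 0

    def to_frame(self) -> pd.DataFrame:
        """One row per animat-timestep (times 1..T) with realized events."""
        T, n = self.actions.shape
        t_idx = np.repeat(np.arange(1, T + 1), n)
        a_idx = np.tile(np.arange(n), T)
        return pd.DataFrame(
            {
                "t": t_idx,
                "animat": a_idx,
                "x": self.x[1:].ravel(),
                "y": self.y[1:].ravel(),
                "orientation": self.orientation[1:].ravel(),
                "sensors": self.sensors.ravel(),
                "action": [ACTIONS[c] for c in self.actions.ravel()],
                "crossing": self.crossings.ravel(),
                "collision": self.collisions[1:].ravel(),
            }
        )

    def events_summary(self) -> dict:
        return {
            "world": self.world_name,
            "T": self.T,
            "group_size": self.group_size,
            "crossings": int((self.crossings > 0).sum()),
            "rewarding_crossings": int((self.crossings == 2).sum()),
            "collision_timesteps": int(self.collisions.sum()),
        }

    def save(self, table_path, summary_path=None) -> None:
        self.to_frame().to_csv(table_path, index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.events_summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# reference semantics (pure Python; the kernel must agree with these)


def sense(
    world: GridWorld,
    occupancy: np.ndarray,
    position: tuple[int, int],
    orientation: int,
    arch: ArchitectureSpec,
) -> np.ndarray:
    """Sensor bit vector for an animat at ``position`` facing ``orientation``.

    Each sensor inspects the single adjacent cell on its side (detection
    range one): wall sensors fire on wall cells (the boundary counts),
    agent sensors on cells occupied by another animat, universal sensors
    on either.
    """
    x, y = position
    bits = np.zeros(arch.n_sensors, dtype=np.uint8)
    for si, (kind, side) in enumerate(arch.sensor_slots):
        d = (orientation + _kernel.SIDE_OFFSETS[side]) % 4
        nx = x + int(_kernel._DX[d])
        ny = y + int(_kernel._DY[d])
        is_wall = world.is_wall(nx, ny)
        has_agent = (not is_wall) and occupancy[ny, nx] > 0
        if kind == "wall":
            bits[si] = is_wall
        elif kind == "agent":
            bits[si] = has_agent
        else:
            bits[si] = is_wall or has_agent
    return bits


def resolve_action(motor_bits: tuple[int, int]) -> str:
    """Map the two motor states to an action.

    Both motors on drives the animat forward; one motor turns 90 degrees
    (first motor: left, second: right — the left/right labeling is a
    convention, the task is symmetric under swapping it); both off is no
    movement.
    """
    m0, m1 = motor_bits
    if m0 and m1:
        return "forward"
    if m0:
        return "turn_left"
    if m1:
        return "turn_right"
    return "none"


def _sensor_arrays(arch: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
    kinds = np.array(
        [_kernel.KIND_CODES[k] for k, _ in arch.sensor_slots], dtype=np.int8
    )
    offs = np.array(
        [_kernel.SIDE_OFFSETS[s] for _, s in arch.sensor_slots], dtype=np.int8
    )
    return kinds, offs


def _world_arrays(world: GridWorld):
    return (
        np.ascontiguousarray(world.wall),
        np.ascontiguousarray(world.room.astype(np.int32)),
        np.ascontiguousarray(world.gate_rewarding),
    )


def _draw_placement(world: GridWorld, n: int, rng: np.random.Generator):
    slots = np.asarray(world.start_slots, dtype=np.int64)
    if n > slots.shape[0]:
        raise ValueError(
            f"group_size {n} exceeds the {slots.shape[0]} available start slots"
        )
    idx = rng.choice(slots.shape[0], size=n, replace=False)
    sx = slots[idx, 0].astype(np.int16)
    sy = slots[idx, 1].astype(np.int16)
    so = rng.integers(0, 4, size=n).astype(np.int8)
    order = rng.permutation(n).astype(np.int64)
    return sx, sy, so, order


def run_trial_with_placement(
    world: GridWorld,
    brain: MarkovBrain,
    config: TrialConfig,
    rules: InteractionRules,
    positions: Sequence[tuple[int, int]],
    orientations: Sequence[int],
    order: Sequence[int] | None = None,
) -> TrialLog:
    """Simulate a trial from explicit start positions and orientations.

    Deterministic companion of :func:`run_trial` for scripted scenarios;
    the serial order defaults to index order.
    """
    n = len(positions)
    sx = np.array([p[0] for p in positions], dtype=np.int16)
    sy = np.array([p[1] for p in positions], dtype=np.int16)
    so = np.asarray(orientations, dtype=np.int8)
    order_arr = (
        np.arange(n, dtype=np.int64)
        if order is None
        else np.asarray(order, dtype=np.int64)
    )
    for x, y in positions:
        if world.is_wall(x, y):
            raise ValueError(f"start position ({x}, {y}) is a wall")
    wall, room, grew = _world_arrays(world)
    s_kind, s_off = _sensor_arrays(brain.arch)
    out = _kernel.simulate_logged(
        wall, room, grew, sx, sy, so, order_arr,
        brain.lookup_table(), s_kind, s_off,
        brain.arch.n_memory, rules.blocking, config.T,
    )
    return _wrap_log(world, config, brain, out)


def _wrap_log(world, config, brain, out) -> TrialLog:
    log_x, log_y, log_o, log_state, log_sens, log_act, log_cross, log_coll = out
    return TrialLog(
        world_name=world.name,
        T=config.T,
        x=log_x,
        y=log_y,
        orientation=log_o,
        states=log_state,
        sensors=log_sens,
        actions=log_act,
        crossings=log_cross,
        collisions=log_coll,
        n_sensors=brain.arch.n_sensors,
    )


def run_trial(
    world: GridWorld,
    brain: MarkovBrain,
    config: TrialConfig,
    rules: InteractionRules,
    rng: np.random.Generator,
) -> TrialLog:
    """Simulate one trial of ``group_size`` clones and return the full log.

    Start slots are sampled without replacement, initial orientations
    uniformly; one serial-order permutation is drawn and reused at every
    timestep. Two calls with identically seeded generators produce
    bit-identical logs.
    """
    sx, sy, so, order = _draw_placement(world, config.group_size, rng)
    wall, room, grew = _world_arrays(world)
    s_kind, s_off = _sensor_arrays(brain.arch)
    out = _kernel.simulate_logged(
        wall, room, grew, sx, sy, so, order,
        brain.lookup_table(), s_kind, s_off,
        brain.arch.n_memory, rules.blocking, config.T,
    )
    return _wrap_log(world, config, brain, out)


def score_animat(
    log: TrialLog,
    animat: int,
    rules: InteractionRules,
    reward_cap: int = 4,
) -> float:
    """Fitness of one animat recomputed from a trial log.

    A crossing of a rewarding gate at time t earns ``reward`` iff no
    crossing of any kind occurred within the previous ``refractory``
    timesteps (any crossing, rewarded or not, restarts the window).
    Rewarded crossings are capped at ``reward_cap``. Each timestep spent
    on a cell occupied by more than one animat costs ``penalty`` while
    the penalty rule is active.
    """
    last = -(10**9)
    rewarded = 0
    for s in range(log.crossings.shape[0]):
        c = int(log.crossings[s, animat])
        if c:
            t = s + 1
            if c == 2 and t - last > rules.refractory:
                rewarded += 1
            last = t
    score = rules.reward * min(rewarded, reward_cap)
    if rules.penalty_active:
        score -= rules.penalty * int(log.collisions[:, animat].sum())
    return float(score)


def score_genome(
    world: GridWorld,
    genome: Genome | MarkovBrain,
    setup: EvalSetup,
    rng: np.random.Generator,
) -> float:
    """Mean, over ``setup.trials`` trials, of one random clone's fitness."""
    brain = (
        genome
        if isinstance(genome, MarkovBrain)
        else MarkovBrain.from_genome(genome, setup.arch)
    )
    if setup.group_size == "random":
        sizes = rng.choice(np.asarray(setup.group_size_vector), size=setup.trials)
    else:
        sizes = np.full(setup.trials, int(setup.group_size))
    wall, room, grew = _world_arrays(world)
    s_kind, s_off = _sensor_arrays(brain.arch)
    lookup = brain.lookup_table()
    rules = setup.rules
    scores = np.empty(setup.trials)
    # trials are batched by group size so the kernel sees rectangular arrays
    for n in np.unique(sizes):
        rows = np.nonzero(sizes == n)[0]
        R = rows.size
        sx = np.empty((R, n), dtype=np.int16)
        sy = np.empty((R, n), dtype=np.int16)
        so = np.empty((R, n), dtype=np.int8)
        orders = np.empty((R, n), dtype=np.int64)
        picks = np.empty(R, dtype=np.int64)
        for i in range(R):
            sx[i], sy[i], so[i], orders[i] = _draw_placement(world, int(n), rng)
            picks[i] = rng.integers(0, n)
        scores[rows] = _kernel.evaluate_trials(
            wall, room, grew, sx, sy, so, orders, picks,
            lookup, s_kind, s_off, brain.arch.n_memory,
            rules.blocking, setup.T,
            rules.reward, rules.penalty, rules.penalty_active,
            rules.refractory, setup.reward_cap,
        )
    return float(scores.mean())
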