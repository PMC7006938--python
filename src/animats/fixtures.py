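"""Hand-wired brains and scripted trial logs.

These fixtures make every stage of the pipeline testable without running
evolution: deterministic brains with known behavior (idle, always
forward, always turning, memory copy loops, a strictly feed-forward
chain) and synthetic trial logs with prescribed crossing and collision
events for exercising the scoring and statistics operations in
isolation.

Scripted logs carry physically meaningless positions (all zeros): they
exist to feed the scoring/statistics operations prescribed event
sequences, not to replay spatial dynamics. Use the hand-wired brains
with :func:`animats.engine.run_trial_with_placement` when real dynamics
matter.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .brain import ARCH_PRESETS, ArchitectureSpec, MarkovBrain
from .engine import TrialLog
from .genome import GateBlueprint

__all__ = [
    "idle_brain",
    "forward_brain",
    "turn_brain",
    "copy_loop_brain",
    "chain_brain",
    "scripted_log",
    "gate_oscillator_log",
]


def idle_brain(arch: ArchitectureSpec | None = None) -> MarkovBrain:
    """A brain with no gates: every non-sensor unit stays 0, no movement."""
    return MarkovBrain(arch or ARCH_PRESETS["baseline"], ())


def forward_brain(arch: ArchitectureSpec | None = None) -> MarkovBrain:
    """Both motors always on: the animat drives forward every step."""
    arch = arch or ARCH_PRESETS["baseline"]
    m0, m1 = arch.motor_units
    gate = GateBlueprint((arch.sensor_units[0],), (m0, m1), (3, 3))
    return MarkovBrain(arch, (gate,))


def turn_brain(direction: str = "left", arch: ArchitectureSpec | None = None) -> MarkovBrain:
    """One motor always on: the animat spins in place."""
    arch = arch or ARCH_PRESETS["baseline"]
    motor = arch.motor_units[0] if direction == "left" else arch.motor_units[1]
    gate = GateBlueprint((arch.sensor_units[0],), (motor,), (1, 1))
    return MarkovBrain(arch, (gate,))


def copy_loop_brain(arch: ArchitectureSpec | None = None) -> MarkovBrain:
    """Two memory units copying each other: a minimal integrated core."""
    arch = arch or ARCH_PRESETS["baseline"]
    a, b = arch.memory_units[:2]
    gates = (
        GateBlueprint((a,), (b,), (0, 1)),
        GateBlueprint((b,), (a,), (0, 1)),
    )
    return MarkovBrain(arch, gates)


def chain_brain() -> MarkovBrain:
    """A 4-unit strictly feed-forward brain: sensor -> memory -> motor.

    One wall sensor, one memory unit, two motors; the sensor state is
    copied into memory and the memory state into the first motor. The
    unit graph is acyclic, so the brain integrates no information.
    """
    arch = ArchitectureSpec((("wall", "front"),), n_memory=1, name="chain")
    s = arch.sensor_units[0]
    m = arch.memory_units[0]
    gates = (
        GateBlueprint((s,), (m,), (0, 1)),
        GateBlueprint((m,), (arch.motor_units[0],), (0, 1)),
    )
    return MarkovBrain(arch, gates)


def scripted_log(
    T: int = 500,
    group_size: int = 1,
    *,
    crossings: Mapping[tuple[int, int], int] | None = None,
    collisions: Iterable[tuple[int, int]] = (),
    actions: np.ndarray | None = None,
    sensors: np.ndarray | None = None,
    world_name: str = "original",
    n_sensors: int = 2,
) -> TrialLog:
    """A synthetic trial log with prescribed events.

    ``crossings`` maps (time t in 1..T, animat) to 1 (non-rewarding gate)
    or 2 (rewarding gate); ``collisions`` lists (time t in 0..T, animat)
    co-occupancy flags. Optional (T, N) ``actions`` and ``sensors``
    arrays drive the behavior-statistics operations.
    """
    n = group_size
    cross = np.zeros((T, n), dtype=np.int8)
    for (t, a), kind in (crossings or {}).items():
        if not 1 <= t <= T:
            raise ValueError(f"crossing time {t} outside 1..{T}")
        cross[t - 1, a] = kind
    coll = np.zeros((T + 1, n), dtype=bool)
    for t, a in collisions:
        coll[t, a] = True
    act = (
        np.zeros((T, n), dtype=np.int8)
        if actions is None
        else np.asarray(actions, dtype=np.int8)
    )
    sens = (
        np.zeros((T, n), dtype=np.uint8)
        if sensors is None
        else np.asarray(sensors, dtype=np.uint8)
    )
    return TrialLog(
        world_name=world_name,
        T=T,
        x=np.zeros((T + 1, n), dtype=np.int16),
        y=np.zeros((T + 1, n), dtype=np.int16),
        orientation=np.zeros((T + 1, n), dtype=np.int8),
        states=np.zeros((T + 1, n), dtype=np.uint32),
        sensors=sens,
        actions=act,
        crossings=cross,
        collisions=coll,
        n_sensors=n_sensors,
    )


def gate_oscillator_log(
    T: int = 500, first: int = 1, spacing: int = 101
) -> TrialLog:
    """Adversarial single-animat log crossing the rewarding gate as often
    as the refractory window permits (first crossing at ``first``, then
    every ``spacing`` timesteps), with no collisions."""
    times = range(first, T + 1, spacing)
    return scripted_log(T=T, crossings={(t, 0): 2 for t in times})
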