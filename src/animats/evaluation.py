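"""Post-evolutionary testing: task-fitness sweeps, reliability, behavior.

Evolved brains are re-tested under eight conditions: the original world
under four interaction-rule variants (Original, No Penalty, Blocked,
Blocked and no Penalty) and four modified wall arrangements under the
original rules (Noisy Corners, Small Gates, 4 Rooms, 4 Messy Rooms), each
across the 21 test group sizes. Task fitness TF for one (condition,
group size) cell is the genome fitness measured there, averaged across
evolution replicates. Reliability R is the unweighted mean of the 21
Original-condition TF values across group sizes — robustness to changes
in group size alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .brain import MarkovBrain
from .engine import (
    GROUP_SIZES,
    EvalSetup,
    InteractionRules,
    TrialLog,
    score_genome,
)
from .world import GridWorld, builtin_world

__all__ = [
    "TEST_CONDITIONS",
    "SweepSpec",
    "TaskFitnessTable",
    "task_fitness_sweep",
    "reliability",
    "behavior_profile",
    "transition_table",
    "table_diff",
    "occupancy_heatmap",
]

#: the eight test conditions: name -> (world name, interaction rules)
TEST_CONDITIONS: dict[str, tuple[str, InteractionRules]] = {
    "Original": ("original", InteractionRules()),
    "No Penalty": ("original", InteractionRules(penalty_active=False)),
    "Blocked": ("original", InteractionRules(blocking=True)),
    "Blocked and no Penalty": (
        "original",
        InteractionRules(penalty_active=False, blocking=True),
    ),
    "Noisy Corners": ("noisy_corners", InteractionRules()),
    "Small Gates": ("small_gate", InteractionRules()),
    "4 Rooms": ("four_rooms", InteractionRules()),
    "4 Messy Rooms": ("four_messy_rooms", InteractionRules()),
}


@dataclass(frozen=True)
class SweepSpec:
    """What to test: conditions x group sizes, trials per cell."""

    conditions: tuple[str, ...] = tuple(TEST_CONDITIONS)
    group_sizes: tuple[int, ...] = GROUP_SIZES
    trials_per_cell: int = 30
    T: int = 500
    reward_cap: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.conditions) - set(TEST_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown test conditions: {sorted(unknown)}")


@dataclass(frozen=True)
class TaskFitnessTable:
    """Long-format TF table with full seed/trial provenance per cell."""

    table: pd.DataFrame  # columns: condition, group_size, tf, n_trials, seed

    def tf(self, condition: str, group_size: int) -> float:
        rows = self.table[
            (self.table.condition == condition)
            & (self.table.group_size == group_size)
        ]
        if rows.empty:
            raise KeyError((condition, group_size))
        return float(rows.tf.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def task_fitness_sweep(
    brains: Sequence[MarkovBrain],
    spec: SweepSpec = SweepSpec(),
    *,
    master_seed: int = 0,
) -> TaskFitnessTable:
    """Average task fitness of evolved brains over the requested cells.

    ``brains`` are the final-generation champions of one evolutionary
    setup (one per evolution replicate); each cell averages their
    individually measured fitness values. Seeds are derived per
    (condition, group size, replicate), so repeated sweeps with the same
    ``master_seed`` are identical.
    """
    if not brains:
        raise ValueError("need at least one brain")
    records = []
    for ci, cond in enumerate(spec.conditions):
        world_name, rules = TEST_CONDITIONS[cond]
        world = builtin_world(world_name)
        for gi, gs in enumerate(spec.group_sizes):
            values = []
            for bi, brain in enumerate(brains):
                ss = np.random.SeedSequence(
                    master_seed, spawn_key=(ci, gi, bi)
                )
                rng = np.random.Generator(np.random.MT19937(ss))
                setup = EvalSetup(
                    arch=brain.arch,
                    rules=rules,
                    trials=spec.trials_per_cell,
                    group_size=int(gs),
                    T=spec.T,
                    reward_cap=spec.reward_cap,
                )
                values.append(score_genome(world, brain, setup, rng))
            records.append(
                {
                    "condition": cond,
                    "group_size": int(gs),
                    "tf": float(np.mean(values)),
                    "n_replicates": len(brains),
                    "n_trials": spec.trials_per_cell,
                    "seed": master_seed,
                }
            )
    return TaskFitnessTable(pd.DataFrame.from_records(records))


def reliability(
    table: TaskFitnessTable,
    group_sizes: Sequence[int] = GROUP_SIZES,
    condition: str = "Original",
) -> float:
    """Unweighted mean TF across the test group sizes in one condition."""
    values = []
    for gs in group_sizes:
        try:
            values.append(table.tf(condition, int(gs)))
        except KeyError:
            raise ValueError(
                f"table is missing group size {gs} in condition {condition!r}"
            ) from None
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# behavior statistics


def _pooled_logs(logs: Iterable[TrialLog]) -> list[TrialLog]:
    logs = list(logs)
    if not logs:
        raise ValueError("no trial logs given")
    return logs


def behavior_profile(logs: Iterable[TrialLog]) -> dict[str, float]:
    """Fractions of animat-timesteps spent idle, turning, moving forward.

    Pools all animat-timesteps of all logs; realized actions are used, so
    a blocked forward attempt counts as no movement. The three fractions
    sum to 1.
    """
    logs = _pooled_logs(logs)
    counts = np.zeros(3, dtype=np.int64)
    for log in logs:
        counts += np.bincount(log.actions.ravel(), minlength=3)
    frac = counts / counts.sum()
    return {"none": float(frac[0]), "turn": float(frac[1]), "forward": float(frac[2])}


def _sm_codes(log: TrialLog) -> np.ndarray:
    """(T, N) composite codes 2*S + M: S = any sensor fired, M = moved/turned."""
    s = (log.sensors > 0).astype(np.int64)
    m = (log.actions > 0).astype(np.int64)
    return 2 * s + m


def transition_table(logs: Iterable[TrialLog]) -> pd.DataFrame:
    """4x4 matrix P(SM at t+1 | SM at t) pooled over animats and logs.

    S codes whether anything (wall or fellow animat) was sensed, M whether
    the animat moved or turned. Rows/columns are labeled 00, 01, 10, 11
    (S then M). Rows with zero support are reported as NaN rather than
    normalized, so downstream differences are not biased by empty cells.
    """
    logs = _pooled_logs(logs)
    counts = np.zeros((4, 4), dtype=np.int64)
    for log in logs:
        codes = _sm_codes(log)
        src = codes[:-1].ravel()
        dst = codes[1:].ravel()
        np.add.at(counts, (src, dst), 1)
    with np.errstate(invalid="ignore"):
        probs = counts / counts.sum(axis=1, keepdims=True)
    labels = ["00", "01", "10", "11"]
    return pd.DataFrame(probs, index=labels, columns=labels)


def table_diff(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Elementwise transition-probability difference P(A) - P(B).

    Negative entries mark transitions more frequent in B.
    """
    return a - b


def occupancy_heatmap(
    logs: Iterable[TrialLog], world: GridWorld
) -> np.ndarray:
    """Mean per-cell occupation count, averaged over timesteps and logs.

    Each log contributes the average over its T+1 logged configurations;
    logs (replicates) are then averaged cellwise. Per timestep the cell
    counts sum to the group size, so the heatmap sums to the mean group
    size across logs.
    """
    logs = _pooled_logs(logs)
    acc = np.zeros((world.height, world.width), dtype=np.float64)
    for log in logs:
        counts = np.zeros_like(acc)
        np.add.at(counts, (log.y.ravel(), log.x.ravel()), 1.0)
        acc += counts / log.x.shape[0]
    return acc / len(logs)
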