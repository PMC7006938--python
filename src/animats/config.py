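"""Named evolutionary setups, experiment configuration, run manifests.

The fifteen evolutionary setups vary one dimension each against the
baseline (group of 36 on the original map, baseline architecture, penalty
active, blocking off):

=====================  ====================================================
label                  deviation from baseline
=====================  ====================================================
1.00 / 0.75 / 0.50 /   fixed group sizes 72 / 54 / 36 / 18 / 1 (fractions
0.25 / single          of the 72 start slots)
random                 group size redrawn per trial from the 21-size vector
bigbrain / smallbrain  8 / 2 memory units instead of 4
no-feedback            motors cannot feed back into the network
no-penalty             no collision penalty
blocked                animats cannot share a cell
blocked/no-penalty     blocking on, penalty off
no-agent               only the front wall sensor
3sides                 wall + agent sensors on front, left and right
w=a                    one universal sensor (wall and animat alike)
=====================  ====================================================
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import yaml

from .brain import ARCH_PRESETS, ArchitectureSpec
from .engine import GROUP_SIZES, InteractionRules
from .evolution import EvolutionConfig
from .genome import MutationParams
from .world import GridWorld, builtin_world

__all__ = ["SETUP_LABELS", "table1_setup", "RunManifest", "build_evolution_config"]

_GROUP_SIZE_BY_LABEL: dict[str, int | str] = {
    "1.00": 72,
    "0.75": 54,
    "0.50": 36,
    "0.25": 18,
    "single": 1,
    "random": "random",
}

SETUP_LABELS = (
    "1.00", "0.75", "0.50", "0.25", "single", "random",
    "bigbrain", "smallbrain", "no-feedback",
    "no-penalty", "blocked/no-penalty", "blocked",
    "no-agent", "3sides", "w=a",
)


def table1_setup(
    label: str,
) -> tuple[GridWorld, ArchitectureSpec, InteractionRules, int | str]:
    """Resolve a setup label to (world, architecture, rules, group size)."""
    if label not in SETUP_LABELS:
        raise ValueError(
            f"unknown setup {label!r}; valid labels: {', '.join(SETUP_LABELS)}"
        )
    world = builtin_world("original")
    arch = ARCH_PRESETS["baseline"]
    rules = InteractionRules()
    group_size: int | str = 36
    if label in _GROUP_SIZE_BY_LABEL:
        group_size = _GROUP_SIZE_BY_LABEL[label]
    elif label in ("bigbrain", "smallbrain", "no-feedback", "no-agent", "3sides", "w=a"):
        arch = ARCH_PRESETS[label]
    elif label == "no-penalty":
        rules = InteractionRules(penalty_active=False)
    elif label == "blocked":
        rules = InteractionRules(blocking=True)
    elif label == "blocked/no-penalty":
        rules = InteractionRules(penalty_active=False, blocking=True)
    return world, arch, rules, group_size


def build_evolution_config(
    setup: str,
    *,
    master_seed: int = 0,
    population_size: int = 100,
    generations: int = 10_000,
    trials_per_genome: int = 30,
    T: int = 500,
    reward_cap: int = 4,
    mutation: MutationParams | None = None,
    **overrides,
) -> EvolutionConfig:
    """An :class:`EvolutionConfig` for one of the named setups."""
    world, arch, rules, group_size = table1_setup(setup)
    return EvolutionConfig(
        world=world,
        arch=arch,
        rules=rules,
        group_size=group_size,
        population_size=population_size,
        generations=generations,
        trials_per_genome=trials_per_genome,
        T=T,
        reward_cap=reward_cap,
        mutation=mutation or MutationParams(),
        master_seed=master_seed,
        label=setup,
        **overrides,
    )


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-identically."""

    setup: str
    master_seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    package_version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            try:
                self.package_version = _pkg_version("animats")
            except Exception:
                self.package_version = "unknown"
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


_CONFIG_KEYS = {
    "setup", "master_seed", "population_size", "generations",
    "trials_per_genome", "T", "reward_cap",
    "point_rate", "insert_prob", "delete_prob", "segment_len_min",
    "segment_len_max", "initial_genome_length", "seed_gates",
    "n_seeded_gates", "selection", "epsilon", "elitism",
    "sweep_trials", "sweep_conditions", "compute_phi", "out_dir",
}


def read_experiment_config(path) -> dict:
    """Flat key/value experiment file (YAML); unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return raw
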