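"""Markov brains: binary units wired by deterministic lookup-table gates.

A brain's units are ordered sensors first, then memory units, then the two
motor units; this ordering fixes the bit positions used everywhere (bit 0 =
unit 0 = first sensor). Each timestep the environment writes the sensor
bits, every gate reads its input units' current states and looks up the
next states of its output units, and all writes to one unit are combined by
bitwise OR (a unit nobody writes falls back to 0). Sensors are never gate
outputs. When motor feedback is disabled, motor units are removed from the
legal gate-input set, shrinking the effective memory capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .genome import GateBlueprint, Genome, decode

__all__ = [
    "SensorKind",
    "SensorSide",
    "ArchitectureSpec",
    "ARCH_PRESETS",
    "MarkovBrain",
    "step",
    "derive_tpm",
    "connectivity",
]

# sensor descriptor vocabularies
WALL, AGENT, UNIVERSAL = "wall", "agent", "universal"
FRONT, LEFT, RIGHT = "front", "left", "right"
SensorKind = str
SensorSide = str

_KINDS = (WALL, AGENT, UNIVERSAL)
_SIDES = (FRONT, LEFT, RIGHT)

MAX_TPM_UNITS = 16  # resource guard for exhaustive state enumeration


@dataclass(frozen=True)
class ArchitectureSpec:
    """Unit layout of an animat brain.

    ``sensor_slots`` lists (kind, side) pairs; kind is ``wall``, ``agent``
    or ``universal`` (fires on either), side is relative to the animat's
    heading. ``n_motors`` is always 2 in this task. ``motor_feedback``
    controls whether motor units may serve as gate inputs.
    """

    sensor_slots: tuple[tuple[SensorKind, SensorSide], ...]
    n_memory: int = 4
    n_motors: int = 2
    motor_feedback: bool = True
    name: str = "custom"

    def __post_init__(self) -> None:
        for kind, side in self.sensor_slots:
            if kind not in _KINDS or side not in _SIDES:
                raise ValueError(f"invalid sensor slot ({kind}, {side})")
        if self.n_memory < 0 or self.n_motors != 2:
            raise ValueError("need n_memory >= 0 and exactly 2 motors")

    # -- unit index map: sensors, then memory, then motors ------------------
    @property
    def n_sensors(self) -> int:
        return len(self.sensor_slots)

    @property
    def n_units(self) -> int:
        return self.n_sensors + self.n_memory + self.n_motors

    @property
    def sensor_units(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors))

    @property
    def memory_units(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors, self.n_sensors + self.n_memory))

    @property
    def motor_units(self) -> tuple[int, ...]:
        return tuple(range(self.n_sensors + self.n_memory, self.n_units))

    @property
    def non_sensor_units(self) -> tuple[int, ...]:
        return self.memory_units + self.motor_units

    @property
    def legal_input_units(self) -> tuple[int, ...]:
        units = self.sensor_units + self.memory_units
        if self.motor_feedback:
            units = units + self.motor_units
        return units

    @property
    def legal_output_units(self) -> tuple[int, ...]:
        return self.non_sensor_units


def _baseline_sensors() -> tuple[tuple[str, str], ...]:
    return ((WALL, FRONT), (AGENT, FRONT))


ARCH_PRESETS: dict[str, ArchitectureSpec] = {
    "baseline": ArchitectureSpec(_baseline_sensors(), n_memory=4, name="baseline"),
    "3sides": ArchitectureSpec(
        (
            (WALL, FRONT), (WALL, LEFT), (WALL, RIGHT),
            (AGENT, FRONT), (AGENT, LEFT), (AGENT, RIGHT),
        ),
        n_memory=4,
        name="3sides",
    ),
    "no-agent": ArchitectureSpec(((WALL, FRONT),), n_memory=4, name="no-agent"),
    "w=a": ArchitectureSpec(((UNIVERSAL, FRONT),), n_memory=4, name="w=a"),
    "smallbrain": ArchitectureSpec(_baseline_sensors(), n_memory=2, name="smallbrain"),
    "bigbrain": ArchitectureSpec(_baseline_sensors(), n_memory=8, name="bigbrain"),
    "no-feedback": ArchitectureSpec(
        _baseline_sensors(), n_memory=4, motor_feedback=False, name="no-feedback"
    ),
}


@dataclass(frozen=True)
class MarkovBrain:
    """An architecture plus a validated list of gates."""

    arch: ArchitectureSpec
    gates: tuple[GateBlueprint, ...]

    def __post_init__(self) -> None:
        legal_in = set(self.arch.legal_input_units)
        legal_out = set(self.arch.legal_output_units)
        for g in self.gates:
            if not set(g.input_unit_ids) <= legal_in:
                raise ValueError(f"gate inputs {g.input_unit_ids} illegal under arch")
            if not set(g.output_unit_ids) <= legal_out:
                raise ValueError(f"gate outputs {g.output_unit_ids} illegal under arch")

    @classmethod
    def from_genome(cls, genome: Genome, arch: ArchitectureSpec) -> "MarkovBrain":
        return cls(arch, tuple(decode(genome, arch)))

    @property
    def n_units(self) -> int:
        return self.arch.n_units

    # -- fast full transition table ----------------------------------------
    def lookup_table(self) -> np.ndarray:
        """Next non-sensor bits for every full brain state.

        Returns an array of length ``2**n_units``; entry ``x`` packs the
        next states of the non-sensor units (memory first, motors last,
        lowest unit in the least significant bit) given full current state
        ``x`` (unit ``u`` in bit ``u``). Sensors are environment-driven and
        carry no rows of their own.
        """
        k = self.n_units
        if k > MAX_TPM_UNITS:
            raise ValueError(f"{k} units exceed the {MAX_TPM_UNITS}-unit guard")
        states = np.arange(2**k, dtype=np.uint32)
        nxt = np.zeros(2**k, dtype=np.uint32)
        n_sensors = self.arch.n_sensors
        for g in self.gates:
            idx = np.zeros(2**k, dtype=np.uint32)
            for j, unit in enumerate(g.input_unit_ids):
                idx |= ((states >> unit) & 1) << j
            rows = np.asarray(g.table, dtype=np.uint32)[idx]
            for m, unit in enumerate(g.output_unit_ids):
                nxt |= ((rows >> m) & 1) << (unit - n_sensors)
        return nxt.astype(np.uint16)

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        """Human-readable gate list; round-trips through :func:`brain_from_text`."""
        lines = [f"arch {self.arch.name}"]
        if self.arch.name not in ARCH_PRESETS:
            slots = ";".join(f"{k},{s}" for k, s in self.arch.sensor_slots)
            lines.append(
                f"custom sensors={slots} memory={self.arch.n_memory} "
                f"feedback={int(self.arch.motor_feedback)}"
            )
        for g in self.gates:
            ins = ",".join(map(str, g.input_unit_ids))
            outs = ",".join(map(str, g.output_unit_ids))
            tab = ",".join(map(str, g.table))
            lines.append(f"gate in={ins} out={outs} table={tab}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def brain_from_text(text: str) -> MarkovBrain:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("arch "):
        raise ValueError("brain file must start with an 'arch <name>' line")
    name = lines[0][5:].strip()
    body = lines[1:]
    if name in ARCH_PRESETS:
        arch = ARCH_PRESETS[name]
    else:
        if not body or not body[0].startswith("custom "):
            raise ValueError(f"unknown arch preset {name!r} without custom line")
        fields = dict(tok.split("=", 1) for tok in body[0][7:].split())
        slots = tuple(
            tuple(pair.split(","))
            for pair in fields["sensors"].split(";")
            if pair
        )
        arch = ArchitectureSpec(
            slots,  # type: ignore[arg-type]
            n_memory=int(fields["memory"]),
            motor_feedback=bool(int(fields["feedback"])),
            name=name,
        )
        body = body[1:]
    gates = []
    for ln in body:
        if not ln.startswith("gate "):
            raise ValueError(f"unrecognized line in brain file: {ln!r}")
        fields = dict(tok.split("=", 1) for tok in ln[5:].split())
        gates.append(
            GateBlueprint(
                tuple(int(x) for x in fields["in"].split(",")),
                tuple(int(x) for x in fields["out"].split(",")),
                tuple(int(x) for x in fields["table"].split(",")),
            )
        )
    return MarkovBrain(arch, tuple(gates))


def load_brain(path) -> MarkovBrain:
    with open(path) as fh:
        return brain_from_text(fh.read())


# ---------------------------------------------------------------------------
# state update


def step(
    brain: MarkovBrain,
    state: Sequence[int] | np.ndarray,
    sensor_values: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """One deterministic brain update.

    The returned state carries ``sensor_values`` in the sensor positions
    (the environment owns them); every non-sensor unit takes the OR of all
    gate outputs targeting it, or 0 if no gate writes it.
    """
    arch = brain.arch
    state = np.asarray(state, dtype=np.uint8)
    sensor_values = np.asarray(sensor_values, dtype=np.uint8)
    if state.size != arch.n_units:
        raise ValueError(f"state length {state.size} != {arch.n_units} units")
    if sensor_values.size != arch.n_sensors:
        raise ValueError(
            f"sensor vector length {sensor_values.size} != {arch.n_sensors}"
        )
    cur = state.copy()
    cur[: arch.n_sensors] = sensor_values
    nxt = np.zeros(arch.n_units, dtype=np.uint8)
    nxt[: arch.n_sensors] = sensor_values
    for g in brain.gates:
        idx = 0
        for j, unit in enumerate(g.input_unit_ids):
            idx |= int(cur[unit]) << j
        row = g.table[idx]
        for m, unit in enumerate(g.output_unit_ids):
            nxt[unit] |= (row >> m) & 1
    return nxt


def derive_tpm(
    brain: MarkovBrain,
    subset: Sequence[int],
    clamp: dict[int, int] | None = None,
) -> np.ndarray:
    """Deterministic transition table of a unit subset, rest held fixed.

    Row ``x`` (bits of ``x`` assigned to ``subset`` in ascending-unit
    order, lowest unit in bit 0) is the next state of the subset obtained
    by a full brain update with excluded units clamped to ``clamp``
    (default 0). Probabilities are interventional: rows come from forced
    perturbations into each state, not from observed trajectories.
    """
    subset = sorted(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    k = len(subset)
    if k > MAX_TPM_UNITS:
        raise ValueError(f"subset of {k} units exceeds the {MAX_TPM_UNITS}-unit guard")
    clamp = dict(clamp or {})
    arch = brain.arch
    base = np.zeros(arch.n_units, dtype=np.uint8)
    for unit, val in clamp.items():
        base[unit] = val
    tpm = np.zeros(2**k, dtype=np.uint32)
    for x in range(2**k):
        cur = base.copy()
        for j, unit in enumerate(subset):
            cur[unit] = (x >> j) & 1
        nxt = step(brain, cur, cur[: arch.n_sensors])
        packed = 0
        for j, unit in enumerate(subset):
            packed |= int(nxt[unit]) << j
        tpm[x] = packed
    return tpm


def connectivity(brain: MarkovBrain) -> nx.DiGraph:
    """Directed unit graph: edge u->v iff some gate reads u and writes v."""
    g = nx.DiGraph()
    g.add_nodes_from(range(brain.n_units))
    for gate in brain.gates:
        for u in gate.input_unit_ids:
            for v in gate.output_unit_ids:
                g.add_edge(u, v)
    return g


def is_feed_forward(brain: MarkovBrain) -> bool:
    """True iff the unit graph has no directed cycle (condensation is the graph)."""
    return nx.is_directed_acyclic_graph(connectivity(brain))


def export_wiring(brain: MarkovBrain, path) -> None:
    """Dump the wiring diagram in GML for external inspection."""
    g = connectivity(brain)
    arch = brain.arch
    for u in g.nodes:
        if u in arch.sensor_units:
            role = "sensor"
        elif u in arch.memory_units:
            role = "memory"
        else:
            role = "motor"
        g.nodes[u]["role"] = role
    nx.write_gml(g, path)
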