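"""Grid environments: rooms, gates, start slots, ASCII map I/O.

Maps are plain ASCII, one character per cell::

    '#'  wall
    '.'  empty cell
    'S'  start slot (an empty cell animats may be placed on)
    'G'  rewarding gate cell
    'g'  non-rewarding gate cell

Coordinates are 0-based with ``x`` the column and ``y`` the row, origin at
the top-left; ``up`` means decreasing ``y``. Rooms are computed by flood
fill over non-wall cells with gate cells acting as separators; a gate cell
belongs to neither room and must adjoin exactly two distinct rooms.

Five environments are bundled: the ``original`` two-room world the animats
evolve in, plus four modified test worlds (``noisy_corners``,
``small_gate``, ``four_rooms``, ``four_messy_rooms``). The published
figures show the modified geometries only pictorially, so the bundled maps
are reconstructions that preserve the stated structural facts (room
counts, gate counts and reward assignment, 72 start slots); users can
substitute their own maps in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _maps

__all__ = ["GridWorld", "WORLD_NAMES", "load_world", "builtin_world", "world_to_text"]

WALL_ROOM = -1
GATE_ROOM = -2

WORLD_NAMES = (
    "original",
    "noisy_corners",
    "small_gate",
    "four_rooms",
    "four_messy_rooms",
)


class MapParseError(ValueError):
    """Raised for malformed ASCII maps; carries 1-based line/column info."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


@dataclass(frozen=True)
class GridWorld:
    """A parsed, validated grid environment."""

    name: str
    wall: np.ndarray          # (H, W) bool
    room: np.ndarray          # (H, W) int: room id >= 0, WALL_ROOM, or GATE_ROOM
    gate_rewarding: np.ndarray  # (H, W) bool, True only on rewarding gate cells
    start_slots: tuple[tuple[int, int], ...]  # (x, y) pairs

    def __post_init__(self) -> None:
        for arr in (self.wall, self.room, self.gate_rewarding):
            arr.setflags(write=False)

    @property
    def height(self) -> int:
        return int(self.wall.shape[0])

    @property
    def width(self) -> int:
        return int(self.wall.shape[1])

    @property
    def n_rooms(self) -> int:
        return int(self.room.max()) + 1

    @property
    def gate_cells(self) -> tuple[tuple[int, int], ...]:
        ys, xs = np.nonzero(self.room == GATE_ROOM)
        return tuple(zip(xs.tolist(), ys.tolist()))

    @property
    def rewarding_gate_cells(self) -> tuple[tuple[int, int], ...]:
        ys, xs = np.nonzero(self.gate_rewarding)
        return tuple(zip(xs.tolist(), ys.tolist()))

    def is_wall(self, x: int, y: int) -> bool:
        """Out-of-bounds cells count as wall (the boundary is solid)."""
        if not (0 <= x < self.width and 0 <= y < self.height):
            return True
        return bool(self.wall[y, x])


def load_world(map_text: str, name: str = "custom") -> GridWorld:
    """Parse an ASCII map into a validated :class:`GridWorld`."""
    rows = [ln for ln in map_text.splitlines() if ln.strip()]
    if not rows:
        raise MapParseError("empty map")
    width = len(rows[0])
    for j, row in enumerate(rows):
        if len(row) != width:
            raise MapParseError(
                f"non-rectangular map: row has {len(row)} cells, expected {width}",
                line=j + 1,
            )
    height = len(rows)
    wall = np.zeros((height, width), dtype=bool)
    gate = np.zeros((height, width), dtype=bool)
    rewarding = np.zeros((height, width), dtype=bool)
    slots: list[tuple[int, int]] = []
    for y, row in enumerate(rows):
        for x, ch in enumerate(row):
            if ch == "#":
                wall[y, x] = True
            elif ch == ".":
                pass
            elif ch == "S":
                slots.append((x, y))
            elif ch == "G":
                gate[y, x] = rewarding[y, x] = True
            elif ch == "g":
                gate[y, x] = True
            else:
                raise MapParseError(
                    f"unknown map character {ch!r}", line=y + 1, col=x + 1
                )
    # solid outer boundary
    border = np.concatenate([wall[0], wall[-1], wall[:, 0], wall[:, -1]])
    if not border.all():
        raise MapParseError("outer boundary must be all wall")

    room = np.full((height, width), WALL_ROOM, dtype=np.int32)
    room[gate] = GATE_ROOM
    open_cells = ~wall & ~gate
    next_room = 0
    for y, x in zip(*np.nonzero(open_cells)):
        if room[y, x] != WALL_ROOM:
            continue
        # iterative flood fill, 4-connectivity
        stack = [(y, x)]
        room[y, x] = next_room
        while stack:
            cy, cx = stack.pop()
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx_ = cy + dy, cx + dx
                if open_cells[ny, nx_] and room[ny, nx_] == WALL_ROOM:
                    room[ny, nx_] = next_room
                    stack.append((ny, nx_))
        next_room += 1

    for y, x in zip(*np.nonzero(gate)):
        neighbors = set()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r = room[y + dy, x + dx]
            if r >= 0:
                neighbors.add(int(r))
        if len(neighbors) != 2:
            raise MapParseError(
                f"gate cell does not separate two distinct rooms "
                f"(adjoins {len(neighbors)})",
                line=y + 1,
                col=x + 1,
            )
    return GridWorld(name, wall, room, rewarding, tuple(slots))


def builtin_world(name: str) -> GridWorld:
    """Return one of the five bundled environments."""
    if name not in WORLD_NAMES:
        raise ValueError(
            f"unknown world {name!r}; valid names: {', '.join(WORLD_NAMES)}"
        )
    return load_world(getattr(_maps, name.upper()), name=name)


def world_to_text(world: GridWorld) -> str:
    """Serialize back to the ASCII dialect accepted by :func:`load_world`."""
    slots = set(world.start_slots)
    lines = []
    for y in range(world.height):
        row = []
        for x in range(world.width):
            if world.wall[y, x]:
                row.append("#")
            elif world.room[y, x] == GATE_ROOM:
                row.append("G" if world.gate_rewarding[y, x] else "g")
            elif (x, y) in slots:
                row.append("S")
            else:
                row.append(".")
        lines.append("".join(row))
    return "\n".join(lines) + "\n"


def reachable_from(world: GridWorld, x: int, y: int) -> np.ndarray:
    """Boolean mask of cells reachable from (x, y); gates are passable."""
    passable = ~world.wall
    seen = np.zeros_like(passable)
    stack = [(y, x)]
    seen[y, x] = True
    while stack:
        cy, cx = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx_ = cy + dy, cx + dx
            if 0 <= ny < world.height and 0 <= nx_ < world.width:
                if passable[ny, nx_] and not seen[ny, nx_]:
                    seen[ny, nx_] = True
                    stack.append((ny, nx_))
    return seen
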