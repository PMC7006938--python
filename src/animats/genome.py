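"""Genomes and their decoding into hidden-Markov-gate blueprints.

An animat's brain is encoded in a flat string of integer loci in [0, 255]
(minimum length 2,000, maximum 20,000). Pairs of consecutive loci equal to
the start codon ``(42, 213)`` mark the beginning of a gate description:

====================  ========================================================
bytes                 meaning
====================  ========================================================
codon (2)             literal ``42, 213``
n_in (1)              number of gate inputs, mapped to 1-4 via ``b % 4 + 1``
n_out (1)             number of gate outputs, mapped the same way
input ids (4)         first ``n_in`` used, reduced modulo the number of units
                      that are legal gate inputs under the architecture
output ids (4)        first ``n_out`` used, reduced modulo the number of
                      legal output units (memory and motors)
table (2**n_in)       one byte per input combination, reduced modulo
                      ``2**n_out`` to the output bit pattern
====================  ========================================================

A header that starts near the genome's end wraps around and continues
reading from the beginning, so every codon yields a complete gate.
Evolution acts on genomes by point substitution plus at most one segment
duplication and one segment deletion per offspring; there is no crossover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .brain import ArchitectureSpec

__all__ = [
    "MIN_LENGTH",
    "MAX_LENGTH",
    "START_CODON",
    "Genome",
    "MutationParams",
    "GateBlueprint",
    "random_genome",
    "mutate",
    "decode",
    "read_genome",
    "write_genome",
]

MIN_LENGTH = 2_000
MAX_LENGTH = 20_000

#: consecutive locus pair that opens a gate description
START_CODON = (42, 213)

# per-gate header layout (see module docstring)
_N_ID_SLOTS = 4
_MAX_ARITY = 4


class GenomeBoundsError(ValueError):
    """Genome length outside the permitted [2000, 20000] range."""


@dataclass(frozen=True)
class Genome:
    """An evolvable string of integer loci in [0, 255]."""

    loci: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.loci)
        if arr.dtype != np.uint8:
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise ValueError("genome loci must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        if not MIN_LENGTH <= arr.size <= MAX_LENGTH:
            raise GenomeBoundsError(
                f"genome length {arr.size} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "loci", arr)

    def __len__(self) -> int:
        return int(self.loci.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.loci.shape == other.loci.shape and bool(
            np.all(self.loci == other.loci)
        )

    def __hash__(self) -> int:
        return hash(self.loci.tobytes())


@dataclass(frozen=True)
class MutationParams:
    """Rates governing the asexual variation operator.

    ``point_rate`` is the per-locus substitution probability; insertion and
    deletion happen at most once per offspring, each with its own
    probability, and duplicate/remove a contiguous segment whose length is
    drawn uniformly from ``segment_len_range`` (inclusive). The published
    setup delegates exact rates to an unavailable supplementary table; the
    defaults here are reconstructions in the range customary for
    Markov-brain evolution and are fully configurable.
    """

    point_rate: float = 0.005
    insert_prob: float = 0.05
    delete_prob: float = 0.02
    segment_len_range: tuple[int, int] = (128, 512)

    def __post_init__(self) -> None:
        for name in ("point_rate", "insert_prob", "delete_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo, hi = self.segment_len_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid segment_len_range {self.segment_len_range}")


@dataclass(frozen=True)
class GateBlueprint:
    """A decoded deterministic lookup-table gate.

    ``table[i]`` holds the output bit pattern (``n_out`` bits, output 0 in
    the least significant position) produced when the inputs spell the
    integer ``i`` (input 0 in the least significant position).
    """

    input_unit_ids: tuple[int, ...]
    output_unit_ids: tuple[int, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        n_in, n_out = len(self.input_unit_ids), len(self.output_unit_ids)
        if not 1 <= n_in <= _MAX_ARITY or not 1 <= n_out <= _MAX_ARITY:
            raise ValueError("gates take 1-4 inputs and 1-4 outputs")
        if len(self.table) != 2**n_in:
            raise ValueError(
                f"table must have {2**n_in} rows, got {len(self.table)}"
            )
        if any(not 0 <= row < 2**n_out for row in self.table):
            raise ValueError("table rows must fit in n_out bits")

    @property
    def n_in(self) -> int:
        return len(self.input_unit_ids)

    @property
    def n_out(self) -> int:
        return len(self.output_unit_ids)


def random_genome(
    length: int,
    rng: np.random.Generator,
    *,
    seed_gates: bool = True,
    n_seeded_gates: int = 8,
) -> Genome:
    """Draw a uniform random genome of the requested length.

    With ``seed_gates`` (the default) ``n_seeded_gates`` start codons are
    planted at evenly spaced positions so first-generation animats carry a
    handful of random gates. With ``seed_gates=False`` no codons are
    planted and accidental codon pairs are scrubbed, yielding gateless
    (unconnected) first-generation brains.
    """
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise GenomeBoundsError(
            f"length {length} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    loci = rng.integers(0, 256, size=length, dtype=np.uint8)
    if seed_gates:
        if n_seeded_gates > 0:
            spacing = length // n_seeded_gates
            offsets = rng.integers(0, max(spacing - 2, 1), size=n_seeded_gates)
            for k in range(n_seeded_gates):
                pos = (k * spacing + int(offsets[k])) % (length - 1)
                loci[pos] = START_CODON[0]
                loci[pos + 1] = START_CODON[1]
    else:
        _scrub_codons(loci)
    return Genome(loci)


def _scrub_codons(loci: np.ndarray) -> None:
    """Destroy every start-codon pair in place (wrap-around included)."""
    while True:
        hits = np.flatnonzero(
            (loci[:-1] == START_CODON[0]) & (loci[1:] == START_CODON[1])
        )
        wrap = loci[-1] == START_CODON[0] and loci[0] == START_CODON[1]
        if hits.size == 0 and not wrap:
            return
        loci[(hits + 1) % loci.size] = (START_CODON[1] + 1) % 256
        if wrap:
            loci[0] = (START_CODON[1] + 1) % 256


def mutate(
    parent: Genome, params: MutationParams, rng: np.random.Generator
) -> Genome:
    """Produce one offspring by point substitution, deletion, duplication.

    Order of application: point substitutions, then at most one segment
    deletion, then at most one segment duplication (an existing segment is
    copied and re-inserted at a random position, the customary
    gene-duplication move). A deletion that would undershoot the minimum
    length, or an insertion that would overshoot the maximum, is skipped.
    """
    child = np.array(parent.loci, dtype=np.uint8)  # writable copy
    if params.point_rate > 0:
        mask = rng.random(child.size) < params.point_rate
        n_hits = int(mask.sum())
        if n_hits:
            child[mask] = rng.integers(0, 256, size=n_hits, dtype=np.uint8)
    lo, hi = params.segment_len_range
    if params.delete_prob > 0 and rng.random() < params.delete_prob:
        seg = int(rng.integers(lo, hi + 1))
        if child.size - seg >= MIN_LENGTH:
            start = int(rng.integers(0, child.size - seg + 1))
            child = np.delete(child, slice(start, start + seg))
    if params.insert_prob > 0 and rng.random() < params.insert_prob:
        seg = int(rng.integers(lo, hi + 1))
        seg = min(seg, child.size)
        if child.size + seg <= MAX_LENGTH:
            src = int(rng.integers(0, child.size - seg + 1))
            dst = int(rng.integers(0, child.size + 1))
            child = np.insert(child, dst, child[src : src + seg])
    return Genome(child)


def _codon_positions(loci: np.ndarray) -> np.ndarray:
    hits = np.flatnonzero(
        (loci[:-1] == START_CODON[0]) & (loci[1:] == START_CODON[1])
    )
    if loci[-1] == START_CODON[0] and loci[0] == START_CODON[1]:
        hits = np.append(hits, loci.size - 1)
    return hits


def decode(genome: Genome, arch: "ArchitectureSpec") -> list[GateBlueprint]:
    """Decode every start-codon occurrence into a gate blueprint.

    Input ids are drawn from the units legal as gate inputs under ``arch``
    (sensors, memory, and motors when motor feedback is enabled); output
    ids from memory and motor units. Raw id bytes are reduced modulo the
    size of the respective legal-unit list. Reading wraps cyclically past
    the genome end. Decoding is pure: identical (genome, arch) pairs yield
    identical gate lists.
    """
    loci = genome.loci
    n = loci.size
    legal_in = np.asarray(arch.legal_input_units, dtype=np.int64)
    legal_out = np.asarray(arch.legal_output_units, dtype=np.int64)
    gates: list[GateBlueprint] = []
    for pos in _codon_positions(loci):
        cursor = int(pos) + 2
        header = loci.take(range(cursor, cursor + 2 + 2 * _N_ID_SLOTS), mode="wrap")
        n_in = int(header[0]) % _MAX_ARITY + 1
        n_out = int(header[1]) % _MAX_ARITY + 1
        in_ids = tuple(
            int(legal_in[int(b) % legal_in.size]) for b in header[2 : 2 + n_in]
        )
        out_ids = tuple(
            int(legal_out[int(b) % legal_out.size])
            for b in header[2 + _N_ID_SLOTS : 2 + _N_ID_SLOTS + n_out]
        )
        table_start = cursor + 2 + 2 * _N_ID_SLOTS
        raw = loci.take(range(table_start, table_start + 2**n_in), mode="wrap")
        table = tuple(int(b) % 2**n_out for b in raw)
        gates.append(GateBlueprint(in_ids, out_ids, table))
    return gates


# ---------------------------------------------------------------------------
# plain-text serialization


def write_genome(genome: Genome, path) -> None:
    """Write one locus per line."""
    np.savetxt(path, genome.loci, fmt="%d")


def read_genome(path) -> Genome:
    loci = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if loci.size and (loci.min() < 0 or loci.max() > 255):
        raise ValueError(f"{path}: loci outside [0, 255]")
    return Genome(loci.astype(np.uint8))
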