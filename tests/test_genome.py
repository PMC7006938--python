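"""Genome representation, mutation, and gate decoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from animats.brain import ARCH_PRESETS
from animats.genome import (
    MAX_LENGTH,
    MIN_LENGTH,
    START_CODON,
    Genome,
    GenomeBoundsError,
    MutationParams,
    decode,
    mutate,
    random_genome,
    read_genome,
    write_genome,
)
from conftest import mt


class TestRandomGenome:
    def test_requested_length_and_locus_range(self):
        g = random_genome(2000, mt(0))
        assert len(g) == 2000
        assert g.loci.min() >= 0 and g.loci.max() <= 255

    @pytest.mark.parametrize("length", [1999, 20001, 0])
    def test_out_of_bounds_length_rejected(self, length):
        with pytest.raises(GenomeBoundsError):
            random_genome(length, mt(0))

    def test_deterministic_under_fixed_seed(self):
        assert random_genome(3000, mt(7)) == random_genome(3000, mt(7))

    def test_unseeded_genome_has_no_start_codons(self):
        g = random_genome(5000, mt(3), seed_gates=False)
        loci = g.loci
        pairs = (loci[:-1] == START_CODON[0]) & (loci[1:] == START_CODON[1])
        assert not pairs.any()
        assert decode(g, ARCH_PRESETS["baseline"]) == []

    def test_seeded_genome_decodes_to_gates(self):
        g = random_genome(5000, mt(3), seed_gates=True, n_seeded_gates=8)
        assert len(decode(g, ARCH_PRESETS["baseline"])) >= 8


class TestMutate:
    def test_zero_rates_produce_identical_child(self):
        parent = random_genome(2500, mt(1))
        params = MutationParams(point_rate=0, insert_prob=0, delete_prob=0)
        assert mutate(parent, params, mt(2)) == parent

    def test_full_point_rate_resamples_every_locus(self):
        # expected fraction of loci equal to the parent is 1/256
        params = MutationParams(point_rate=1.0, insert_prob=0, delete_prob=0)
        rng = mt(11)
        same = total = 0
        for _ in range(10):
            parent = random_genome(20000, rng, seed_gates=False)
            child = mutate(parent, params, rng)
            same += int((child.loci == parent.loci).sum())
            total += len(parent)
        p = 1 / 256
        se = np.sqrt(p * (1 - p) / total)
        assert abs(same / total - p) < 3 * se

    def test_expected_substitution_count(self):
        rate = 0.01
        params = MutationParams(point_rate=rate, insert_prob=0, delete_prob=0)
        rng = mt(5)
        diffs = total = 0
        for _ in range(10):
            parent = random_genome(20000, rng, seed_gates=False)
            child = mutate(parent, params, rng)
            diffs += int((child.loci != parent.loci).sum())
            total += len(parent)
        # a hit changes the locus with probability 255/256
        p_change = rate * 255 / 256
        se = np.sqrt(p_change * (1 - p_change) / total)
        assert abs(diffs / total - p_change) < 3 * se

    def test_deletion_pressure_respects_minimum_length(self):
        params = MutationParams(point_rate=0, insert_prob=0, delete_prob=1)
        g = random_genome(MIN_LENGTH, mt(0))
        rng = mt(1)
        for _ in range(50):
            g = mutate(g, params, rng)
            assert len(g) >= MIN_LENGTH

    def test_insertion_pressure_respects_maximum_length(self):
        params = MutationParams(point_rate=0, insert_prob=1, delete_prob=0)
        g = random_genome(MAX_LENGTH - 100, mt(0))
        rng = mt(1)
        for _ in range(20):
            g = mutate(g, params, rng)
            assert len(g) <= MAX_LENGTH

    @given(
        point=st.floats(0, 1),
        ins=st.floats(0, 1),
        dele=st.floats(0, 1),
        lo=st.integers(1, 500),
        span=st.integers(0, 500),
        length=st.integers(MIN_LENGTH, 4000),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_child_always_valid(self, point, ins, dele, lo, span, length, seed):
        params = MutationParams(
            point_rate=point,
            insert_prob=ins,
            delete_prob=dele,
            segment_len_range=(lo, lo + span),
        )
        parent = random_genome(length, mt(seed))
        child = mutate(parent, params, mt(seed + 1))
        assert MIN_LENGTH <= len(child) <= MAX_LENGTH
        assert child.loci.min() >= 0 and child.loci.max() <= 255


def _hand_built_genome() -> Genome:
    """One codon, 1-in/1-out identity gate from unit byte 0 to output byte 0."""
    loci = np.zeros(2000, dtype=np.uint8)
    pos = 100
    payload = [
        START_CODON[0], START_CODON[1],
        0,  # n_in byte -> 1 input
        0,  # n_out byte -> 1 output
        0, 0, 0, 0,  # input id bytes (first used)
        0, 0, 0, 0,  # output id bytes (first used)
        0, 1,  # 2-row table: identity
    ]
    loci[pos : pos + len(payload)] = payload
    return Genome(loci)


class TestDecode:
    def test_no_codons_yield_no_gates(self):
        g = Genome(np.zeros(2000, dtype=np.uint8))
        assert decode(g, ARCH_PRESETS["baseline"]) == []

    def test_hand_built_single_gate(self):
        # hand-decoded oracle: baseline legal inputs are units 0..7 in
        # order, legal outputs are units 2..7; id byte 0 maps to the
        # first entry of each list
        gates = decode(_hand_built_genome(), ARCH_PRESETS["baseline"])
        assert len(gates) == 1
        (gate,) = gates
        assert gate.input_unit_ids == (0,)
        assert gate.output_unit_ids == (2,)
        assert gate.table == (0, 1)

    def test_decode_is_pure(self):
        g = random_genome(4000, mt(9))
        arch = ARCH_PRESETS["baseline"]
        assert decode(g, arch) == decode(g, arch)

    def test_no_feedback_arch_never_reads_motors(self):
        arch = ARCH_PRESETS["no-feedback"]
        motors = set(arch.motor_units)
        for seed in range(5):
            g = random_genome(6000, mt(seed))
            for gate in decode(g, arch):
                assert not motors & set(gate.input_unit_ids)

    def test_codon_at_genome_end_wraps_around(self):
        loci = np.zeros(2000, dtype=np.uint8)
        loci[-2] = START_CODON[0]
        loci[-1] = START_CODON[1]
        gates = decode(Genome(loci), ARCH_PRESETS["baseline"])
        assert len(gates) == 1  # header read continues at position 0

    def test_ids_reduced_modulo_legal_units(self):
        arch = ARCH_PRESETS["baseline"]  # 8 legal inputs, 6 legal outputs
        loci = np.zeros(2000, dtype=np.uint8)
        payload = [
            START_CODON[0], START_CODON[1], 0, 0,
            9, 0, 0, 0,   # input id 9 % 8 = 1 -> unit 1
            7, 0, 0, 0,   # output id 7 % 6 = 1 -> second legal output
            0, 1,
        ]
        loci[50 : 50 + len(payload)] = payload
        (gate,) = decode(Genome(loci), arch)
        assert gate.input_unit_ids == (arch.legal_input_units[1],)
        assert gate.output_unit_ids == (arch.legal_output_units[1],)


def test_genome_file_round_trip(tmp_path):
    g = random_genome(2345, mt(4))
    path = tmp_path / "genome.txt"
    write_genome(g, path)
    assert read_genome(path) == g


def test_genome_file_rejects_out_of_range(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("\n".join(["1"] * 1999 + ["300"]))
    with pytest.raises(ValueError):
        read_genome(path)
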