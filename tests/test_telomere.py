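"""Telomere motif counting, end calls, reference-read selection, patching."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from t2tkit.genome_io import GenomeAssembly, SequenceRecord, reverse_complement
from t2tkit.simulate import SimConfig, simulate_genome
from t2tkit.telomere import (
    FIVE_PRIME,
    THREE_PRIME,
    PatchDecision,
    TelomereMotif,
    align_consensus_to_terminus,
    apply_terminal_patch,
    call_chromosome_telomeres,
    collect_terminal_reads,
    count_motif_repeats,
    decide_terminal_patch,
    naive_consensus,
    select_reference_read,
    telomere_count,
)
from .conftest import random_dna

MOTIF = TelomereMotif()


def motif_free_dna(rng, n, motifs=("TTTAGGG", "CCCTAAA")):
    s = random_dna(rng, n)
    while any(m in s for m in motifs):
        for m in motifs:
            s = s.replace(m, random_dna(rng, 7))
    return s


class TestMotifCounting:
    def test_pure_tandem_array(self):
        assert count_motif_repeats("TTTAGGG" * 5, "TTTAGGG") == 5

    def test_no_occurrence(self):
        assert count_motif_repeats("ACGTACGT", "TTTAGGG") == 0

    def test_empty_motif_errors(self):
        with pytest.raises(ValueError):
            count_motif_repeats("ACGT", "")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_regex_oracle_on_planted_copies(self, seed):
        rng = np.random.default_rng(seed)
        seq = list(motif_free_dna(rng, 2_000))
        spots = sorted(rng.choice(range(0, 1_990, 10), size=12, replace=False))
        for s in spots:
            seq[s : s + 7] = "TTTAGGG"
        seq = "".join(seq)
        expected = len(re.findall("TTTAGGG", seq))
        assert count_motif_repeats(seq, "TTTAGGG") == expected >= 12

    @given(st.text(alphabet="ACGTN", max_size=300))
    def test_count_bounded_by_capacity(self, seq):
        assert count_motif_repeats(seq, "TTTAGGG") <= len(seq) // 7

    def test_motif_pair_must_be_reverse_complement(self):
        with pytest.raises(ValueError):
            TelomereMotif("TTTAGGG", "CCCATTT")
        assert reverse_complement("TTTAGGG") == "CCCTAAA"


class TestChromosomeCalls:
    def _chrom(self, rng, c5, c3, length=60_000):
        body = motif_free_dna(rng, length - 7 * (c5 + c3))
        return "CCCTAAA" * c5 + body + "TTTAGGG" * c3

    def test_five_prime_only(self):
        rng = np.random.default_rng(0)
        asm = GenomeAssembly([SequenceRecord("c", self._chrom(rng, 158, 0))])
        calls = call_chromosome_telomeres(asm)
        by_end = {c.end: c for c in calls}
        assert by_end[FIVE_PRIME].present
        assert by_end[FIVE_PRIME].repeat_count == 158
        assert not by_end[THREE_PRIME].present

    def test_both_ends(self):
        rng = np.random.default_rng(1)
        asm = GenomeAssembly([SequenceRecord("c", self._chrom(rng, 40, 60))])
        assert telomere_count(call_chromosome_telomeres(asm)) == 2

    def test_thirteen_of_sixteen_pattern(self):
        """An 8-chromosome genome missing Chr4-5', Chr5-5', Chr7-3' telomeres
        yields 13 present calls."""
        cfg = SimConfig(
            seed=3, n_chromosomes=8, chrom_length=500_000, array_length=50_000,
            dropped_ends=((3, "5prime"), (4, "5prime"), (6, "3prime")),
        )
        genome, truth = simulate_genome(cfg)
        calls = call_chromosome_telomeres(genome)
        assert telomere_count(calls) == 13
        planted = sum(1 for v in truth.telomeres.values() if v > 0)
        assert planted == 13

    def test_simulator_truth_across_seeds(self):
        for seed in range(6):
            cfg = SimConfig(seed=seed, n_chromosomes=4, chrom_length=400_000,
                            array_length=40_000,
                            dropped_ends=((seed % 4, "3prime"),))
            genome, truth = simulate_genome(cfg)
            calls = call_chromosome_telomeres(genome)
            assert telomere_count(calls) == sum(
                1 for v in truth.telomeres.values() if v > 0
            )

    def test_window_longer_than_chromosome_errors(self):
        asm = GenomeAssembly([SequenceRecord("c", "ACGT" * 100)])
        with pytest.raises(ValueError):
            call_chromosome_telomeres(asm, terminal_window=20_000)


class _ReadAln:
    def __init__(self, read_id, chrom, start, end, n_alignments=1):
        self.read_id, self.chrom = read_id, chrom
        self.start, self.end, self.n_alignments = start, end, n_alignments


class TestTerminalReadCollection:
    def _asm(self):
        rng = np.random.default_rng(2)
        return GenomeAssembly([SequenceRecord("Chr1", random_dna(rng, 100_000))])

    def test_within_window_collected(self):
        got = collect_terminal_reads([_ReadAln("r1", "Chr1", 0, 40_000)], self._asm())
        assert got[("Chr1", FIVE_PRIME)] == ["r1"]

    def test_outside_window_skipped(self):
        got = collect_terminal_reads([_ReadAln("r1", "Chr1", 51, 40_000)], self._asm())
        assert got[("Chr1", FIVE_PRIME)] == []

    def test_multi_mapping_read_skipped_when_unique_only(self):
        aln = _ReadAln("r1", "Chr1", 0, 40_000, n_alignments=2)
        got = collect_terminal_reads([aln], self._asm())
        assert got[("Chr1", FIVE_PRIME)] == []
        got = collect_terminal_reads([aln], self._asm(), unique_only=False)
        assert got[("Chr1", FIVE_PRIME)] == ["r1"]

    def test_three_prime_end(self):
        got = collect_terminal_reads([_ReadAln("r1", "Chr1", 60_000, 99_980)], self._asm())
        assert got[("Chr1", THREE_PRIME)] == ["r1"]


class TestReferenceReadSelection:
    def test_argmax(self):
        reads = [("r1", "TTTAGGG" * 5), ("r2", "TTTAGGG" * 9), ("r3", "TTTAGGG" * 2)]
        ref, queries = select_reference_read(reads)
        assert ref == "r2" and queries == ["r1", "r3"]

    def test_tie_breaks_to_longer_read(self):
        rng = np.random.default_rng(3)
        pad = motif_free_dna(rng, 200)
        reads = [("r1", "TTTAGGG" * 5), ("r2", "TTTAGGG" * 5 + pad)]
        assert select_reference_read(reads)[0] == "r2"

    def test_counts_both_orientations(self):
        reads = [("fwd", "TTTAGGG" * 3), ("rev", "CCCTAAA" * 5)]
        assert select_reference_read(reads)[0] == "rev"

    def test_planted_copy_numbers(self):
        rng = np.random.default_rng(4)
        copies = rng.integers(5, 60, size=20)
        reads = [
            (f"r{i}", "TTTAGGG" * int(c) + motif_free_dna(rng, 100))
            for i, c in enumerate(copies)
        ]
        brute_best = max(reads, key=lambda r: r[1].count("TTTAGGG"))[0]
        assert select_reference_read(reads)[0] == brute_best

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_reference_read([])


class TestPatchDecision:
    def _aln(self, identity, start, end):
        return {"identity": identity, "aligned_ref_interval": (start, end)}

    def test_low_identity_rejected(self):
        d = decide_terminal_patch(self._aln(0.79, 1_000, 3_000), 100_000, FIVE_PRIME)
        assert (d.accept, d.reason) == (False, "low_identity")

    def test_too_far_rejected(self):
        d = decide_terminal_patch(self._aln(0.95, 25_000, 27_000), 100_000, FIVE_PRIME)
        assert (d.accept, d.reason) == (False, "too_far")

    def test_accepted(self):
        d = decide_terminal_patch(self._aln(0.95, 5_000, 7_000), 100_000, FIVE_PRIME)
        assert (d.accept, d.reason) == (True, "ok")

    def test_no_alignment(self):
        d = decide_terminal_patch(None, 100_000, FIVE_PRIME)
        assert (d.accept, d.reason) == (False, "no_alignment")

    @given(
        st.floats(0, 1), st.floats(0, 1), st.integers(0, 50_000), st.integers(0, 50_000)
    )
    def test_monotone_in_identity_and_distance(self, id1, id2, d1, d2):
        """Raising identity or moving closer to the end never flips accept
        into reject."""
        lo_id, hi_id = sorted([id1, id2])
        near, far = sorted([d1, d2])
        def dec(identity, dist):
            return decide_terminal_patch(
                {"identity": identity, "aligned_ref_interval": (dist, dist + 100)},
                100_000, FIVE_PRIME,
            ).accept
        if dec(lo_id, far):
            assert dec(hi_id, far) and dec(lo_id, near) and dec(hi_id, near)


class TestPatchApplication:
    def test_five_prime_round_trip(self):
        rng = np.random.default_rng(5)
        truth = "CCCTAAA" * 100 + motif_free_dna(rng, 50_000)
        trunc = GenomeAssembly(
            [SequenceRecord("c", truth[3_000:]),
             SequenceRecord("other", random_dna(rng, 30_000))]
        )
        read = truth[:40_000]
        aln = align_consensus_to_terminus(read, trunc["c"].seq, FIVE_PRIME)
        dec = decide_terminal_patch(aln, trunc["c"].length, FIVE_PRIME)
        assert dec.accept
        patched = apply_terminal_patch(trunc, "c", FIVE_PRIME, read, aln, dec)
        assert patched["c"].seq == truth
        assert patched["other"].seq == trunc["other"].seq  # untouched

    def test_three_prime_prefix_untouched(self):
        rng = np.random.default_rng(6)
        truth = motif_free_dna(rng, 50_000) + "TTTAGGG" * 100
        trunc = GenomeAssembly([SequenceRecord("c", truth[:-2_000])])
        read = truth[-40_000:]
        aln = align_consensus_to_terminus(read, trunc["c"].seq, THREE_PRIME)
        dec = decide_terminal_patch(aln, trunc["c"].length, THREE_PRIME)
        patched = apply_terminal_patch(trunc, "c", THREE_PRIME, read, aln, dec)
        assert patched["c"].seq == truth
        assert patched["c"].seq[:10_000] == trunc["c"].seq[:10_000]

    def test_rejected_decision_raises(self):
        asm = GenomeAssembly([SequenceRecord("c", "ACGT" * 100)])
        dec = PatchDecision(False, 0.5, 100, "low_identity")
        with pytest.raises(ValueError):
            apply_terminal_patch(asm, "c", FIVE_PRIME, "ACGT", {}, dec)


class TestNaiveConsensus:
    def test_identity(self):
        ref = "ACGT" * 200
        assert naive_consensus([ref, ref, ref], ref) == ref

    def test_majority_substitution_adopted(self):
        rng = np.random.default_rng(7)
        ref = random_dna(rng, 500)
        alt = ("A" if ref[250] != "A" else "C")
        mutant = ref[:250] + alt + ref[251:]
        assert naive_consensus([mutant] * 4 + [ref], ref)[250] == alt

    def test_noisy_reads_recover_truth(self):
        rng = np.random.default_rng(8)
        truth = random_dna(rng, 4_000)
        def noisy(s, rate=0.02):
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            basis = np.frombuffer(b"ACGT", dtype=np.uint8)
            for i in np.flatnonzero(rng.random(len(arr)) < rate):
                arr[i] = rng.choice(basis[basis != arr[i]])
            return arr.tobytes().decode()
        cons = naive_consensus([noisy(truth) for _ in range(20)], noisy(truth))
        mismatches = sum(a != b for a, b in zip(cons, truth))
        assert mismatches / len(truth) <= 0.001

    def test_empty_ref_errors(self):
        with pytest.raises(ValueError):
            naive_consensus(["ACGT"], "")
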