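"""Linker matching, pair clipping, 454 splitting, adapter dropping.

The reference scorer used here is an independent, purely-Python exhaustive
scan over every ungapped offset and both strands; the library matcher must
agree with it exactly on small instances.
"""

import random

import pytest

from genomeprep.formats import Read, ReadPair, revcomp
from genomeprep.linker_clip import (
    AdapterFilterConfig,
    ClipCategory,
    LinkerConfig,
    clip_pair,
    drop_adapter_reads,
    find_linker,
    split_454,
)

LINKER = "TCGTCTTCAAGAATTCTCATGTTTGACAGCTTATCATC"  # 38 bp


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def oracle_best_match(read: str, linker: str, min_core: int, min_identity: float,
                      both_strands: bool = True):
    """Exhaustive reference: every offset, every strand, partial overhangs."""
    candidates = []
    strands = [("+", linker)] + ([("-", revcomp(linker))] if both_strands else [])
    R = len(read)
    for strand, lk in strands:
        L = len(lk)
        for off in range(-(L - min_core), R - min_core + 1):
            rs, re = max(0, off), min(R, off + L)
            aligned = re - rs
            if aligned < min_core:
                continue
            eq = [read[rs + i] == lk[rs - off + i] and read[rs + i] in "ACGT"
                  for i in range(aligned)]
            matches = sum(eq)
            run = best = 0
            for m in eq:
                run = run + 1 if m else 0
                best = max(best, run)
            if matches / aligned >= min_identity and best >= min_core:
                candidates.append((matches, rs, strand, re, aligned, best))
    if not candidates:
        return None
    # highest matches, then leftmost start, then '+'
    return min(candidates, key=lambda c: (-c[0], c[1], c[2]))


class TestFindLinker:
    def test_planted_exact_linker(self):
        rng = random.Random(7)
        read = random_dna(rng, 20) + LINKER + random_dna(rng, 20)
        m = find_linker(read, LinkerConfig(LINKER))
        assert m is not None
        assert m.read_start == 20
        assert m.read_end == 58
        assert m.longest_exact_run == 38
        assert m.matches == 38

    def test_core_rule_rejects_periodic_mismatches(self):
        """A linker copy with a mismatch every 9th base has no 9-bp exact run
        and must be rejected even though its identity (34/38) clears 0.875."""
        rng = random.Random(9)
        corrupted = list(LINKER)
        for pos in (8, 17, 26, 35):
            corrupted[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[pos]]
        corrupted = "".join(corrupted)
        read = random_dna(rng, 15) + corrupted + random_dna(rng, 15)
        assert find_linker(read, LinkerConfig(LINKER, min_core=9, min_identity=0.875)) is None
        # sanity: with a 1-bp core requirement the same placement qualifies
        relaxed = find_linker(read, LinkerConfig(LINKER, min_core=1, min_identity=0.875))
        assert relaxed is not None and relaxed.read_start == 15

    def test_linker_free_read(self):
        rng = random.Random(13)
        # oracle-screened clean read
        while True:
            read = random_dna(rng, 120)
            if oracle_best_match(read, LINKER, 9, 0.8) is None:
                break
        assert find_linker(read, LinkerConfig(LINKER)) is None

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            find_linker("", LinkerConfig(LINKER))

    def test_agrees_with_exhaustive_oracle(self):
        """Exact agreement with the reference scorer on 300 random instances,
        a third of which carry a (possibly overhanging) noisy linker copy."""
        rng = random.Random(42)
        config = LinkerConfig(LINKER)
        for trial in range(300):
            n = rng.randint(9, 200)
            read = list(random_dna(rng, n))
            if trial % 3 == 0:
                lk = LINKER if rng.random() < 0.5 else revcomp(LINKER)
                off = rng.randint(-20, n - 10)
                for i, base in enumerate(lk):
                    if 0 <= off + i < n and rng.random() > 0.1:
                        read[off + i] = base
            read = "".join(read)
            got = find_linker(read, config)
            want = oracle_best_match(read, LINKER, 9, 0.8)
            if want is None:
                assert got is None, read
            else:
                assert got is not None, read
                assert (got.matches, got.read_start, got.strand) == want[:3]
                assert (got.read_end, got.aligned_length, got.longest_exact_run) == want[3:]

    def test_core_rule_monotone(self):
        """Any read accepted at min_core=9 is accepted at min_core=1."""
        rng = random.Random(77)
        loose = LinkerConfig(LINKER, min_core=1)
        strict = LinkerConfig(LINKER, min_core=9)
        for trial in range(100):
            read = list(random_dna(rng, 80))
            off = rng.randint(0, 42)
            for i, base in enumerate(LINKER):
                if off + i < 80 and rng.random() > 0.2:
                    read[off + i] = base
            read = "".join(read)
            if find_linker(read, strict) is not None:
                assert find_linker(read, loose) is not None


def _mk_pair(seq1, seq2):
    return ReadPair(
        Read("p/1", seq1, [35] * len(seq1)), Read("p/2", seq2, [35] * len(seq2))
    )


class TestClipPair:
    CONFIG = LinkerConfig(LINKER)

    def test_both_members_planted(self):
        rng = random.Random(3)
        s1 = random_dna(rng, 60) + LINKER + random_dna(rng, 30)
        s2 = random_dna(rng, 40) + LINKER + random_dna(rng, 50)
        out = clip_pair(_mk_pair(s1, s2), self.CONFIG)
        assert out.category is ClipCategory.BOTH
        assert out.pair.read1.sequence == s1[:60]
        assert out.pair.read2.sequence == s2[:40]
        assert not out.demoted

    def test_neither_member(self):
        rng = random.Random(5)
        while True:
            s1, s2 = random_dna(rng, 100), random_dna(rng, 100)
            if (oracle_best_match(s1, LINKER, 9, 0.8) is None
                    and oracle_best_match(s2, LINKER, 9, 0.8) is None):
                break
        out = clip_pair(_mk_pair(s1, s2), self.CONFIG)
        assert out.category is ClipCategory.NEITHER
        assert out.pair.read1.sequence == s1 and out.pair.read2.sequence == s2

    def test_short_kept_length_demotes(self):
        rng = random.Random(8)
        s1 = random_dna(rng, 10) + LINKER + random_dna(rng, 60)
        while True:
            s2 = random_dna(rng, 108)
            if oracle_best_match(s2, LINKER, 9, 0.8) is None:
                break
        out = clip_pair(_mk_pair(s1, s2), self.CONFIG, min_kept_length=25)
        assert out.category is ClipCategory.READ1_ONLY
        assert out.read1_too_short and out.demoted
        assert len(out.pair.read1) == 10

    def test_idempotent(self):
        """Clipping an already-clipped pair changes nothing."""
        rng = random.Random(31)
        for trial in range(50):
            s1 = random_dna(rng, rng.randint(40, 80))
            s2 = random_dna(rng, rng.randint(40, 80))
            if trial % 2 == 0:
                s1 = s1[:30] + LINKER + s1[30:]
            once = clip_pair(_mk_pair(s1, s2), self.CONFIG)
            twice = clip_pair(once.pair, self.CONFIG)
            assert twice.category is ClipCategory.NEITHER
            assert twice.pair.read1.sequence == once.pair.read1.sequence
            assert twice.pair.read2.sequence == once.pair.read2.sequence


class TestSplit454:
    CONFIG = LinkerConfig(LINKER)

    def test_palindromic_tail_self_check(self):
        read = Read("x", "AAAA" + LINKER + "CCGG", [30] * 46)
        fwd, rev, split = split_454(read, self.CONFIG, trim_quality=20)
        assert split
        assert fwd.sequence == "AAAA"
        assert rev.sequence == revcomp("CCGG") == "CCGG"  # palindrome

    def test_low_quality_tail_trimmed_before_rc(self):
        tail = "ACGTTG"
        quals = [30] * (4 + 38) + [30, 30, 30, 30, 2, 2]
        read = Read("x", "TTTT" + LINKER + tail, quals)
        fwd, rev, split = split_454(read, self.CONFIG, trim_quality=20)
        assert split
        # trailing two Q2 bases dropped, remainder reverse complemented
        assert rev.sequence == revcomp("ACGT")
        assert rev.quality == [30, 30, 30, 30]

    def test_unsplit_flag_without_linker(self):
        rng = random.Random(17)
        while True:
            seq = random_dna(rng, 90)
            if oracle_best_match(seq, LINKER, 9, 0.8) is None:
                break
        fwd, rev, split = split_454(Read("x", seq, [30] * 90), self.CONFIG)
        assert not split and fwd is None and rev is None

    def test_length_conservation(self):
        rng = random.Random(23)
        for _ in range(25):
            a, b = rng.randint(0, 40), rng.randint(0, 40)
            seq = random_dna(rng, a) + LINKER + random_dna(rng, b)
            read = Read("x", seq, [30] * len(seq))
            fwd, rev, split = split_454(read, self.CONFIG, trim_quality=0)
            if not split:
                continue
            m = find_linker(seq, self.CONFIG)
            # Q0 threshold: nothing trimmed, so segments partition the read
            assert len(fwd) + (m.read_end - m.read_start) + len(rev) == len(read)


ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


class TestAdapterDrop:
    CONFIG = AdapterFilterConfig([ADAPTER], kmer_length=11, min_terminal_match=8)

    def _run(self, reads):
        stream, counter = drop_adapter_reads(reads, self.CONFIG)
        kept = list(stream)
        return kept, counter

    def test_full_adapter_copy_dropped_stage1(self):
        rng = random.Random(2)
        read = Read("a", random_dna(rng, 30) + ADAPTER + random_dna(rng, 30), [30] * 93)
        kept, counter = self._run([read])
        assert kept == [] and counter.stage1 == 1

    def test_terminal_fragment_dropped_stage2(self):
        rng = random.Random(4)
        read = Read("a", random_dna(rng, 92) + ADAPTER[:8], [30] * 100)
        kept, counter = self._run([read])
        assert kept == [] and counter.stage2 == 1

    def test_adapter_free_reads_all_kept(self):
        """No false positives: every clean read (verified by a brute-force
        substring/terminal oracle) passes both stages unmodified."""
        rng = random.Random(6)
        variants = [ADAPTER, revcomp(ADAPTER)]
        reads = []
        while len(reads) < 200:
            seq = random_dna(rng, 100)
            clean = all(
                a[i : i + 11] not in seq
                for a in variants
                for i in range(len(a) - 10)
            ) and all(
                not seq.endswith(a[:n]) and not seq.startswith(a[-n:])
                for a in variants
                for n in range(8, 34)
            )
            if clean:
                reads.append(Read(f"r{len(reads)}", seq, [30] * 100))
        kept, counter = self._run(reads)
        assert len(kept) == 200
        assert counter.dropped == 0
        assert [r.sequence for r in kept] == [r.sequence for r in reads]

    def test_empty_adapter_list_rejected(self):
        with pytest.raises(ValueError):
            AdapterFilterConfig([])
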