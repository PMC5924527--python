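"""Mate-pair linker clipping and adapter read filtering.

Cre-Lox mate-pair libraries carry a long circularisation linker; reads that
cross the junction must be truncated at the linker or the pair will chimerise
the assembly.  A plain best-match-count scan (as NextClip uses for the short
Nextera junction) produces too many false hits with a long linker, so the
qualifying rule here additionally demands a continuous 9-bp exactly-matching
core inside the aligned span.  The same matcher drives splitting of 454-style
paired reads at an internal linker, and a separate two-stage screen drops
whole reads contaminated by adapters (no trimming — downstream assemblers
that model full-length reads want reads untouched or gone).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .formats import Read, ReadPair, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
# N (and anything else) stays 255 and can never match


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class LinkerConfig:
    """Matching parameters for one linker sequence.

    ``min_core`` is the continuous exact-match run a candidate must contain;
    ``min_identity`` is the fraction of matching bases over the aligned span
    (the span may be a partial overhang at a read end, but never shorter than
    ``min_core``).
    """

    linker_sequence: str
    min_core: int = 9
    min_identity: float = 0.8
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        self.linker_sequence = self.linker_sequence.upper()
        if self.min_core < 1:
            raise ValueError("min_core must be >= 1")
        if self.min_core > len(self.linker_sequence):
            raise ValueError("min_core exceeds linker length")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class LinkerMatch:
    """One qualifying ungapped placement of the linker on a read."""

    read_start: int
    read_end: int  # exclusive
    matches: int
    aligned_length: int
    longest_exact_run: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (self.longest_exact_run <= self.matches <= self.aligned_length):
            raise ValueError("inconsistent match statistics")
        if self.read_start >= self.read_end:
            raise ValueError("empty match span")


def _longest_run(mask: np.ndarray) -> int:
    """Longest run of True in a small boolean vector."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        if cur > best:
            best = cur
    return best


def _scan_strand(
    read_codes: np.ndarray, linker_codes: np.ndarray, config: LinkerConfig, strand: str
) -> list[LinkerMatch]:
    """All qualifying ungapped placements of one linker strand on the read.

    Offsets run from -(L - min_core) to R - min_core so partial overhangs at
    either read end are scanned, but the aligned span (and therefore the
    exact core) always lies fully inside the read.
    """
    R, L = len(read_codes), len(linker_codes)
    out: list[LinkerMatch] = []
    # full-overlap offsets, vectorised
    if R >= L:
        windows = np.lib.stride_tricks.sliding_window_view(read_codes, L)
        eq = windows == linker_codes[None, :]
        match_counts = eq.sum(axis=1)
        qualifying = (match_counts >= config.min_core) & (
            match_counts / L >= config.min_identity
        )
        for off in np.nonzero(qualifying)[0]:
            run = _longest_run(eq[off])
            if run >= config.min_core:
                out.append(
                    LinkerMatch(
                        read_start=int(off),
                        read_end=int(off) + L,
                        matches=int(match_counts[off]),
                        aligned_length=L,
                        longest_exact_run=run,
                        strand=strand,
                    )
                )
    # overhang offsets (aligned span shorter than L but >= min_core)
    overhang_offsets = list(range(-(L - config.min_core), 0))
    overhang_offsets += list(range(max(0, R - L + 1), R - config.min_core + 1))
    for off in overhang_offsets:
        rs, re = max(0, off), min(R, off + L)
        if re - rs < config.min_core or re - rs == L:
            continue
        eq = read_codes[rs:re] == linker_codes[rs - off : re - off]
        aligned = re - rs
        matches = int(eq.sum())
        if matches / aligned < config.min_identity:
            continue
        run = _longest_run(eq)
        if run >= config.min_core:
            out.append(
                LinkerMatch(
                    read_start=rs,
                    read_end=re,
                    matches=matches,
                    aligned_length=aligned,
                    longest_exact_run=run,
                    strand=strand,
                )
            )
    return out


def find_linker(sequence: str, config: LinkerConfig) -> Optional[LinkerMatch]:
    """Best qualifying linker placement on ``sequence``, or None.

    Candidates are ranked by match count; ties break to the leftmost
    read_start, then to the '+' strand, so the result is deterministic.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    if len(sequence) < config.min_core:
        return None
    read_codes = _encode(sequence)
    candidates = _scan_strand(read_codes, _encode(config.linker_sequence), config, "+")
    if config.search_both_strands:
        candidates += _scan_strand(
            read_codes, _encode(revcomp(config.linker_sequence)), config, "-"
        )
    if not candidates:
        return None
    return min(candidates, key=lambda m: (-m.matches, m.read_start, m.strand))


class ClipCategory(enum.Enum):
    BOTH = "BOTH"
    READ1_ONLY = "READ1_ONLY"
    READ2_ONLY = "READ2_ONLY"
    NEITHER = "NEITHER"


@dataclass
class ClipOutcome:
    """Result of clipping one mate pair.

    Members truncated below ``min_kept_length`` are flagged too-short; such a
    pair is demoted — the surviving member should go to a single-end file so
    the paired outputs keep equal cardinality.
    """

    category: ClipCategory
    pair: ReadPair
    read1_too_short: bool = False
    read2_too_short: bool = False

    @property
    def demoted(self) -> bool:
        return self.read1_too_short or self.read2_too_short


def clip_pair(
    pair: ReadPair, config: LinkerConfig, min_kept_length: int = 25
) -> ClipOutcome:
    """Truncate each member at its linker start; classify the pair.

    Truncation keeps [0, match.read_start); applying the operation twice is a
    no-op because no qualifying match survives its own truncation.
    """
    clipped: list[Read] = []
    matched: list[bool] = []
    short: list[bool] = []
    for read in (pair.read1, pair.read2):
        m = find_linker(read.sequence, config) if len(read) >= config.min_core else None
        if m is None:
            clipped.append(read)
            matched.append(False)
            short.append(False)
        else:
            kept = read.slice(0, m.read_start)
            clipped.append(kept)
            matched.append(True)
            short.append(len(kept) < min_kept_length)
    category = {
        (True, True): ClipCategory.BOTH,
        (True, False): ClipCategory.READ1_ONLY,
        (False, True): ClipCategory.READ2_ONLY,
        (False, False): ClipCategory.NEITHER,
    }[(matched[0], matched[1])]
    out_pair = ReadPair.__new__(ReadPair)  # allow empty truncated members
    out_pair.read1, out_pair.read2, out_pair.library_id = (
        clipped[0],
        clipped[1],
        pair.library_id,
    )
    return ClipOutcome(category, out_pair, short[0], short[1])


def split_454(
    read: Read, config: LinkerConfig, trim_quality: int = 20
) -> tuple[Optional[Read], Optional[Read], bool]:
    """Split a 454-style read at an internal linker.

    Returns (forward, reverse_rc, split_flag).  The forward segment is
    [0, linker start); the reverse segment is [linker end, read end) with
    trailing bases of quality < ``trim_quality`` dropped from its 3' end and
    the remainder reverse-complemented (quality reversed alongside) so the
    pair mimics an Illumina mate-pair library.  Unsplit reads come back as
    (None, None, False).
    """
    m = find_linker(read.sequence, config) if len(read) >= config.min_core else None
    if m is None:
        return None, None, False
    forward = read.slice(0, m.read_start)
    forward.id = read.id + "/1"
    reverse = read.slice(m.read_end, len(read))
    end = len(reverse)
    while end > 0 and reverse.quality[end - 1] < trim_quality:
        end -= 1
    reverse = reverse.slice(0, end).reverse_complement()
    reverse.id = read.id + "/2"
    return forward, reverse, True


@dataclass
class AdapterFilterConfig:
    """Two-stage whole-read adapter screen.

    Stage 1 drops a read containing any exact adapter k-mer (both strands);
    stage 2 drops a read whose end carries a terminal exact adapter fragment
    of at least ``min_terminal_match`` bp (read 3' end vs adapter prefix,
    read 5' end vs adapter suffix, both strands).
    """

    adapter_sequences: list[str]
    kmer_length: int = 11
    min_terminal_match: int = 8

    def __post_init__(self) -> None:
        if not self.adapter_sequences:
            raise ValueError("empty adapter list")
        self.adapter_sequences = [a.upper() for a in self.adapter_sequences]
        if self.kmer_length > min(len(a) for a in self.adapter_sequences):
            raise ValueError("kmer_length exceeds shortest adapter length")


def _adapter_kmer_set(config: AdapterFilterConfig) -> set[str]:
    k = config.kmer_length
    kmers: set[str] = set()
    for adapter in config.adapter_sequences:
        for seq in (adapter, revcomp(adapter)):
            for i in range(len(seq) - k + 1):
                kmers.add(seq[i : i + k])
    return kmers


def _has_terminal_match(seq: str, config: AdapterFilterConfig) -> bool:
    t = config.min_terminal_match
    for adapter in config.adapter_sequences:
        for a in (adapter, revcomp(adapter)):
            nmax = min(len(seq), len(a))
            for n in range(t, nmax + 1):
                if seq.endswith(a[:n]) or seq.startswith(a[-n:]):
                    return True
    return False


def drop_adapter_reads(
    reads: Iterable[Read], config: AdapterFilterConfig
) -> tuple[Iterator[Read], "AdapterDropCounter"]:
    """Yield adapter-free reads; count drops per stage.

    Reads are never modified — they are kept whole or dropped whole.  The
    counter fills in as the returned stream is consumed.
    """
    counter = AdapterDropCounter()
    kmers = _adapter_kmer_set(config)
    k = config.kmer_length

    def _gen() -> Iterator[Read]:
        for read in reads:
            seq = read.sequence
            if any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1)):
                counter.stage1 += 1
                continue
            if _has_terminal_match(seq, config):
                counter.stage2 += 1
                continue
            counter.kept += 1
            yield read

    return _gen(), counter


@dataclass
class AdapterDropCounter:
    kept: int = 0
    stage1: int = 0  # internal adapter k-mer
    stage2: int = 0  # terminal adapter fragment

    @property
    def dropped(self) -> int:
        return self.stage1 + self.stage2
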