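"""Seeded generators for every input class the toolkit consumes.

Each generator emulates the corresponding real data source — a genome with
controlled duplication structure, shotgun reads with substitution errors and
adapter contamination, mate pairs with read-through junction linkers, pair
alignments with a known insert distribution, annotated variants on both
sides of every hard-filter threshold — and emits a machine-readable truth
record alongside, so every downstream module can be tested against known
ground truth without external downloads.  All generators are deterministic
under their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .formats import Read, ReadPair, MaskIntervals, revcomp
from .insert_size import Orientation, PairAlignment
from .variant_filter import FilterPolicy, Genotype, VariantRecord, hard_filter

PathLike = Union[str, Path]

#: placeholder Cre-Lox-style junction linker: fixed 38 bp, non-palindromic
DEFAULT_LINKER = "TCGTCTTCAAGAATTCTCATGTTTGACAGCTTATCATC"
#: Illumina TruSeq universal adapter
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the simulators.

    Defaults describe a desk-scale shotgun experiment: a 200 kb genome read
    to 60× with 100 bp reads, error-free unless ``base_error_rate`` is set,
    and a 5 kb ± 300 bp mate-pair insert distribution.
    """

    seed: int = 0
    genome_size: int = 200_000
    duplicated_fraction: float = 0.0
    gc: float = 0.36
    read_length: int = 100
    coverage: float = 60.0
    base_error_rate: float = 0.0
    insert_mean: int = 5000
    insert_sd: int = 300
    linker: str = DEFAULT_LINKER
    adapter: str = DEFAULT_ADAPTER
    contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("duplicated_fraction", "gc", "base_error_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_size < 1000:
            raise ValueError("genome_size must be >= 1 kb")
        if self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("read_length and coverage must be positive")


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def make_genome(config: SimConfig) -> str:
    """Random genome at the configured GC with optional duplication.

    Bases are i.i.d. with P(G)+P(C) = ``gc``.  If ``duplicated_fraction`` is
    d, a contiguous segment of d·genome_size bases from the unique part is
    appended as a second copy, so the returned sequence has exactly
    ``genome_size`` bases of which the segment occurs twice.
    """
    rng = np.random.default_rng(config.seed)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    dup_len = int(round(config.duplicated_fraction * config.genome_size))
    unique_len = config.genome_size - dup_len
    base = rng.choice(4, size=unique_len, p=p)
    if dup_len > 0:
        if dup_len > unique_len:
            raise ValueError("duplicated_fraction too large for genome_size")
        start = int(rng.integers(0, unique_len - dup_len + 1))
        base = np.concatenate([base, base[start : start + dup_len]])
    return _decode(base.astype(np.uint8))


def _quality_for_error_rate(e: float) -> int:
    if e <= 0:
        return 40
    return min(40, max(2, int(round(-10 * math.log10(e)))))


def make_reads(genome: str, config: SimConfig) -> Iterator[Read]:
    """Uniform shotgun reads from both strands with substitution errors.

    Read count is round(coverage · genome / read_length); start positions
    are uniform, strand is fair, substitutions occur i.i.d. per base at
    ``base_error_rate`` (always to a different base).  If
    ``contamination_rate`` > 0, that fraction of reads has the adapter
    overwrite its 3' end from a random internal position, emulating
    adapter read-through.  Qualities encode the error model.
    """
    rng = np.random.default_rng(config.seed + 1)
    G, L = len(genome), config.read_length
    if L > G:
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(config.coverage * G / L))
    table = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    genome_codes = table[np.frombuffer(genome.encode("ascii"), dtype=np.uint8)]
    q = _quality_for_error_rate(config.base_error_rate)
    quality = [q] * L
    positions = rng.integers(0, G - L + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    contaminated = (
        rng.random(n_reads) < config.contamination_rate
        if config.contamination_rate > 0
        else np.zeros(n_reads, dtype=bool)
    )
    adapter = config.adapter.upper()
    for i in range(n_reads):
        codes = genome_codes[positions[i] : positions[i] + L].copy()
        if strands[i]:
            codes = (3 - codes)[::-1]
        if config.base_error_rate > 0:
            errs = np.nonzero(rng.random(L) < config.base_error_rate)[0]
            if errs.size:
                codes[errs] = (codes[errs] + rng.integers(1, 4, size=errs.size)) % 4
        seq = _decode(codes)
        if contaminated[i]:
            at = int(rng.integers(10, max(11, L - 5)))
            fill = (adapter * (L // len(adapter) + 2))[: L - at]  # read-through
            seq = seq[:at] + fill
        yield Read(f"sr{i}", seq, list(quality))


@dataclass
class MatePairTruth:
    """read id → 0-based linker start in that read, or None."""

    linker_positions: dict[str, Optional[int]] = field(default_factory=dict)

    def to_tsv(self, dest: PathLike) -> None:
        with open(dest, "w") as fh:
            for rid, pos in self.linker_positions.items():
                fh.write(f"{rid}\t{'-' if pos is None else pos}\n")


def make_matepairs(
    genome: str,
    config: SimConfig,
    n_pairs: int = 2000,
    linker_fraction: float = 0.3,
) -> tuple[list[ReadPair], MatePairTruth]:
    """Mate pairs with read-through junction linkers planted at known sites.

    Each pair spans an insert drawn from N(insert_mean, insert_sd²)
    (truncated to [2·read_length, genome length]).  With probability
    ``linker_fraction`` per read, the read runs through the circularisation
    junction: its tail from a recorded offset is replaced by the linker
    followed by sequence from the opposite fragment end — the failure mode
    junction clipping exists to fix.  The truth table records the linker
    start per read (None for clean reads).
    """
    rng = np.random.default_rng(config.seed + 2)
    G, L = len(genome), config.read_length
    linker = config.linker.upper()
    if L < len(linker) + 10:
        raise ValueError("read_length too short to plant a full linker")
    truth = MatePairTruth()
    pairs: list[ReadPair] = []
    lo, hi = 2 * L, G
    for i in range(n_pairs):
        insert = int(round(np.clip(rng.normal(config.insert_mean, config.insert_sd), lo, hi)))
        start = int(rng.integers(0, G - insert + 1))
        fragment = genome[start : start + insert]
        reads: list[Read] = []
        for mate, rid in ((1, f"mp{i}/1"), (2, f"mp{i}/2")):
            if mate == 1:
                seq = fragment[:L]
                other_end = revcomp(fragment)[:]  # opposite end, junction side
            else:
                seq = revcomp(fragment)[:L]
                other_end = fragment
            if rng.random() < linker_fraction:
                j = int(rng.integers(5, L - len(linker) - 4))
                tail_len = L - j - len(linker)
                seq = seq[:j] + linker + other_end[:tail_len]
                truth.linker_positions[rid] = j
            else:
                truth.linker_positions[rid] = None
            reads.append(Read(rid, seq[:L], [37] * L))
        pairs.append(ReadPair(reads[0], reads[1], library_id="simMP"))
    return pairs, truth


def make_pair_alignments(
    config: SimConfig,
    n_pairs: int = 1000,
    contig_length: int = 30_000,
    contig_id: str = "ctg1",
    orientation: Orientation = Orientation.FR,
) -> list[PairAlignment]:
    """Pair alignments with a known insert distribution on one contig.

    Inserts are drawn from N(insert_mean, insert_sd²) truncated to
    [2·read_length, contig_length]; left ends are uniform given the insert.
    """
    rng = np.random.default_rng(config.seed + 3)
    L = config.read_length
    out: list[PairAlignment] = []
    for _ in range(n_pairs):
        insert = int(
            round(np.clip(rng.normal(config.insert_mean, config.insert_sd), 2 * L, contig_length))
        )
        pos1 = int(rng.integers(0, contig_length - insert + 1))
        pos2 = pos1 + insert - L
        out.append(
            PairAlignment(
                contig_id=contig_id,
                contig_length=contig_length,
                pos1=pos1,
                pos2=pos2,
                read_len1=L,
                read_len2=L,
                orientation=orientation,
                mapq1=60,
                mapq2=60,
                same_contig=True,
            )
        )
    return out


def write_sam(pairs: list[PairAlignment], dest: PathLike) -> None:
    """Plain-SAM rendering of simulated FR pair alignments."""
    contigs: dict[str, int] = {}
    for p in pairs:
        contigs[p.contig_id] = max(contigs.get(p.contig_id, 0), p.contig_length)
    with open(dest, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, p in enumerate(pairs):
            qname = p.qname or f"pa{i}"
            seq1, seq2 = "A" * p.read_len1, "A" * p.read_len2
            # FR: mate1 forward at pos1, mate2 reverse at pos2
            fh.write(
                f"{qname}\t99\t{p.contig_id}\t{p.pos1 + 1}\t{p.mapq1}\t"
                f"{p.read_len1}M\t=\t{p.pos2 + 1}\t{p.insert}\t{seq1}\t*\n"
            )
            fh.write(
                f"{qname}\t147\t{p.contig_id}\t{p.pos2 + 1}\t{p.mapq2}\t"
                f"{p.read_len2}M\t=\t{p.pos1 + 1}\t{-p.insert}\t{seq2}\t*\n"
            )


@dataclass
class VariantTruth:
    should_pass: dict[int, bool] = field(default_factory=dict)  # record index
    masked: dict[int, bool] = field(default_factory=dict)

    def to_json(self, dest: PathLike) -> None:
        with open(dest, "w") as fh:
            json.dump(
                {"should_pass": self.should_pass, "masked": self.masked}, fh, default=str
            )


# per-rule (passing-range, failing-range) samplers; ranges sit clear of the
# thresholds so the designed truth is unambiguous
_RULE_RANGES = {
    "QD": ((2.5, 35.0), (0.0, 1.8)),
    "FS": ((0.0, 18.0), (22.0, 60.0)),
    "MQ": ((42.0, 60.0), (10.0, 38.0)),
    "MQRankSum": ((-10.0, 5.0), (-30.0, -14.0)),
    "ReadPosRankSum": ((-6.0, 6.0), (-19.0, -9.0)),
}
_INDEL_RPRS = ((-18.0, 6.0), (-40.0, -22.0))


def make_variants(
    config: SimConfig,
    n_records: int = 500,
    contig_length: int = 100_000,
    fail_rate: float = 0.3,
    missing_rate: float = 0.1,
    masked_fraction: float = 0.2,
    snp_fraction: float = 0.7,
    hom_fraction: float = 0.05,
) -> tuple[list[VariantRecord], MaskIntervals, VariantTruth]:
    """Annotated variants with designed pass/fail truth plus a repeat mask.

    Each record is designed to pass or fail the hard filter: failing records
    have at least one annotation drawn from beyond its threshold, passing
    records have all present annotations inside the keep region (absent
    annotations pass by convention).  A mask of roughly ``masked_fraction``
    of the contig is emitted with per-record membership in the truth.
    """
    rng = np.random.default_rng(config.seed + 4)
    positions = np.sort(rng.choice(contig_length, size=n_records, replace=False))
    bases = "ACGT"
    records: list[VariantRecord] = []
    truth = VariantTruth()
    policy = FilterPolicy()
    for idx, pos in enumerate(positions):
        is_snp = rng.random() < snp_fraction
        ref_base = bases[rng.integers(0, 4)]
        if is_snp:
            alt = bases[(bases.index(ref_base) + int(rng.integers(1, 4))) % 4]
            ref = ref_base
            keys = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
        else:
            if rng.random() < 0.5:  # deletion
                ref = ref_base + "".join(bases[b] for b in rng.integers(0, 4, size=2))
                alt = ref_base
            else:  # insertion
                ref = ref_base
                alt = ref_base + "".join(bases[b] for b in rng.integers(0, 4, size=2))
            keys = ("QD", "FS", "ReadPosRankSum")
        should_pass = bool(rng.random() >= fail_rate)
        failing = set()
        if not should_pass:
            failing = {keys[int(rng.integers(0, len(keys)))]}
        annotations: dict[str, float] = {}
        for key in keys:
            rng_pass, rng_fail = (
                _INDEL_RPRS if (key == "ReadPosRankSum" and not is_snp) else _RULE_RANGES[key]
            )
            if key in failing:
                lo, hi = rng_fail
            else:
                if rng.random() < missing_rate:
                    continue  # genuinely absent annotation; passes by default
                lo, hi = rng_pass
            annotations[key] = round(float(rng.uniform(lo, hi)), 2)
        genotype = Genotype.HOM_ALT if rng.random() < hom_fraction else Genotype.HET
        rec = VariantRecord(
            contig="chr1",
            pos=int(pos),
            ref=ref,
            alt=alt,
            genotype=genotype,
            annotations=annotations,
            sample="1/1" if genotype is Genotype.HOM_ALT else "0/1",
        )
        passed, _ = hard_filter(rec, policy)
        assert passed == should_pass, "designed truth must match the predicate"
        records.append(rec)
        truth.should_pass[idx] = should_pass
    # mask: non-overlapping random intervals totalling ~masked_fraction
    mask = MaskIntervals()
    n_iv = 20
    iv_len = int(masked_fraction * contig_length / n_iv)
    starts = np.sort(rng.choice(contig_length - iv_len, size=n_iv, replace=False))
    for s in starts:
        mask.add("chr1", int(s), int(s) + iv_len)
    for idx, rec in enumerate(records):
        truth.masked[idx] = mask.contains(rec.contig, rec.pos)
    return records, mask, truth
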