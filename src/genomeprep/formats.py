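"""Readers/writers for the plain-text formats the toolkit consumes.

All coordinates are normalised to 0-based half-open internally; 1-based
formats (VCF) are converted at the I/O boundary.  FASTQ quality is Phred-33.
The VCF reader handles a deliberate minimal subset (CHROM/POS/REF/ALT, the
numeric INFO annotations the hard filter needs, one sample's GT); everything
else is carried as opaque text so records round-trip byte-identically.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO

from .variant_filter import ANNOTATION_KEYS, Genotype, VariantRecord

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N self-complements."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed record in an input file; the message names the record."""


# ---------------------------------------------------------------------------
# reads


@dataclass
class Read:
    """A sequencing read: id, uppercase DNA over {A,C,G,T,N}, Phred scores."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> "Read":
        return Read(self.id, self.sequence[start:end], self.quality[start:end])

    def reverse_complement(self) -> "Read":
        return Read(self.id, revcomp(self.sequence), self.quality[::-1])


@dataclass
class ReadPair:
    read1: Read
    read2: Read
    library_id: str = ""

    def __post_init__(self) -> None:
        if len(self.read1) == 0 or len(self.read2) == 0:
            raise ValueError("both members of a ReadPair must be non-empty")


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(source: Union[PathLike, TextIO]) -> Iterator[Read]:
    """Stream 4-line FASTQ records as :class:`Read` (Phred = ASCII − 33)."""
    handle = source if hasattr(source, "read") else _open_text(source)
    close = handle is not source
    try:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                break
            index += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"record {index}: header does not start with '@'")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"record {index}: missing '+' separator line")
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {index}: sequence length {len(seq)} != quality "
                    f"length {len(qual)}"
                )
            yield Read(header[1:].split()[0] if header[1:] else "",
                       seq, [ord(c) - 33 for c in qual])
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[Read], dest: Union[PathLike, TextIO]) -> int:
    """Write reads as 4-line FASTQ; returns the record count."""
    handle = dest if hasattr(dest, "write") else _open_text(dest, "wt")
    close = handle is not dest
    n = 0
    try:
        for r in reads:
            handle.write(f"@{r.id}\n{r.sequence}\n+\n")
            handle.write("".join(chr(q + 33) for q in r.quality) + "\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def read_fasta(source: PathLike) -> dict[str, str]:
    """id → uppercase sequence (Biopython-backed)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


def write_fasta(seqs: dict[str, str], dest: Union[PathLike, TextIO], width: int = 80) -> None:
    handle = dest if hasattr(dest, "write") else _open_text(dest, "wt")
    close = handle is not dest
    try:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# intervals (BED)


class MaskIntervals:
    """Per-sequence sorted, merged 0-based half-open intervals.

    Overlapping or book-ended intervals are merged on normalisation, so the
    stored set is always disjoint and sorted; membership and total masked
    length are O(log n) / O(n).
    """

    def __init__(self, intervals: Optional[dict[str, Iterable[tuple[int, int]]]] = None):
        self._raw: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for contig, ivs in intervals.items():
                for s, e in ivs:
                    self.add(contig, s, e)

    def add(self, contig: str, start: int, end: int) -> None:
        if start < 0 or start >= end:
            raise ParseError(f"invalid interval {contig}:{start}-{end}")
        self._raw.setdefault(contig, []).append((int(start), int(end)))
        self._merged: Optional[dict[str, list[tuple[int, int]]]] = None

    @property
    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        if getattr(self, "_merged", None) is None:
            merged: dict[str, list[tuple[int, int]]] = {}
            for contig, ivs in self._raw.items():
                out: list[tuple[int, int]] = []
                for s, e in sorted(ivs):
                    if out and s <= out[-1][1]:  # overlap or adjacency
                        out[-1] = (out[-1][0], max(out[-1][1], e))
                    else:
                        out.append((s, e))
                merged[contig] = out
            self._merged = merged
        return self._merged

    def contains(self, contig: str, pos: int) -> bool:
        ivs = self.intervals.get(contig)
        if not ivs:
            return False
        import bisect

        i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def masked_length(self, contig: Optional[str] = None) -> int:
        ivs = self.intervals
        if contig is not None:
            return sum(e - s for s, e in ivs.get(contig, []))
        return sum(e - s for lst in ivs.values() for s, e in lst)

    def contigs(self) -> list[str]:
        return sorted(self.intervals)


def read_bed(source: Union[PathLike, TextIO]) -> MaskIntervals:
    """Parse a 3+ column BED into merged :class:`MaskIntervals`."""
    handle = source if hasattr(source, "read") else _open_text(source)
    close = handle is not source
    mask = MaskIntervals()
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"BED line {lineno}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"BED line {lineno}: start {start} >= end {end}")
            mask.add(contig, start, end)
    finally:
        if close:
            handle.close()
    mask.intervals  # force normalisation so errors surface here
    return mask


def write_bed(mask: MaskIntervals, dest: Union[PathLike, TextIO]) -> None:
    handle = dest if hasattr(dest, "write") else _open_text(dest, "wt")
    close = handle is not dest
    try:
        for contig in mask.contigs():
            for s, e in mask.intervals[contig]:
                handle.write(f"{contig}\t{s}\t{e}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# minimal VCF

_VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample"


def _classify_gt(gt: str) -> Genotype:
    alleles = gt.replace("|", "/").split("/")
    nonref = [a for a in alleles if a not in ("0", ".")]
    if not nonref:
        return Genotype.HOM_REF
    if len(nonref) == len(alleles) and len(set(nonref)) == 1:
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf_min(source: Union[PathLike, TextIO]) -> Iterator[VariantRecord]:
    """Stream a minimal VCF subset as :class:`VariantRecord`.

    POS is converted to 0-based.  The numeric annotations QD, FS, MQ,
    MQRankSum and ReadPosRankSum are parsed when present; a missing key is
    stored as absent.  One sample with a GT field is required.
    """
    handle = source if hasattr(source, "read") else _open_text(source)
    close = handle is not source
    try:
        recno = 0
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            recno += 1
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"VCF record {recno}: expected ≥10 columns, got {len(parts)}")
            chrom, pos, vid, ref, alt, qual, filt, info, fmt = parts[:9]
            sample = parts[9]
            annotations: dict[str, float] = {}
            info_other: dict[str, Optional[str]] = {}
            if info != ".":
                for item in info.split(";"):
                    if "=" in item:
                        key, value = item.split("=", 1)
                    else:
                        key, value = item, None
                    if key in ANNOTATION_KEYS:
                        try:
                            annotations[key] = float(value)  # type: ignore[arg-type]
                        except (TypeError, ValueError):
                            raise ParseError(
                                f"VCF record {recno}: non-numeric {key}={value!r}"
                            ) from None
                    else:
                        info_other[key] = value
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise ParseError(f"VCF record {recno}: no GT in FORMAT")
            gt = sample.split(":")[fmt_keys.index("GT")]
            yield VariantRecord(
                contig=chrom,
                pos=int(pos) - 1,
                ref=ref,
                alt=alt,
                genotype=_classify_gt(gt),
                annotations=annotations,
                vcf_id=vid,
                qual=qual,
                filter=filt,
                info_other=info_other,
                format=fmt,
                sample=sample,
            )
    finally:
        if close:
            handle.close()


def _format_float(x: float) -> str:
    # match the conventional fixed-point INFO rendering; trim trailing zeros
    s = f"{x:.6g}"
    return s


def write_vcf_min(
    records: Iterable[VariantRecord],
    dest: Union[PathLike, TextIO],
    filter_override: Optional[dict[int, str]] = None,
) -> int:
    """Write records in the minimal subset; POS back to 1-based.

    ``filter_override`` maps record index (0-based, in iteration order) to a
    FILTER string (e.g. 'PASS' or semicolon-joined failed-rule names).
    """
    handle = dest if hasattr(dest, "write") else _open_text(dest, "wt")
    close = handle is not dest
    n = 0
    try:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(_VCF_HEADER + "\n")
        for i, v in enumerate(records):
            info_items = [
                f"{k}={_format_float(v.annotations[k])}"
                for k in ANNOTATION_KEYS
                if k in v.annotations
            ]
            info_items += [
                k if val is None else f"{k}={val}" for k, val in v.info_other.items()
            ]
            info = ";".join(info_items) if info_items else "."
            filt = v.filter
            if filter_override and i in filter_override:
                filt = filter_override[i]
            handle.write(
                "\t".join(
                    [
                        v.contig,
                        str(v.pos + 1),
                        v.vcf_id,
                        v.ref,
                        v.alt,
                        v.qual,
                        filt,
                        info,
                        v.format,
                        v.sample,
                    ]
                )
                + "\n"
            )
            n += 1
    finally:
        if close:
            handle.close()
    return n
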