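"""Insert-size estimation from read-pair alignments.

Mate-pair libraries rarely achieve their nominal insert size, and scaffolders
need the realised distribution.  Pairs aligned near contig ends are biased
(a contig shorter than the insert cannot host a concordant pair at all), so
only contigs at least three times the nominal insert length contribute.
Residual junction chimeras are handled with a robust MAD-based outlier pass
before the mean/sd are taken.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam

PathLike = Union[str, Path]


class Orientation(enum.Enum):
    FR = "FR"  # innie: upstream mate forward, downstream mate reverse
    RF = "RF"  # outie
    TANDEM = "TANDEM"  # same strand; never a valid library geometry here


@dataclass
class PairAlignment:
    """Geometry of one read pair on the assembly."""

    contig_id: str
    contig_length: int
    pos1: int  # 0-based leftmost mapped position of mate 1
    pos2: int
    read_len1: int
    read_len2: int
    orientation: Orientation
    mapq1: int = 60
    mapq2: int = 60
    same_contig: bool = True
    qname: str = ""

    def __post_init__(self) -> None:
        if self.read_len1 <= 0 or self.read_len2 <= 0:
            raise ValueError("read lengths must be positive")
        if self.same_contig:
            for p in (self.pos1, self.pos2):
                if not 0 <= p < self.contig_length:
                    raise ValueError(
                        f"position {p} outside contig {self.contig_id} "
                        f"(length {self.contig_length})"
                    )

    @property
    def insert(self) -> int:
        """Outer distance: leftmost start to rightmost end."""
        return max(self.pos1 + self.read_len1, self.pos2 + self.read_len2) - min(
            self.pos1, self.pos2
        )


@dataclass
class InsertSizeEstimate:
    mean: float
    sd: float
    median: float
    n_used: int
    n_rejected_by_contig_gate: int
    n_rejected_other: int
    rejection_detail: dict[str, int] = field(default_factory=dict)


class NoUsablePairsError(ValueError):
    def __init__(self, detail: dict[str, int]):
        self.detail = detail
        super().__init__(f"no usable pairs; rejections: {detail}")


def parse_sam_pairs(source: PathLike) -> Iterator[PairAlignment]:
    """Join primary SAM records into :class:`PairAlignment` by query name.

    Secondary and supplementary records are ignored; pairs with an unmapped
    or missing mate are skipped (counted on the generator's ``skipped``
    attribute after exhaustion).  Contig lengths come from the @SQ header.
    """
    return _SamPairIterator(source)


class _SamPairIterator:
    def __init__(self, source: PathLike):
        self.skipped = 0
        self._source = str(source)

    def __iter__(self) -> Iterator[PairAlignment]:
        pending: dict[str, pysam.AlignedSegment] = {}
        with pysam.AlignmentFile(self._source, "r", check_sq=False) as sam:
            lengths = dict(zip(sam.references, sam.lengths))
            for rec in sam:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_unmapped or rec.reference_name is None:
                    self.skipped += 1
                    continue
                if rec.reference_name not in lengths:
                    raise ValueError(f"unknown contig {rec.reference_name!r} in record")
                mate = pending.pop(rec.query_name, None)
                if mate is None:
                    pending[rec.query_name] = rec
                    continue
                yield _join(mate, rec, lengths)
        self.skipped += len(pending)


def _join(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, lengths: dict[str, int]
) -> PairAlignment:
    r1, r2 = (a, b) if a.is_read1 or b.is_read2 else (b, a)
    same = r1.reference_name == r2.reference_name
    if r1.is_reverse == r2.is_reverse:
        orientation = Orientation.TANDEM
    else:
        upstream = r1 if r1.reference_start <= r2.reference_start else r2
        orientation = Orientation.RF if upstream.is_reverse else Orientation.FR
    return PairAlignment(
        contig_id=r1.reference_name,
        contig_length=lengths[r1.reference_name],
        pos1=r1.reference_start,
        pos2=r2.reference_start if same else 0,
        read_len1=r1.query_length or r1.infer_read_length() or 1,
        read_len2=r2.query_length or r2.infer_read_length() or 1,
        orientation=orientation,
        mapq1=r1.mapping_quality,
        mapq2=r2.mapping_quality,
        same_contig=same,
        qname=r1.query_name or "",
    )


def estimate_insert(
    pairs: Iterable[PairAlignment],
    target_insert: int,
    expected_orientation: Orientation = Orientation.FR,
    min_mapq: int = 20,
    contig_gate_factor: float = 3.0,
    mad_factor: float = 10.0,
) -> InsertSizeEstimate:
    """Robust insert-size distribution from gated pair alignments.

    A pair contributes only if both mates map to the same contig of length
    ≥ ``contig_gate_factor`` × ``target_insert``, in the expected orientation,
    with both mapping qualities ≥ ``min_mapq``.  Inserts farther than
    ``mad_factor`` × MAD from the median are removed in a single pass before
    the mean and sd are computed.
    """
    if target_insert <= 0:
        raise ValueError("target_insert must be positive")
    detail = {
        "different_contig": 0,
        "contig_gate": 0,
        "orientation": 0,
        "mapq": 0,
        "outlier": 0,
    }
    inserts: list[int] = []
    for p in pairs:
        if not p.same_contig:
            detail["different_contig"] += 1
            continue
        if p.contig_length < contig_gate_factor * target_insert:
            detail["contig_gate"] += 1
            continue
        if p.orientation is Orientation.TANDEM or p.orientation is not expected_orientation:
            detail["orientation"] += 1
            continue
        if p.mapq1 < min_mapq or p.mapq2 < min_mapq:
            detail["mapq"] += 1
            continue
        inserts.append(p.insert)
    if not inserts:
        raise NoUsablePairsError(detail)
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    keep = np.abs(arr - med) <= mad_factor * mad
    detail["outlier"] = int((~keep).sum())
    used = arr[keep]
    return InsertSizeEstimate(
        mean=float(np.mean(used)),
        sd=float(np.std(used, ddof=1)) if used.size > 1 else 0.0,
        median=float(np.median(used)),
        n_used=int(used.size),
        n_rejected_by_contig_gate=detail["contig_gate"],
        n_rejected_other=sum(v for k, v in detail.items() if k != "contig_gate"),
        rejection_detail=detail,
    )
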