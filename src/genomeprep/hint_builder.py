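"""Homology-evidence hint construction for gene prediction.

Protein and transcript alignments against the assembly (exonerate-style,
up to three hits per query) are ranked into a top hit and secondary hits.
The aligned CDS fragments are then truncated from each side — more for
weaker evidence classes, since alignment boundaries of secondary hits are
less trustworthy — clustered into non-redundant intervals, and emitted as
GFF3 hints a gene predictor can anchor on.  After prediction, only genes
supported by both a hint overlap and a protein-database hit are retained.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

PathLike = Union[str, Path]


class Evidence(enum.Enum):
    PROTEIN = "PROTEIN"
    TRANSCRIPT = "TRANSCRIPT"


class Rank(enum.Enum):
    TOP = "TOP"
    SECONDARY = "SECONDARY"


@dataclass
class HomologyHit:
    """One ranked alignment of a query protein/transcript to the assembly."""

    query_id: str
    evidence: Evidence
    target_contig: str
    strand: str  # '+' or '-'
    score: float
    cds_segments: list[tuple[int, int]]  # 0-based half-open on target
    rank: Optional[Rank] = None

    def __post_init__(self) -> None:
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"hit {self.query_id!r}: overlapping segments")
        for s, e in segs:
            if s >= e:
                raise ValueError(f"hit {self.query_id!r}: empty segment ({s},{e})")
        self.cds_segments = segs

    @property
    def total_segment_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def leftmost_start(self) -> int:
        return self.cds_segments[0][0]


@dataclass
class HintPolicy:
    """Per-side truncation widths by (evidence, rank), in target bp.

    Protein evidence: 3 bp per side for top hits, 9 bp for secondary.
    Transcript evidence: untouched for top hits, 3 bp for secondary.
    ``codon_multiple_cuts`` rounds protein cuts up to a multiple of 3
    (off by default: cuts are applied literally in bp).
    """

    cut_bp: dict[tuple[Evidence, Rank], int] = field(
        default_factory=lambda: {
            (Evidence.PROTEIN, Rank.TOP): 3,
            (Evidence.PROTEIN, Rank.SECONDARY): 9,
            (Evidence.TRANSCRIPT, Rank.TOP): 0,
            (Evidence.TRANSCRIPT, Rank.SECONDARY): 3,
        }
    )
    max_hits_per_query: int = 3
    min_segment_after_cut: int = 1
    codon_multiple_cuts: bool = False

    def cut_for(self, evidence: Evidence, rank: Rank) -> int:
        cut = self.cut_bp[(evidence, rank)]
        if self.codon_multiple_cuts and evidence is Evidence.PROTEIN and cut % 3:
            cut += 3 - cut % 3
        return cut


@dataclass
class Hint:
    contig: str
    strand: str
    start: int
    end: int
    source_evidence: Evidence
    support_count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty hint interval")


def rank_hits(
    hits: Iterable[HomologyHit], policy: Optional[HintPolicy] = None
) -> list[HomologyHit]:
    """Assign TOP/SECONDARY ranks per query; drop hits beyond the maximum.

    Per query: sort by score descending, breaking ties by longer summed
    segment length, then leftmost target start, then contig id.  The best
    hit is TOP, the next ``max_hits_per_query − 1`` are SECONDARY.
    """
    policy = policy or HintPolicy()
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[HomologyHit] = []
    for query in by_query:
        ordered = sorted(
            by_query[query],
            key=lambda h: (
                -h.score,
                -h.total_segment_length,
                h.leftmost_start,
                h.target_contig,
            ),
        )
        for i, h in enumerate(ordered[: policy.max_hits_per_query]):
            h.rank = Rank.TOP if i == 0 else Rank.SECONDARY
            out.append(h)
    return out


def truncate_segments(
    hit: HomologyHit, policy: Optional[HintPolicy] = None
) -> tuple[list[tuple[int, int]], int]:
    """Trim each CDS segment by the policy's per-side cut for this hit.

    Returns (trimmed segments, number of segments dropped because trimming
    left them shorter than ``min_segment_after_cut``).
    """
    policy = policy or HintPolicy()
    if hit.rank is None:
        raise ValueError("hit has no rank; call rank_hits first")
    cut = policy.cut_for(hit.evidence, hit.rank)
    trimmed: list[tuple[int, int]] = []
    dropped = 0
    for s, e in hit.cds_segments:
        ns, ne = s + cut, e - cut
        if ne - ns >= policy.min_segment_after_cut:
            trimmed.append((ns, ne))
        else:
            dropped += 1
    return trimmed, dropped


@dataclass
class TaggedSegment:
    contig: str
    strand: str
    evidence: Evidence
    start: int
    end: int


def cluster_hints(segments: Iterable[TaggedSegment]) -> list[Hint]:
    """Single-linkage merge of strictly overlapping segments into hints.

    Segments are grouped by (contig, strand, evidence); half-open abutment
    is *not* overlap, so book-ended segments stay separate.  Output hints
    are disjoint and sorted; their union equals the input union.
    """
    groups: dict[tuple[str, str, Evidence], list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.start >= seg.end:
            raise ValueError("empty segment")
        groups.setdefault((seg.contig, seg.strand, seg.evidence), []).append(
            (seg.start, seg.end)
        )
    hints: list[Hint] = []
    for (contig, strand, evidence), ivs in groups.items():
        current: Optional[list] = None  # [start, end, support]
        for s, e in sorted(ivs):
            if current is not None and s < current[1]:  # strict overlap
                current[1] = max(current[1], e)
                current[2] += 1
            else:
                if current is not None:
                    hints.append(Hint(contig, strand, current[0], current[1], evidence, current[2]))
                current = [s, e, 1]
        if current is not None:
            hints.append(Hint(contig, strand, current[0], current[1], evidence, current[2]))
    hints.sort(key=lambda h: (h.contig, h.start, h.end, h.strand, h.source_evidence.value))
    return hints


def build_hints(
    hits: Iterable[HomologyHit], policy: Optional[HintPolicy] = None
) -> tuple[list[Hint], dict[str, int]]:
    """rank → truncate → cluster; returns hints plus bookkeeping counts."""
    policy = policy or HintPolicy()
    ranked = rank_hits(hits, policy)
    segments: list[TaggedSegment] = []
    dropped_total = 0
    for hit in ranked:
        trimmed, dropped = truncate_segments(hit, policy)
        dropped_total += dropped
        for s, e in trimmed:
            segments.append(TaggedSegment(hit.target_contig, hit.strand, hit.evidence, s, e))
    hints = cluster_hints(segments)
    return hints, {
        "ranked_hits": len(ranked),
        "segments": len(segments),
        "segments_dropped": dropped_total,
        "hints": len(hints),
    }


@dataclass
class GeneSupport:
    gene_id: str
    has_hint_support: bool
    has_db_hit: bool


def retain_genes(genes: Iterable[GeneSupport]) -> tuple[list[str], dict[str, int]]:
    """Keep genes with both hint support and a protein-database hit.

    Purely de novo predictions (neither evidence) and half-supported models
    are discarded; the counts say why.
    """
    kept: list[str] = []
    discarded = {"no_hint": 0, "no_db_hit": 0, "neither": 0}
    for g in genes:
        if g.has_hint_support and g.has_db_hit:
            kept.append(g.gene_id)
        elif g.has_hint_support:
            discarded["no_db_hit"] += 1
        elif g.has_db_hit:
            discarded["no_hint"] += 1
        else:
            discarded["neither"] += 1
    return kept, discarded


# ---------------------------------------------------------------------------
# I/O


def read_hits_tsv(source: PathLike, evidence: Evidence) -> list[HomologyHit]:
    """Tabular hits: query, contig, strand, score, comma-separated segments.

    Segments are given as 'start-end' in 0-based half-open coordinates, e.g.
    ``q1  ctg7  +  812.0  100-220,300-451``.
    """
    hits: list[HomologyHit] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"hits line {lineno}: expected 5 columns")
            query, contig, strand, score, seglist = parts[:5]
            segments = []
            for item in seglist.split(","):
                s, e = item.split("-")
                segments.append((int(s), int(e)))
            hits.append(HomologyHit(query, evidence, contig, strand, float(score), segments))
    return hits


def write_hints_gff3(hints: Iterable[Hint], dest: Union[PathLike, TextIO]) -> int:
    """GFF3 hints with AUGUSTUS-style src/grp attributes (1-based on disk)."""
    handle = dest if hasattr(dest, "write") else open(dest, "w")
    close = handle is not dest
    n = 0
    try:
        handle.write("##gff-version 3\n")
        for i, h in enumerate(hints, 1):
            src = "P" if h.source_evidence is Evidence.PROTEIN else "E"
            feature = "CDSpart" if h.source_evidence is Evidence.PROTEIN else "exonpart"
            handle.write(
                f"{h.contig}\thomology\t{feature}\t{h.start + 1}\t{h.end}\t.\t"
                f"{h.strand}\t.\tsrc={src};grp=hint{i};pri=4;mult={h.support_count}\n"
            )
            n += 1
    finally:
        if close:
            handle.close()
    return n
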