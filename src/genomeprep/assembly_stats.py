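"""Assembly metrics, length filtering and percentage reports.

Standard contiguity statistics (N50/L50 and friends), the final short-
scaffold filter (fragments shorter than the read length of the library that
built the contigs are treated as assembly artifacts), cutoff tables showing
how the metrics move as a minimum-length threshold is raised, and the
rounded percentage arithmetic used in completeness (CEGMA/BUSCO-style) and
repeat-content reports.  All printed percentages round half-up at the
reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]


@dataclass
class Scaffold:
    id: str
    length: int
    n_count: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.id!r}: non-positive length")
        if not 0 <= self.n_count <= self.length:
            raise ValueError(f"scaffold {self.id!r}: n_count out of range")


@dataclass
class ScaffoldSet:
    scaffolds: list[Scaffold] = field(default_factory=list)

    @classmethod
    def from_fasta(cls, path: PathLike) -> "ScaffoldSet":
        scaffolds = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            scaffolds.append(Scaffold(rec.id, len(seq), seq.upper().count("N")))
        return cls(scaffolds)

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "ScaffoldSet":
        return cls([Scaffold(f"s{i}", ln) for i, ln in enumerate(lengths)])

    @property
    def lengths(self) -> list[int]:
        return [s.length for s in self.scaffolds]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    @property
    def n_bases(self) -> int:
        return sum(s.n_count for s in self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)


@dataclass
class StatsConfig:
    length_cutoffs: Sequence[int] = (0, 100, 250, 500, 1000)
    min_final_length: int = 250

    def __post_init__(self) -> None:
        if list(self.length_cutoffs) != sorted(self.length_cutoffs):
            raise ValueError("length_cutoffs must be sorted ascending")


def nx_lx(lengths: Sequence[int], x: float = 50) -> tuple[int, int]:
    """(Nx, Lx): sort descending; Nx is the length where the running sum
    first reaches x% of the total, Lx the number of scaffolds up to it."""
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    threshold = x / 100 * sum(ordered)
    acc = 0
    for i, ln in enumerate(ordered, 1):
        acc += ln
        if acc >= threshold:
            return ln, i
    return ordered[-1], len(ordered)  # unreachable for x <= 100


@dataclass
class FilterResult:
    kept: ScaffoldSet
    removed_count: int
    removed_bp: int


def filter_short(scaffolds: ScaffoldSet, min_final_length: int = 250) -> FilterResult:
    """Drop scaffolds shorter than ``min_final_length`` (boundary kept)."""
    kept = [s for s in scaffolds.scaffolds if s.length >= min_final_length]
    removed = [s for s in scaffolds.scaffolds if s.length < min_final_length]
    return FilterResult(
        kept=ScaffoldSet(kept),
        removed_count=len(removed),
        removed_bp=sum(s.length for s in removed),
    )


def stats_table(scaffolds: ScaffoldSet, config: Optional[StatsConfig] = None) -> pd.DataFrame:
    """One row per minimum-length cutoff; metrics on the ≥-cutoff subset."""
    config = config or StatsConfig()
    rows = []
    for cutoff in config.length_cutoffs:
        subset = [s for s in scaffolds.scaffolds if s.length >= cutoff]
        if subset:
            lengths = [s.length for s in subset]
            n50, l50 = nx_lx(lengths, 50)
            rows.append(
                {
                    "cutoff": cutoff,
                    "count": len(subset),
                    "total_length": sum(lengths),
                    "N50": n50,
                    "L50": l50,
                    "longest": max(lengths),
                    "Ns": sum(s.n_count for s in subset),
                }
            )
        else:
            rows.append(
                {"cutoff": cutoff, "count": 0, "total_length": 0, "N50": 0,
                 "L50": 0, "longest": 0, "Ns": 0}
            )
    return pd.DataFrame(rows).set_index("cutoff")


def percent_report(part: int, whole: int, decimals: int = 2) -> float:
    """100·part/whole, rounded half-up to ``decimals``."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(part) * 100 / Decimal(whole)).quantize(q, rounding=ROUND_HALF_UP))


def repeat_fraction_table(
    class_lengths: dict[str, int], assembly_length: int, decimals: int = 2
) -> dict[str, float]:
    """Per-class masked fraction of the assembly, in percent (half-up)."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    q = Decimal(1).scaleb(-decimals)
    out: dict[str, float] = {}
    for cls, length in class_lengths.items():
        if length < 0 or length > assembly_length:
            raise ValueError(f"class {cls!r}: length {length} outside [0, assembly]")
        out[cls] = float(
            (Decimal(length) * 100 / Decimal(assembly_length)).quantize(
                q, rounding=ROUND_HALF_UP
            )
        )
    return out
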