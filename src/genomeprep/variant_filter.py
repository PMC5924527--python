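"""Variant hard-filtering, repeat-mask exclusion and heterozygosity summaries.

Post-calling QC for a selfing, nearly homozygous diploid genome: variants are
kept or rejected by per-annotation hard thresholds (the GATK-style QD / FS /
MQ / rank-sum battery), variants inside repeat-masked space are discarded,
and the survivors are summarised as zygosity counts and per-kbp heterozygous
densities over the non-masked genome fraction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence


class VariantType(enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class Genotype(enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"


#: annotation keys the hard filter understands
ANNOTATION_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def variant_type(ref: str, alt: str) -> VariantType:
    """SNP iff both alleles are single bases; everything else is an indel."""
    return VariantType.SNP if len(ref) == 1 and len(alt) == 1 else VariantType.INDEL


@dataclass
class VariantRecord:
    """One variant site with the annotations the hard filter consumes.

    ``pos`` is 0-based internally (converted from 1-based VCF at the I/O
    boundary).  ``annotations`` holds only the numeric keys that were present
    in INFO; a missing key is genuinely absent, never imputed to zero.
    Remaining VCF columns are carried as opaque text so that a record can be
    written back unchanged.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    annotations: dict[str, float] = field(default_factory=dict)
    # opaque pass-through fields for round-tripping the on-disk record
    vcf_id: str = "."
    qual: str = "."
    filter: str = "."
    info_other: dict[str, Optional[str]] = field(default_factory=dict)
    format: str = "GT"
    sample: str = "./."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.contig}:{self.pos}")

    @property
    def vtype(self) -> VariantType:
        return variant_type(self.ref, self.alt)

    @property
    def is_het(self) -> bool:
        return self.genotype is Genotype.HET


# ---------------------------------------------------------------------------
# hard filter


@dataclass(frozen=True)
class Rule:
    """keep-condition: annotation `op` threshold (strict inequality)."""

    key: str
    op: str  # 'gt' or 'lt'
    threshold: float

    def passes(self, value: float) -> bool:
        return value > self.threshold if self.op == "gt" else value < self.threshold

    def __str__(self) -> str:
        sym = ">" if self.op == "gt" else "<"
        return f"{self.key}{sym}{self.threshold}"


@dataclass
class FilterPolicy:
    """Keep-thresholds applied per variant type.

    Note the FS rule is a *keep* condition FS < 20.0 — considerably stricter
    than the customary FS > 60 fail threshold — and the indel rule set omits
    the mapping-quality annotations entirely.  Both are deliberate.
    When ``missing_annotation_passes`` a rule whose annotation is absent from
    the record passes (rank-sum statistics are undefined for many sites).
    """

    snp_rules: tuple[Rule, ...] = (
        Rule("QD", "gt", 2.0),
        Rule("FS", "lt", 20.0),
        Rule("MQ", "gt", 40.0),
        Rule("MQRankSum", "gt", -12.5),
        Rule("ReadPosRankSum", "gt", -8.0),
    )
    indel_rules: tuple[Rule, ...] = (
        Rule("QD", "gt", 2.0),
        Rule("FS", "lt", 20.0),
        Rule("ReadPosRankSum", "gt", -20.0),
    )
    missing_annotation_passes: bool = True

    def rules_for(self, vtype: VariantType) -> tuple[Rule, ...]:
        return self.snp_rules if vtype is VariantType.SNP else self.indel_rules


def hard_filter(
    record: VariantRecord, policy: FilterPolicy | None = None
) -> tuple[bool, list[str]]:
    """Apply the per-type rule battery; return (passed, failed-rule names).

    A pure predicate: depends only on the record and the policy.
    """
    policy = policy or FilterPolicy()
    failed: list[str] = []
    for rule in policy.rules_for(record.vtype):
        value = record.annotations.get(rule.key)
        if value is None:
            if not policy.missing_annotation_passes:
                failed.append(rule.key)
            continue
        if not rule.passes(value):
            failed.append(rule.key)
    return (not failed), failed


# ---------------------------------------------------------------------------
# mask subtraction


def subtract_masked(
    variants: Iterable[VariantRecord], mask
) -> tuple[list[VariantRecord], int]:
    """Drop variants whose start coordinate lies inside a masked interval.

    Membership is tested on the variant's 0-based start only (indel spans are
    not intersected); ``mask`` is any object with a ``contains(contig, pos)``
    method, normally :class:`genomeprep.formats.MaskIntervals`.
    """
    kept: list[VariantRecord] = []
    removed = 0
    for v in variants:
        if mask.contains(v.contig, v.pos):
            removed += 1
        else:
            kept.append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# summaries


def _round_half_up(value: Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def zygosity_summary(
    variants: Iterable[VariantRecord],
) -> dict[VariantType, dict[str, float]]:
    """Per-type counts: total, hom_alt, het, and percent homozygous (2 dp).

    A type with zero observed variants is simply absent from the result —
    reporting 0% homozygosity for an empty class would be misleading.
    """
    counts: dict[VariantType, dict[str, int]] = {}
    for v in variants:
        c = counts.setdefault(v.vtype, {"total": 0, "hom_alt": 0, "het": 0})
        c["total"] += 1
        if v.genotype is Genotype.HOM_ALT:
            c["hom_alt"] += 1
        elif v.genotype is Genotype.HET:
            c["het"] += 1
    out: dict[VariantType, dict[str, float]] = {}
    for vt, c in counts.items():
        out[vt] = dict(c)
        out[vt]["percent_hom"] = _round_half_up(
            Decimal(c["hom_alt"]) * 100 / Decimal(c["total"]), 2
        )
    return out


def density_per_kbp(het_count: int, unmasked_bp: int, decimals: int = 4) -> float:
    """Heterozygous-variant density per kbp of non-masked sequence."""
    if unmasked_bp <= 0:
        raise ValueError("unmasked_bp must be positive")
    if het_count < 0:
        raise ValueError("het_count must be non-negative")
    return _round_half_up(Decimal(het_count) / (Decimal(unmasked_bp) / 1000), decimals)


def het_density(
    variants: Iterable[VariantRecord], unmasked_bp: int
) -> dict[VariantType, float]:
    """Per-type heterozygous density per kbp (4 dp) over ``unmasked_bp``.

    The denominator is an explicit input: what counts as "non-masked" depends
    on which masker produced the mask, so it is never derived silently here.
    """
    if unmasked_bp <= 0:
        raise ValueError("unmasked_bp must be positive")
    het: dict[VariantType, int] = {}
    seen: set[VariantType] = set()
    for v in variants:
        seen.add(v.vtype)
        if v.is_het:
            het[v.vtype] = het.get(v.vtype, 0) + 1
    return {vt: density_per_kbp(het.get(vt, 0), unmasked_bp) for vt in seen}


def apply_filters(
    variants: Iterable[VariantRecord],
    policy: FilterPolicy | None = None,
    mask=None,
) -> dict:
    """Full pipeline: hard filter, then optional mask subtraction.

    Returns a dict with ``passed`` records, ``failed`` (record, failed-rules)
    pairs, and the count removed by the mask.
    """
    policy = policy or FilterPolicy()
    passed: list[VariantRecord] = []
    failed: list[tuple[VariantRecord, list[str]]] = []
    for v in variants:
        ok, why = hard_filter(v, policy)
        if ok:
            passed.append(v)
        else:
            failed.append((v, why))
    masked_removed = 0
    if mask is not None:
        passed, masked_removed = subtract_masked(passed, mask)
    return {"passed": passed, "failed": failed, "masked_removed": masked_removed}
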