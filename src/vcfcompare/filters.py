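"""Variant filters: FILTER status, genomic regions, type and chromosome.

All filters are pure subset operations on a :class:`~vcfcompare.vcf_io.CallSet`
and are idempotent.  The pipeline applies them in the fixed order
PASS -> regions -> chromosome/type.

Region membership convention: BED intervals are 0-based half-open
[start, end); a variant with 1-based position p lies inside
(chrom, start, end) iff the chromosome matches exactly and
p - 1 ∈ [start, end), i.e. start < p <= end.  Only the variant's
anchor base (POS) is tested, not the full REF span.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

from .vcf_io import CallSet, RegionSet, VariantKey


class RegionMode(str, Enum):
    """Keep variants inside the regions, or outside them."""

    INSIDE = "inside"
    OUTSIDE = "outside"


def filter_pass(cs: CallSet) -> CallSet:
    """Keep only variants whose FILTER value is exactly "PASS".

    "." and empty FILTER values count as non-PASS.
    """
    kept = {k for k in cs.variants if cs.filter_status.get(k) == "PASS"}
    return cs.replace_variants(kept)


def _inside_naive(key: VariantKey, rs: RegionSet) -> bool:
    p0 = key.pos - 1
    for chrom, start, end in rs.intervals:
        if chrom == key.chrom and start <= p0 < end:
            return True
    return False


def filter_regions_naive(
    cs: CallSet, rs: RegionSet, mode: RegionMode = RegionMode.INSIDE
) -> CallSet:
    """Region filter checking every interval for every variant (O(n·m)).

    Retained as the reference implementation the optimized sweep is
    verified against.
    """
    mode = RegionMode(mode)
    if mode is RegionMode.INSIDE:
        kept = {k for k in cs.variants if _inside_naive(k, rs)}
    else:
        kept = {k for k in cs.variants if not _inside_naive(k, rs)}
    return cs.replace_variants(kept)


def filter_regions_sorted(
    cs: CallSet, rs: RegionSet, mode: RegionMode = RegionMode.INSIDE
) -> CallSet:
    """Region filter as a single forward sweep over two sorted streams.

    Per chromosome, variants (sorted by position) and intervals (sorted
    by start) are each consumed once.  A running maximum interval end
    handles overlapping and nested intervals without merging them:
    after advancing past all intervals whose start <= p-1, the variant
    is inside iff that maximum end exceeds p-1.
    """
    mode = RegionMode(mode)
    by_chrom = rs.by_chrom()  # interval lists inherit RegionSet's sort
    inside: set[VariantKey] = set()
    variants_by_chrom: dict[str, list[VariantKey]] = {}
    for key in sorted(cs.variants):
        variants_by_chrom.setdefault(key.chrom, []).append(key)
    for chrom, keys in variants_by_chrom.items():
        intervals = by_chrom.get(chrom)
        if not intervals:
            continue
        j = 0
        max_end = -1
        for key in keys:  # ascending pos
            p0 = key.pos - 1
            while j < len(intervals) and intervals[j][0] <= p0:
                if intervals[j][1] > max_end:
                    max_end = intervals[j][1]
                j += 1
            if p0 < max_end:
                inside.add(key)
    if mode is RegionMode.INSIDE:
        kept = inside
    else:
        kept = cs.variants - inside
    return cs.replace_variants(kept)


_BASES = {"A", "C", "G", "T"}


def filter_variant_type(cs: CallSet, vtype: str) -> CallSet:
    """Keep SNPs (single-base substitutions) or indels (length changes).

    snp: len(ref) == len(alt) == 1 with both in {A,C,G,T};
    indel: len(ref) != len(alt).  Multi-base balanced substitutions
    (e.g. AT->GC) belong to neither class.
    """
    if vtype not in ("snp", "indel"):
        raise ValueError(f"vtype must be 'snp' or 'indel', got {vtype!r}")
    if vtype == "snp":
        kept = {
            k
            for k in cs.variants
            if len(k.ref) == 1 and len(k.alt) == 1 and k.ref in _BASES and k.alt in _BASES
        }
    else:
        kept = {k for k in cs.variants if len(k.ref) != len(k.alt)}
    return cs.replace_variants(kept)


def filter_chromosomes(cs: CallSet, chroms: Sequence[str]) -> CallSet:
    """Keep variants on the named chromosomes (exact string match)."""
    wanted = set(chroms)
    return cs.replace_variants({k for k in cs.variants if k.chrom in wanted})
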