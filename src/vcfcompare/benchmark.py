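"""Precision/recall benchmarking of call sets against a golden set.

A called variant is correct iff it has an exact (chrom, pos, ref, alt)
match in the golden set G.  For a compare-set file or pooled group C:

    precision = |C ∩ G| / |C|        recall = |C ∩ G| / |G|

Raw counts are carried alongside the ratios so exported tables are
self-auditing.  The golden set is never filtered; filters apply to the
compare set only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .errors import UndefinedScoreError
from .grouping import VariantGroup
from .vcf_io import CallSet, GoldenSet

Comparable = Union[CallSet, VariantGroup]


@dataclass
class BenchmarkResult:
    """Precision/recall of one file or group against the golden set."""

    name: str
    precision: float
    recall: float
    n_correct: int
    n_called: int
    n_golden: int


def _variants_and_name(item: Comparable):
    if isinstance(item, VariantGroup):
        return item.pooled.variants, item.name
    return item.variants, item.name


def precision_recall(c: Comparable, g: GoldenSet) -> BenchmarkResult:
    """Benchmark one call set (or pooled group) against the golden set.

    Raises :class:`UndefinedScoreError` when either operand is empty —
    a division by zero is never silently returned.
    """
    variants, name = _variants_and_name(c)
    if not variants:
        raise UndefinedScoreError(f"{name}: compare set is empty; precision undefined")
    if not g.variants:
        raise UndefinedScoreError("golden set is empty; recall undefined")
    n_correct = len(variants & g.variants)
    return BenchmarkResult(
        name=name,
        precision=n_correct / len(variants),
        recall=n_correct / len(g.variants),
        n_correct=n_correct,
        n_called=len(variants),
        n_golden=len(g.variants),
    )


def benchmark_many(
    items: Sequence[Comparable], g: GoldenSet
) -> list[BenchmarkResult]:
    """Element-wise :func:`precision_recall`, preserving input order."""
    return [precision_recall(item, g) for item in items]
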