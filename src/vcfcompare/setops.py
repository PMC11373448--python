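"""Multi-set overlap accounting, Jaccard similarity and clustering order.

``venn_tally`` classifies every variant of the union of 2-6 named sets
into exactly one membership pattern (encoded as a bitmask over the
ordered set names), so pattern counts always sum to the size of the
union.

The pairwise similarity used throughout is |A∩B| / |A∪B| — the Jaccard
index.  (Some tools label this quantity a "Jaccard distance"; the
formula is a similarity, and 1 − J is what we feed to clustering.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ArityError, UndefinedScoreError
from .vcf_io import VariantKey

VENN_MIN_SETS = 2
VENN_MAX_SETS = 6


@dataclass
class VennTally:
    """Counts of every non-empty membership pattern over k named sets.

    ``counts`` maps a bitmask (bit i set <=> the variant is in
    ``set_names[i]``) to the number of union variants with exactly that
    membership; there are 2^k - 1 patterns.  ``percentages`` are the
    counts as fractions of the union size.
    """

    set_names: list[str]
    counts: dict[int, int]
    percentages: dict[int, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pattern_label(self, mask: int) -> str:
        return " & ".join(
            name for i, name in enumerate(self.set_names) if mask >> i & 1
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per pattern: membership flags, count and percentage."""
        rows = []
        for mask in sorted(self.counts):
            row = {
                name: int(mask >> i & 1) for i, name in enumerate(self.set_names)
            }
            row["pattern"] = self.pattern_label(mask)
            row["count"] = self.counts[mask]
            row["percentage"] = 100.0 * self.percentages[mask]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Jaccard similarities in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ClusterResult:
    """Deterministic leaf order and merge list from average-linkage clustering."""

    leaf_order: list[int]
    linkage: np.ndarray  # scipy linkage matrix: (i, j, height, size) rows


def _as_sets(
    sets: Mapping[str, Collection[VariantKey]]
) -> tuple[list[str], list[set]]:
    names = list(sets)
    return names, [set(sets[n]) for n in names]


def venn_tally(sets: Mapping[str, Collection[VariantKey]]) -> VennTally:
    """Assign every union variant to its exact membership pattern.

    Accepts 2-6 named sets (insertion order fixes the bit order).
    """
    names, members = _as_sets(sets)
    k = len(names)
    if not (VENN_MIN_SETS <= k <= VENN_MAX_SETS):
        raise ArityError(f"venn_tally supports 2-6 sets, got {k}")
    counts = {mask: 0 for mask in range(1, 2**k)}
    for v in set().union(*members):
        mask = 0
        for i, s in enumerate(members):
            if v in s:
                mask |= 1 << i
        counts[mask] += 1
    total = sum(counts.values())
    percentages = {
        mask: (c / total if total else 0.0) for mask, c in counts.items()
    }
    return VennTally(set_names=names, counts=counts, percentages=percentages)


def intersection_all(
    sets: Mapping[str, Collection[VariantKey]]
) -> set[VariantKey]:
    """Variants present in every set (exportable as a VCF)."""
    names, members = _as_sets(sets)
    if not members:
        raise ArityError("intersection_all needs at least one set")
    return set.intersection(*members)


def jaccard(a: Collection[VariantKey], b: Collection[VariantKey]) -> float:
    """|a ∩ b| / |a ∪ b|; undefined when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise UndefinedScoreError("Jaccard is undefined for two empty sets")
    return len(sa & sb) / len(union)


def jaccard_matrix(sets: Mapping[str, Collection[VariantKey]]) -> SimilarityMatrix:
    """All pairwise Jaccard similarities among >= 2 named sets."""
    names, members = _as_sets(sets)
    if len(names) < 2:
        raise ArityError("jaccard_matrix needs at least two sets")
    for name, s in zip(names, members):
        if not s:
            raise UndefinedScoreError(f"set {name!r} is empty; Jaccard undefined")
    k = len(members)
    values = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = jaccard(members[i], members[j])
    return SimilarityMatrix(labels=names, values=values)


def cluster_order(m: SimilarityMatrix) -> ClusterResult:
    """Average-linkage agglomerative clustering on distance 1 − J.

    The leaf order is deterministic for a given input order (scipy's
    linkage resolves equal-distance merges by candidate index, i.e.
    input order) and is applied to both rows and columns of the
    clustergram.
    """
    if len(m.labels) < 2:
        raise ArityError("cluster_order needs at least two labels")
    dist = 1.0 - m.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return ClusterResult(leaf_order=[int(i) for i in leaves], linkage=linkage)
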