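"""Metadata-driven grouping of call sets.

Files in the compare set are partitioned by the values they take in
chosen metadata columns, and each group's variants are pooled by one of
three methods:

* union         - present in any member file
* intersection  - present in all member files
* majority      - present in strictly more than 50% of member files
                  (a variant in exactly half of an even-sized group is
                  excluded)

The pooled sets satisfy intersection ⊆ majority ⊆ union, and a
singleton group pools to its sole member under all three methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .errors import MetadataError, SpecError
from .vcf_io import CallSet, MetadataTable, VariantKey

logger = logging.getLogger(__name__)

COMBINE_METHODS = ("union", "intersection", "majority")


@dataclass
class GroupSpec:
    """How to partition and pool the compare set.

    group_by: metadata property columns whose value tuples define groups.
    combine: union / intersection / majority.
    label_columns: subset of property columns used for display labels
        (empty means label by the full group key).
    """

    group_by: Sequence[str]
    combine: str = "union"
    label_columns: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_by:
            raise SpecError("group_by must name at least one metadata column")
        if self.combine not in COMBINE_METHODS:
            raise SpecError(
                f"combine must be one of {COMBINE_METHODS}, got {self.combine!r}"
            )


@dataclass
class VariantGroup:
    """One metadata-defined group: its key, member files and pooled set."""

    key: tuple[str, ...]
    group_by: tuple[str, ...]
    members: list[CallSet]
    pooled: CallSet

    @property
    def name(self) -> str:
        return self.pooled.name

    def values(self) -> dict[str, str]:
        return dict(zip(self.group_by, self.key))


def _pool(member_sets: list[set[VariantKey]], combine: str) -> set[VariantKey]:
    if combine == "union":
        return set().union(*member_sets)
    if combine == "intersection":
        return set.intersection(*member_sets)
    # majority: strict > 50% of members
    threshold = 0.5 * len(member_sets)
    pooled = set()
    for v in set().union(*member_sets):
        if sum(v in s for s in member_sets) > threshold:
            pooled.add(v)
    return pooled


def make_groups(
    callsets: Sequence[CallSet], meta: MetadataTable, spec: GroupSpec
) -> list[VariantGroup]:
    """Partition ``callsets`` by their ``spec.group_by`` metadata values.

    Groups are returned sorted by key tuple so downstream tables and
    plots have a deterministic order.  Pooled call sets carry no
    FILTER status (grouping happens after PASS filtering).
    """
    unknown = [c for c in spec.group_by if c not in meta.property_columns]
    if unknown:
        raise SpecError(f"unknown group_by column(s): {', '.join(unknown)}")
    bad_labels = [c for c in spec.label_columns if c not in meta.property_columns]
    if bad_labels:
        raise SpecError(f"unknown label column(s): {', '.join(bad_labels)}")

    buckets: dict[tuple[str, ...], list[CallSet]] = {}
    for cs in callsets:
        row = meta.row(cs.name)  # raises MetadataError on missing file
        key = tuple(row[c] for c in spec.group_by)
        buckets.setdefault(key, []).append(cs)

    groups: list[VariantGroup] = []
    for key in sorted(buckets):
        members = buckets[key]
        pooled_keys = _pool([m.variants for m in members], spec.combine)
        pooled = CallSet(name=" & ".join(key), variants=pooled_keys)
        groups.append(
            VariantGroup(
                key=key, group_by=tuple(spec.group_by), members=members, pooled=pooled
            )
        )

    labels = [group_label(g, spec.label_columns) for g in groups]
    if len(set(labels)) < len(labels):
        logger.warning(
            "group labels collide after restricting to columns %s", spec.label_columns
        )
    return groups


def group_label(g: VariantGroup, label_columns: Sequence[str] | None = None) -> str:
    """Display label: the group's values in ``label_columns``, " & "-joined.

    An empty selection falls back to the full group key.
    """
    if not label_columns:
        return " & ".join(g.key)
    values = g.values()
    missing = [c for c in label_columns if c not in values]
    if missing:
        raise SpecError(
            f"label column(s) not in group_by: {', '.join(missing)}"
        )
    return " & ".join(values[c] for c in label_columns)
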