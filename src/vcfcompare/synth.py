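"""Synthetic VCF/BED/CSV inputs with controlled overlap structure.

Every generator is seeded and deterministic (same seed, byte-identical
files) and returns a ground-truth manifest, so the true Venn tally,
Jaccard matrix and precision/recall against any designed golden subset
are computable in closed form and every analysis module can be checked
against them exactly.

The generated data models structural overlap only — which variants the
files share — not realistic allele frequencies, error profiles or
genotype fields.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import SpecError
from .vcf_io import VariantKey, write_variants_vcf

_CHROMS = ("chr1", "chr2", "chr3")
_POS_MAX = 1_000_000
_BASES = "ACGT"


@dataclass
class OverlapDesign:
    """Requested Venn structure for a family of synthetic VCF files.

    ``pattern_counts`` maps a membership pattern — a tuple of set names,
    a subset of ``set_names`` — to the number of variants that should be
    present in exactly those files.  ``filter_mix`` is the fraction of
    each file's variants marked non-PASS: exactly floor(n * filter_mix)
    of the n variants, taken from the start of the file's sorted key
    list, get FILTER "q10"; the rest are "PASS".
    """

    set_names: Sequence[str]
    pattern_counts: Mapping[tuple[str, ...], int]
    filter_mix: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= len(self.set_names) <= 6):
            raise SpecError("OverlapDesign supports 2-6 set names")
        if len(set(self.set_names)) != len(self.set_names):
            raise SpecError("set names must be unique")
        if not (0.0 <= self.filter_mix <= 1.0):
            raise SpecError("filter_mix must be in [0, 1]")
        known = set(self.set_names)
        for pattern, count in self.pattern_counts.items():
            if count < 0:
                raise SpecError(f"negative count for pattern {pattern}")
            if not pattern or not set(pattern) <= known:
                raise SpecError(f"pattern {pattern} is not a non-empty subset")


def _random_keys(rng: random.Random, n: int) -> list[VariantKey]:
    """n distinct variant keys over chr1-3, positions 1..1e6.

    Distinctness is guaranteed by sampling (chrom, pos) slots without
    replacement; ref != alt always holds.
    """
    slots = rng.sample(range(len(_CHROMS) * _POS_MAX), n)
    keys = []
    for slot in slots:
        chrom = _CHROMS[slot // _POS_MAX]
        pos = slot % _POS_MAX + 1
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        keys.append(VariantKey(chrom, pos, ref, alt))
    return keys


def synth_vcfs(design: OverlapDesign, out_dir: str | Path) -> dict:
    """Write one VCF per set name realizing the designed overlap exactly.

    Returns the ground-truth manifest (also written to
    ``out_dir/manifest.json``): each file's path and exact key set, and
    the realized pattern counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(design.seed)

    patterns = sorted(design.pattern_counts.items())
    total = sum(c for _, c in patterns)
    pool = _random_keys(rng, total)
    per_set: dict[str, set[VariantKey]] = {n: set() for n in design.set_names}
    i = 0
    for pattern, count in patterns:
        for key in pool[i : i + count]:
            for name in pattern:
                per_set[name].add(key)
        i += count

    manifest: dict = {
        "seed": design.seed,
        "filter_mix": design.filter_mix,
        "patterns": {"&".join(p): c for p, c in patterns},
        "files": {},
        "sets": {},
    }
    for name in design.set_names:
        keys = sorted(per_set[name])
        n_nonpass = int(len(keys) * design.filter_mix)
        status = {
            k: ("q10" if j < n_nonpass else "PASS") for j, k in enumerate(keys)
        }
        path = out_dir / f"{name}.vcf"
        write_variants_vcf(keys, path, filter_status=status, compress=False)
        manifest["files"][name] = str(path)
        manifest["sets"][name] = [[k.chrom, k.pos, k.ref, k.alt] for k in keys]
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def manifest_keys(manifest: dict, name: str) -> set[VariantKey]:
    """Rehydrate one file's true key set from a :func:`synth_vcfs` manifest."""
    return {
        VariantKey(c, p, r, a) for c, p, r, a in manifest["sets"][name]
    }


def synth_bed(
    n_intervals: int,
    chrom_sizes: Mapping[str, int],
    seed: int,
    out_path: str | Path,
) -> tuple[Path, set[tuple[str, int]]]:
    """Random sorted BED file plus its exact 1-based position coverage.

    Returns the path and the set of covered (chrom, pos) pairs so region
    filters can be checked against an enumerated oracle.
    """
    rng = random.Random(seed)
    chroms = sorted(chrom_sizes)
    intervals = []
    for _ in range(n_intervals):
        chrom = rng.choice(chroms)
        size = chrom_sizes[chrom]
        start = rng.randrange(0, size)
        end = rng.randrange(start + 1, min(size, start + max(2, size // 4)) + 1)
        intervals.append((chrom, start, end))
    intervals.sort()
    out_path = Path(out_path)
    with open(out_path, "w", encoding="utf-8") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    covered = {
        (chrom, pos)
        for chrom, start, end in intervals
        for pos in range(start + 1, end + 1)  # 1-based positions
    }
    return out_path, covered


def synth_metadata(
    filenames: Sequence[str],
    columns: Mapping[str, Sequence[str]],
    out_path: str | Path,
) -> Path:
    """CSV metadata assigning property values to files as a crossed design.

    Columns cycle like nested loops — the first column varies slowest,
    the last fastest — so 4 files with aligner in {BWA, Bowtie2} and
    caller in {HC, VS} enumerate all four combinations.
    """
    if not filenames:
        raise SpecError("synth_metadata needs at least one filename")
    if len(set(filenames)) != len(filenames):
        raise SpecError("filenames must be unique")
    for col, values in columns.items():
        if not values:
            raise SpecError(f"column {col!r} has no values to cycle")
    out_path = Path(out_path)
    header = ["FILENAME"] + list(columns)
    lines = [",".join(header)]
    for i, fname in enumerate(filenames):
        row = [fname]
        for j, (col, values) in enumerate(columns.items()):
            # vary the fastest-cycling column last, like nested loops
            period = 1
            for later in list(columns.values())[j + 1 :]:
                period *= len(later)
            row.append(str(values[(i // period) % len(values)]))
        lines.append(",".join(row))
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path
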