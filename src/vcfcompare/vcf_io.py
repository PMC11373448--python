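"""Reading and writing the tool's file formats.

VCF files (plain text, GZip- or Zip-compressed) are reduced on load to
their exact-match variant identities: one :class:`VariantKey` per
``(CHROM, POS, REF, ALT)`` combination, with the record's FILTER value
kept alongside.  Genotype columns, INFO annotations and QUAL are read
but deliberately not retained — comparison in this package is purely
set-based on variant identity.

The reader is a line parser rather than an htslib wrapper: it must
accept generic-gzip streams, single-member Zip archives and files whose
header is nothing more than a ``#CHROM`` line, and building the
(chrom, pos, ref, alt) key is the one primitive everything else in the
package stands on.

BED intervals are standard 0-based half-open; VCF POS is 1-based.
Metadata is an RFC-4180 CSV keyed by a ``FILENAME`` column.
"""

from __future__ import annotations

import gzip
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import (
    BedFormatError,
    DecompressionError,
    FileSizeError,
    MetadataError,
    VcfFormatError,
)

DEFAULT_MAX_SIZE = 200 * 1024 * 1024  # 200 MB per file

_GZIP_MAGIC = b"\x1f\x8b"
_ZIP_MAGIC = b"PK\x03\x04"


class VariantKey(NamedTuple):
    """Exact-match identity of one variant.

    Equality is component-wise and exact: no normalization is performed
    beyond uppercasing REF/ALT on load, so ``chr1`` and ``1`` are
    different chromosomes and unnormalized indel representations are
    different variants.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class CallSet:
    """A named, deduplicated set of variant keys from one VCF file.

    ``filter_status`` maps every key to the FILTER string of the record
    it came from ("PASS", "q10", "." ...).  When a file contains the
    same key more than once, the first record's FILTER wins.
    """

    name: str
    variants: set[VariantKey] = field(default_factory=set)
    filter_status: dict[VariantKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.filter_status) - self.variants
        if extra:
            raise ValueError("filter_status contains keys not in variants")

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    def sorted_variants(self) -> list[VariantKey]:
        return sorted(self.variants)

    def replace_variants(self, keys: Iterable[VariantKey]) -> "CallSet":
        """New CallSet with the same name restricted to ``keys``."""
        kept = set(keys)
        return CallSet(
            name=self.name,
            variants=kept,
            filter_status={k: v for k, v in self.filter_status.items() if k in kept},
        )


@dataclass
class GoldenSet:
    """Pooled (union) deduplicated truth set from one or more VCF files."""

    variants: set[VariantKey] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class RegionSet:
    """Sorted genomic intervals, 0-based half-open, pooled from BED files."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {(chrom, start, end)}")
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return out

    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}


@dataclass
class MetadataTable:
    """Per-file property table keyed by the mandatory FILENAME column."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "FILENAME" not in self.frame.columns:
            raise MetadataError("metadata is missing the required FILENAME column")
        names = self.frame["FILENAME"]
        if names.duplicated().any():
            dupes = sorted(names[names.duplicated()].unique())
            raise MetadataError(f"duplicate FILENAME values: {', '.join(dupes)}")

    @property
    def property_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "FILENAME"]

    @property
    def filenames(self) -> list[str]:
        return list(self.frame["FILENAME"])

    def row(self, filename: str) -> dict[str, str]:
        hit = self.frame[self.frame["FILENAME"] == filename]
        if hit.empty:
            raise MetadataError(f"file not present in metadata: {filename}")
        return {c: str(hit.iloc[0][c]) for c in self.property_columns}


def _open_vcf_text(path: Path) -> io.TextIOBase:
    """Open plain / gzip / zip VCF content as a text stream.

    Container detection is by magic bytes, not file extension.
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == _GZIP_MAGIC:
        try:
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        except OSError as exc:  # pragma: no cover - gzip.open is lazy
            raise DecompressionError(f"{path}: cannot read gzip stream: {exc}")
    if magic == _ZIP_MAGIC:
        try:
            zf = zipfile.ZipFile(path)
            members = [m for m in zf.namelist() if not m.endswith("/")]
        except zipfile.BadZipFile as exc:
            raise DecompressionError(f"{path}: cannot read zip archive: {exc}")
        if len(members) != 1:
            raise DecompressionError(
                f"{path}: zip archive must contain exactly one file, found {len(members)}"
            )
        return io.TextIOWrapper(zf.open(members[0]), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _check_size(path: Path, max_size: int) -> None:
    size = path.stat().st_size
    if size > max_size:
        raise FileSizeError(
            f"{path}: file size {size} bytes exceeds the limit of {max_size} bytes"
        )


def read_vcf(path: str | Path, max_size: int = DEFAULT_MAX_SIZE) -> CallSet:
    """Load one VCF file into a deduplicated :class:`CallSet`.

    Multi-allelic records (comma-separated ALT) are split into one key
    per alternate allele, each carrying the record's FILTER value.
    REF/ALT are uppercased; chromosome names are kept verbatim.
    Records whose ALT is "." (no alternate called) contribute no keys.
    Duplicate keys are collapsed; the first record's FILTER is kept.
    """
    path = Path(path)
    if not path.exists():
        raise VcfFormatError(path, "file does not exist")
    _check_size(path, max_size)

    variants: set[VariantKey] = set()
    filter_status: dict[VariantKey, str] = {}
    saw_header = False
    try:
        with _open_vcf_text(path) as stream:
            for lineno, raw in enumerate(stream, start=1):
                line = raw.rstrip("\r\n")
                if not line:
                    continue
                if line.startswith("##"):
                    continue
                if line.startswith("#"):
                    if not line.startswith("#CHROM"):
                        raise VcfFormatError(
                            path, f"unexpected header line: {line[:40]!r}", lineno
                        )
                    saw_header = True
                    continue
                if not saw_header:
                    raise VcfFormatError(
                        path, "data before the #CHROM header line (garbled header?)", lineno
                    )
                fields = line.split("\t")
                if len(fields) < 7:
                    raise VcfFormatError(
                        path, f"record has {len(fields)} columns, expected >= 7", lineno
                    )
                chrom, pos_s, _id, ref, alt_field, _qual, filt = fields[:7]
                try:
                    pos = int(pos_s)
                except ValueError:
                    raise VcfFormatError(path, f"non-integer POS {pos_s!r}", lineno)
                if pos < 1:
                    raise VcfFormatError(path, f"POS must be >= 1, got {pos}", lineno)
                ref = ref.upper()
                if not ref or ref == ".":
                    raise VcfFormatError(path, "missing REF allele", lineno)
                if not filt:
                    filt = "."
                if alt_field in (".", ""):
                    continue  # monomorphic record: no alternate allele
                for alt in alt_field.upper().split(","):
                    if not alt:
                        raise VcfFormatError(path, "empty ALT allele", lineno)
                    key = VariantKey(chrom, pos, ref, alt)
                    if key not in variants:
                        variants.add(key)
                        filter_status[key] = filt
    except (OSError, UnicodeDecodeError, EOFError) as exc:
        raise DecompressionError(f"{path}: cannot read contents: {exc}")

    if not saw_header:
        raise VcfFormatError(path, "no #CHROM header line found")
    return CallSet(name=path.name, variants=variants, filter_status=filter_status)


def read_golden(
    paths: Sequence[str | Path], max_size: int = DEFAULT_MAX_SIZE
) -> GoldenSet:
    """Pool one or more truth VCFs into a single deduplicated set (union)."""
    pooled: set[VariantKey] = set()
    for p in paths:
        pooled |= read_vcf(p, max_size=max_size).variants
    return GoldenSet(variants=pooled)


def read_bed(paths: Sequence[str | Path]) -> RegionSet:
    """Pool intervals from one or more BED files into a sorted RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    for p in paths:
        path = Path(p)
        if not path.exists():
            raise BedFormatError(path, "file does not exist")
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise BedFormatError(
                        path, f"expected >= 3 columns, got {len(fields)}", lineno
                    )
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise BedFormatError(
                        path, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
                    )
                if start < 0 or start >= end:
                    raise BedFormatError(
                        path, f"invalid interval [{start}, {end})", lineno
                    )
                intervals.append((chrom, start, end))
    return RegionSet(intervals=intervals)


def read_metadata(
    path: str | Path, compare_names: Sequence[str] | None = None
) -> MetadataTable:
    """Load the per-file property CSV and validate it against the compare set.

    Every compare-set filename must appear under the FILENAME column;
    any number of further columns define user properties for grouping,
    labeling and plot styling.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    table = MetadataTable(frame=frame)
    if compare_names:
        known = set(table.filenames)
        missing = [n for n in compare_names if n not in known]
        if missing:
            raise MetadataError(
                "compare-set files missing from metadata FILENAME column: "
                + ", ".join(missing)
            )
    return table


def write_variants_vcf(
    variants: Iterable[VariantKey],
    path: str | Path,
    filter_status: Mapping[VariantKey, str] | None = None,
    compress: bool = True,
) -> Path:
    """Write variant keys as a minimal, sorted, (optionally GZip) VCF.

    Records are sorted by (chrom, pos, ref, alt) with lexicographic
    chromosome order; ``read_vcf`` on the output recovers exactly the
    input key set.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=vcfcompare",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    status = filter_status or {}
    for key in sorted(set(variants)):
        filt = status.get(key, ".")
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t{filt}\t."
        )
    text = "\n".join(lines) + "\n"
    if compress:
        # mtime pinned so identical inputs give byte-identical output
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode("utf-8"))
    else:
        path.write_text(text, encoding="utf-8")
    return path


def write_table_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a labeled table as RFC-4180 CSV (lossless label round-trip).

    The index is written only when it carries labels (non-default).
    """
    path = Path(path)
    keep_index = not isinstance(table.index, pd.RangeIndex) or table.index.name
    table.to_csv(path, index=bool(keep_index))
    return path
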