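"""Orchestration of one analysis request.

The stages run in a fixed order: validate the request, load every
input (collecting errors per file), apply the PASS filter, apply
genomic-region filtering, apply chromosome/type filters, group by
metadata, then run the requested analysis and write its outputs.  If
any input fails to load, no analysis stage runs and the run log
carries the error report instead.

Loaded VCF/BED inputs are cached in-process keyed by file content
hash, so repeated requests over the same data skip re-parsing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import benchmark as bench
from . import filters, grouping, report, setops, vcf_io
from .errors import ArityError, InputError, SpecError, UndefinedScoreError
from .filters import RegionMode
from .grouping import GroupSpec, VariantGroup
from .report import PivotSpec, StyleSpec
from .vcf_io import CallSet, DEFAULT_MAX_SIZE, GoldenSet, MetadataTable, RegionSet

logger = logging.getLogger(__name__)

ANALYSES = ("summary", "venn", "clustergram", "pr", "filter")


@dataclass
class AnalysisRequest:
    """Everything needed to run one analysis end to end."""

    compare_paths: Sequence[str | Path]
    analysis: str = "summary"
    golden_paths: Sequence[str | Path] = field(default_factory=list)
    metadata_path: str | Path | None = None
    region_paths: Sequence[str | Path] = field(default_factory=list)
    pass_only: bool = False
    region_mode: RegionMode | None = None
    vtype: str | None = None
    chroms: Sequence[str] | None = None
    group_spec: GroupSpec | None = None
    pivot_spec: PivotSpec | None = None
    style: StyleSpec = field(default_factory=StyleSpec)
    output_dir: str | Path = "."
    max_file_size: int = DEFAULT_MAX_SIZE

    def validate(self) -> None:
        if self.analysis not in ANALYSES:
            raise SpecError(f"unknown analysis {self.analysis!r}")
        if not self.compare_paths:
            raise SpecError("compare set must contain at least one file")
        if self.analysis == "pr" and not self.golden_paths:
            raise SpecError("precision-recall analysis requires a golden set")
        if self.group_spec is not None and self.metadata_path is None:
            raise SpecError("grouping requires a metadata CSV")
        if self.region_mode is not None and not self.region_paths:
            raise SpecError("region filtering requires at least one BED file")


@dataclass
class RunLog:
    """Per-file load outcomes, per-stage variant tallies, warnings, errors."""

    load_outcomes: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    outputs: list[Path] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def record_stage(self, name: str, stage: str, count: int) -> None:
        self.stage_counts.setdefault(name, []).append((stage, count))


_vcf_cache: dict[str, CallSet] = {}


def _content_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_vcf_cached(path: Path, max_size: int) -> CallSet:
    digest = _content_hash(path)
    cached = _vcf_cache.get(digest)
    if cached is not None:
        return CallSet(cached.name, set(cached.variants), dict(cached.filter_status))
    cs = vcf_io.read_vcf(path, max_size=max_size)
    _vcf_cache[digest] = CallSet(
        cs.name, set(cs.variants), dict(cs.filter_status)
    )
    return cs


def _load_inputs(request: AnalysisRequest, log: RunLog):
    """Load everything, collecting per-file errors instead of aborting."""
    callsets: list[CallSet] = []
    for p in request.compare_paths:
        try:
            cs = _load_vcf_cached(Path(p), request.max_file_size)
            callsets.append(cs)
            log.load_outcomes[str(p)] = f"ok ({len(cs)} unique variants)"
        except InputError as exc:
            log.load_outcomes[str(p)] = "error"
            log.errors.append(str(exc))

    golden: GoldenSet | None = None
    if request.golden_paths:
        pooled: set = set()
        failed = False
        for p in request.golden_paths:
            try:
                pooled |= _load_vcf_cached(Path(p), request.max_file_size).variants
                log.load_outcomes[str(p)] = "ok (golden)"
            except InputError as exc:
                log.load_outcomes[str(p)] = "error"
                log.errors.append(str(exc))
                failed = True
        if not failed:
            golden = GoldenSet(variants=pooled)

    regions: RegionSet | None = None
    if request.region_paths:
        try:
            regions = vcf_io.read_bed(request.region_paths)
            for p in request.region_paths:
                log.load_outcomes[str(p)] = "ok (regions)"
            log.warnings.append(f"loaded {len(regions)} genomic regions")
        except InputError as exc:
            log.errors.append(str(exc))

    meta: MetadataTable | None = None
    if request.metadata_path is not None:
        try:
            meta = vcf_io.read_metadata(
                request.metadata_path, [cs.name for cs in callsets]
            )
            log.load_outcomes[str(request.metadata_path)] = "ok (metadata)"
        except InputError as exc:
            log.errors.append(str(exc))

    return callsets, golden, regions, meta


def _warn_disjoint_chroms(
    callsets: Sequence[CallSet],
    golden: GoldenSet | None,
    regions: RegionSet | None,
    log: RunLog,
) -> None:
    compare_chroms = {k.chrom for cs in callsets for k in cs.variants}
    if golden is not None and golden.variants:
        golden_chroms = {k.chrom for k in golden.variants}
        if compare_chroms and not (compare_chroms & golden_chroms):
            log.warnings.append(
                "compare-set and golden-set chromosome names are disjoint "
                "(chromosome matching is exact: 'chr1' != '1')"
            )
    if regions is not None and len(regions):
        if compare_chroms and not (compare_chroms & regions.chroms()):
            log.warnings.append(
                "compare-set and region chromosome names are disjoint "
                "(chromosome matching is exact: 'chr1' != '1')"
            )


def _apply_filters(
    callsets: list[CallSet], request: AnalysisRequest, regions: RegionSet | None,
    log: RunLog,
) -> list[CallSet]:
    out = []
    for cs in callsets:
        log.record_stage(cs.name, "loaded", len(cs))
        if request.pass_only:
            cs = filters.filter_pass(cs)
            log.record_stage(cs.name, "pass", len(cs))
        if request.region_mode is not None and regions is not None:
            cs = filters.filter_regions_sorted(cs, regions, request.region_mode)
            log.record_stage(cs.name, "regions", len(cs))
        if request.chroms:
            cs = filters.filter_chromosomes(cs, request.chroms)
            log.record_stage(cs.name, "chromosomes", len(cs))
        if request.vtype:
            cs = filters.filter_variant_type(cs, request.vtype)
            log.record_stage(cs.name, "variant_type", len(cs))
        out.append(cs)
    return out


def run(request: AnalysisRequest) -> RunLog:
    """Execute one analysis request; outputs land in ``request.output_dir``."""
    request.validate()
    log = RunLog()
    out_dir = Path(request.output_dir)

    callsets, golden, regions, meta = _load_inputs(request, log)
    if not log.ok:
        return log  # error report instead of analysis (fail before running)

    _warn_disjoint_chroms(callsets, golden, regions, log)
    callsets = _apply_filters(callsets, request, regions, log)

    groups: list[VariantGroup] | None = None
    if request.group_spec is not None and meta is not None:
        groups = grouping.make_groups(callsets, meta, request.group_spec)
    items: list = groups if groups is not None else callsets
    label_cols = list(request.group_spec.label_columns) if request.group_spec else []
    if groups is not None:
        named_sets = {
            grouping.group_label(g, label_cols): g.pooled.variants for g in groups
        }
    else:
        named_sets = {cs.name: cs.variants for cs in callsets}

    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        if request.analysis == "summary":
            counts = report.count_table(items)
            log.outputs.append(
                vcf_io.write_table_csv(counts, out_dir / "variant_counts.csv")
            )
            log.outputs.append(
                report.render_histogram(
                    counts, request.style, out_dir / "variant_counts.png"
                )
            )
            if request.pivot_spec is not None and groups is not None:
                pivot = report.pivot_counts(groups, request.pivot_spec)
                log.outputs.append(
                    vcf_io.write_table_csv(pivot, out_dir / "pivot_counts.csv")
                )
        elif request.analysis == "venn":
            if not (2 <= len(named_sets) <= 6):
                raise ArityError(
                    f"Venn analysis needs 2-6 sets after grouping, "
                    f"got {len(named_sets)}"
                )
            tally = setops.venn_tally(named_sets)
            log.outputs.append(
                report.render_venn(tally, request.style, out_dir / "venn.png")
            )
            log.outputs.append(out_dir / "venn.csv")
            common = setops.intersection_all(named_sets)
            log.outputs.append(
                vcf_io.write_variants_vcf(common, out_dir / "intersection.vcf.gz")
            )
        elif request.analysis == "clustergram":
            matrix = setops.jaccard_matrix(named_sets)
            order = setops.cluster_order(matrix)
            label_classes = None
            if meta is not None and request.style.color_by and groups is None:
                label_classes = [
                    meta.row(cs.name)[request.style.color_by] for cs in callsets
                ]
            log.outputs.append(
                report.render_clustergram(
                    matrix, order, request.style, out_dir / "clustergram.png",
                    label_classes=label_classes,
                )
            )
            log.outputs.append(out_dir / "clustergram.csv")
        elif request.analysis == "pr":
            assert golden is not None
            results = bench.benchmark_many(items, golden)
            if groups is not None and label_cols:
                for r, g in zip(results, groups):
                    r.name = grouping.group_label(g, label_cols)
            log.outputs.append(
                report.render_pr_plot(
                    results, meta, request.style, out_dir / "precision_recall.png"
                )
            )
            log.outputs.append(out_dir / "precision_recall.csv")
        elif request.analysis == "filter":
            for cs in callsets:
                dest = out_dir / f"{Path(cs.name).stem}.filtered.vcf.gz"
                log.outputs.append(
                    vcf_io.write_variants_vcf(
                        cs.variants, dest, filter_status=cs.filter_status
                    )
                )
    except (ArityError, SpecError, UndefinedScoreError) as exc:
        log.errors.append(str(exc))
    return log
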