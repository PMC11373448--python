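# Methods

## Variant identity and comparison model

All comparison in this package is set-based on an exact-match variant key
`(chrom, pos, ref, alt)`:

- `pos` is the 1-based VCF coordinate; `ref`/`alt` are uppercased on load;
  chromosome names are kept verbatim, so `chr1` and `1` never match (the
  pipeline warns when the compare set shares no chromosome name with the
  golden set or the region files).
- Multi-allelic records are split into one key per alternate allele; each
  split key carries the record's FILTER value.
- No normalization is performed: left-alignment, decomposition and
  genotype-aware or distance-tolerant matching are out of scope, so two
  different representations of the same indel count as different variants.
- A file's records are deduplicated to a set. When duplicate keys carry
  conflicting FILTER values, the first record wins (the choice is arbitrary
  but fixed; it only matters for malformed inputs).
- Records with ALT `.` (no alternate called) contribute no keys. Symbolic
  ALTs (`<DEL>`, breakends) are kept verbatim as strings; under the
  SNP/indel classifier below they fall where their string lengths put them.

VCF input may be plain text, generic GZip, or a Zip archive containing
exactly one member; containers are detected by magic bytes, not extension.
The reader is a line parser rather than an htslib wrapper because it must
accept generic-gzip streams and header-minimal files (a bare `#CHROM` line),
and because key construction is the package's central primitive. A per-file
size limit (default 200 MB) guards against accidental uploads of BAMs etc.

## Filters

Filters run in a fixed order — PASS, then genomic regions, then
chromosome/variant type — and each is a pure, idempotent subset operation.

- **PASS**: keeps variants whose FILTER is exactly `PASS`; `.` and empty are
  non-PASS.
- **Regions**: BED intervals are 0-based half-open; a variant is inside
  `(chrom, start, end)` iff the chromosome matches and `p − 1 ∈ [start, end)`.
  Only the anchor base at POS is tested — a deletion spanning a region
  boundary is classified by where its first reference base lies. Two
  implementations exist with an equivalence contract: an exhaustive
  per-variant scan, and a single-pass sweep over the two sorted streams that
  carries a per-chromosome running maximum of interval ends, which makes it
  correct for overlapping and nested intervals without pre-merging. The
  sweep is the one the pipeline uses; the scan is the test oracle.
- **Type**: `snp` keeps single-base A/C/G/T→A/C/G/T substitutions; `indel`
  keeps keys with `len(ref) ≠ len(alt)`. Balanced multi-base substitutions
  belong to neither class and are dropped by both.
- **Chromosome**: exact string membership in the requested list.

The golden set is never filtered; filters apply to the compare set only, so
benchmarking measures the filtered calls against the full truth set.

## Grouping

Groups are the distinct value tuples of the chosen metadata columns, ordered
by key tuple for deterministic output. Pooling is union, intersection, or
majority with a strict `> 50 %` threshold — in a group of 4, a variant in
exactly 2 members is excluded. Pooled sets drop FILTER status (grouping runs
after PASS filtering). Labels join the selected columns' values with `" & "`;
colliding labels after column subsetting are allowed but logged. For labeling
purposes the selected columns must be among the grouping columns, since only
those have a single value per group.

## Overlap accounting and similarity

`venn_tally` classifies every variant of the union into exactly one
membership pattern, encoded as a bitmask over the ordered set names, so the
2^k − 1 counts always sum to the union size. Similarity is the Jaccard index
`|A∩B| / |A∪B|`; it is undefined (an error, never a silent 0/0) when both
sets are empty, and the similarity matrix refuses empty sets by name.
Clustering is SciPy average-linkage (UPGMA) agglomeration on the distance
`1 − J`; equal-distance merges resolve by candidate index, i.e. input order,
so the leaf order is reproducible, and the same order is applied to heatmap
rows and columns.

## Venn rendering

Diagrams are drawn from fixed circle/ellipse layouts on a unit canvas:
circles for 2–3 sets, a four-ellipse arrangement for 4 sets, and a symmetric
five-ellipse arrangement (72° rotations, ellipse centers offset 0.15 from
the canvas center, axes 1.4 × 0.8, +30° twist) for 5 sets. Rather than
hand-placing 15–31 region labels, the layout is rasterized on a 500×500
grid, each grid point is assigned its membership bitmask from the ellipse
equations, and each region's label (count, with its percentage of the union
in parentheses) is placed at the centroid of its points. Rasterization also
verifies the 4- and 5-set layouts realize all 2^k − 1 regions. No 6-curve
ellipse diagram can realize all 63 regions, so the 6-set drawing is
inherently a pseudo-Venn: a ring of six ellipses labeling only the patterns
that have geometric area, with the complete 63-pattern tally always written
to the sibling CSV so no information is lost to the approximation. The
`pseudo_venn` style flag is accepted only for 6 sets.

## Benchmarking

Precision `|C∩G|/|C|` and recall `|C∩G|/|G|` are computed from exact key
intersections; results carry the raw counts (`n_correct`, `n_called`,
`n_golden`) so exported tables are self-auditing. Empty compare or golden
sets raise an error. Useful identities that the tests exercise: `C ⊆ G`
forces precision 1; `G ⊆ C` forces recall 1 (hence the recall-1.0 identity
when the golden set is the intersection of all compare files);
union-pooling a group can only keep or raise recall relative to its members,
intersection-pooling can only keep or lower it.

## Pipeline and outputs

One analysis request runs validate → load → PASS → regions → chrom/type →
group → analyze → export. All load errors are collected per file and, if any
input fails, no analysis stage runs — the run log carries the error report
instead. Parsed VCFs are cached in-process keyed by content hash. The run
log records per-file, per-stage variant tallies (monotone non-increasing
through the filter stages). Everything is deterministic: no randomness, GZip
output written with a pinned mtime, records sorted by key (chromosomes
lexicographically — no natural-order guessing), so identical requests
produce byte-identical CSVs and VCFs.

Figure styling: `color_by`/`shape_by` take metadata columns (shape only on
the precision–recall scatter; for grouped results the group label itself is
the style category), font size defaults to 12, heatmap palette defaults to
viridis. Every renderer writes a decodable PNG plus a CSV of its numbers.

## Synthetic data

`synth_vcfs` realizes a requested Venn pattern structure exactly: distinct
keys are sampled without replacement from (chr1–chr3) × positions 1..10^6 ×
ref≠alt ∈ {A,C,G,T}, assigned to membership patterns, and written per file
in sorted order, so the same seed yields byte-identical files. A JSON
manifest records every file's exact key set, making the true Venn tally,
Jaccard matrix and precision/recall against any designed golden subset
computable in closed form for tests. `filter_mix` marks exactly
`floor(n · f)` of a file's n variants non-PASS (`q10`), taken from the start
of the sorted key list. `synth_bed` returns the generated intervals'
enumerated 1-based coverage as an oracle for the region filters;
`synth_metadata` writes crossed designs (first column slowest). The
generators model structural overlap only — not allele frequencies, error
profiles, genotypes, clustered positions or realistic indel length
distributions — so passing tests demonstrate correctness of the set
algebra and plumbing, not robustness to messy real-world call sets.

Test and acceptance problem sizes (tens-to-hundreds of variants per file,
~1000 randomized region-filter instances) were chosen to exercise every
code path and boundary case while keeping the whole suite in seconds; all
the properties checked are size-invariant set identities.

## Known limitations

- No genotype or INFO awareness; no variant normalization; no
  distance-tolerant matching.
- Chromosome sort order is lexicographic (`chr10` < `chr2`), chosen for
  determinism over natural-order guessing.
- The 6-set diagram omits zero-area intersection patterns (see above).
- Region filtering anchors on POS only; REF spans crossing a region edge
  are not split.
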