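# vcfcompare

Set-based comparison, filtering, grouping and benchmarking of VCF files.

When several variant-calling pipelines (different aligners, callers or library
preparations) are run on the same sample, the resulting VCF files must be
compared to decide which pipeline to trust. `vcfcompare` reduces each file to
its set of exact-match variant identities — one key per
`(CHROM, POS, REF, ALT)` combination, with multi-allelic records split per
alternate allele — and then answers the questions practitioners actually ask:

- **How much do the files overlap?** Multi-set Venn tallies (2–6 sets) with
  counts and percentages, plus the all-sets intersection exported as a VCF.
- **Which files are similar?** Pairwise Jaccard index
  `J(A, B) = |A ∩ B| / |A ∪ B|`, rendered as a clustergram (heatmap with
  average-linkage dendrograms on distance `1 − J`).
- **Which pipeline is best?** Precision/recall against a trusted *golden set*
  `G`: for a call set `C`,

  ```
  precision = |C ∩ G| / |C|        recall = |C ∩ G| / |G|
  ```

  where a called variant is correct iff it has an exact key match in `G`.

Before analysis, call sets can be filtered by FILTER status (`PASS` only), by
genomic regions from BED files (keep inside or outside; a variant's 1-based
position `p` is inside a 0-based half-open interval `[start, end)` iff
`start < p ≤ end`), by variant type (SNP/indel) and by chromosome. Files can
also be grouped by a metadata CSV (keyed by a `FILENAME` column) and each
group's variants pooled by **union**, **intersection**, or **majority**
(present in strictly more than 50 % of the group's files).

Inputs may be plain, GZip- or Zip-compressed VCF text. Every figure (PNG) is
written alongside a CSV of its underlying numbers.

## Worked example

Generate four synthetic call sets with a known overlap structure and benchmark
them against the first one:

```sh
python - <<'PY'
from vcfcompare import OverlapDesign, synth_vcfs
design = OverlapDesign(
    set_names=("A", "B", "C", "D"),
    pattern_counts={("A","B","C","D"): 40, ("A","B"): 12, ("C","D"): 8,
                    ("A",): 5, ("B",): 4, ("C",): 3, ("D",): 6},
    filter_mix=0.2, seed=99)
synth_vcfs(design, "in")
PY
vcfcompare pr --compare in/A.vcf --compare in/B.vcf \
              --compare in/C.vcf --compare in/D.vcf \
              --golden in/A.vcf --out pr_out
cat pr_out/precision_recall.csv
```

```
name,precision,recall,n_correct,n_called,n_golden
A.vcf,1.0,1.0,57,57,57
B.vcf,0.9285714285714286,0.9122807017543859,52,56,57
C.vcf,0.7843137254901961,0.7017543859649122,40,51,57
D.vcf,0.7407407407407407,0.7017543859649122,40,54,57
```

`A.vcf` benchmarked against itself is perfect by definition. `B.vcf` shares
the designed 40-variant common core and 12 further variants with `A`, so 52 of
its 56 calls are correct (precision 0.93) and it recovers 52 of `A`'s 57
variants (recall 0.91). `C` and `D` share only the common core with `A`, so
both recall 40/57 ≈ 0.70. The scatter plot of these four points is in
`pr_out/precision_recall.png`.

The same inputs drive the other analyses:

```sh
vcfcompare venn        --compare in/A.vcf ... --out venn_out   # + intersection.vcf.gz
vcfcompare clustergram --compare in/A.vcf ... --out cg_out
vcfcompare summary     --compare in/A.vcf ... --out sum_out
vcfcompare filter      --compare in/A.vcf --pass-only --out filt_out
```

Metadata-driven grouping and styling (`--metadata meta.csv --group-by caller
--combine union --color-by caller --shape-by aligner`) work on every
subcommand; see `vcfcompare <subcommand> --help`.

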