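import random

import pytest

from vcfcompare import CallSet, VariantKey


def make_vcf(path, records, header=True, fileformat=True):
    """Write a small VCF from (chrom, pos, ref, alt, filter) tuples."""
    lines = []
    if fileformat:
        lines.append("##fileformat=VCFv4.2")
    if header:
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt, filt in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.")
    path.write_text("\n".join(lines) + "\n")
    return path


def random_keys(rng, n, chroms=("chr1", "chr2"), pos_max=500):
    """n distinct random variant keys on a small coordinate range."""
    slots = rng.sample(range(len(chroms) * pos_max), n)
    keys = []
    for s in slots:
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        keys.append(VariantKey(chroms[s // pos_max], s % pos_max + 1, ref, alt))
    return keys


@pytest.fixture
def rng():
    return random.Random(20240903)


@pytest.fixture
def callset_pair():
    shared = {VariantKey("chr1", i, "A", "G") for i in range(100, 110)}
    only_a = {VariantKey("chr1", i, "C", "T") for i in range(200, 205)}
    only_b = {VariantKey("chr2", i, "G", "C") for i in range(300, 303)}
    a = CallSet("a.vcf", shared | only_a)
    b = CallSet("b.vcf", shared | only_b)
    return a, b, shared, only_a, only_b
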