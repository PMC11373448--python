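"""Reading/writing VCF, BED and metadata CSV, including compression."""

import gzip
import zipfile

import pandas as pd
import pytest

from vcfcompare import (
    CallSet,
    VariantKey,
    read_bed,
    read_golden,
    read_metadata,
    read_vcf,
    write_table_csv,
    write_variants_vcf,
)
from vcfcompare.errors import (
    BedFormatError,
    DecompressionError,
    FileSizeError,
    MetadataError,
    VcfFormatError,
)
from conftest import make_vcf


class TestReadVcf:
    def test_basic_parse_keeps_keys_and_filters(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [
            ("chr1", 100, "A", "G", "PASS"),
            ("chr1", 200, "C", "T", "q10"),
        ])
        cs = read_vcf(p)
        assert cs.name == "x.vcf"
        assert cs.variants == {
            VariantKey("chr1", 100, "A", "G"),
            VariantKey("chr1", 200, "C", "T"),
        }
        assert cs.filter_status[VariantKey("chr1", 100, "A", "G")] == "PASS"
        assert cs.filter_status[VariantKey("chr1", 200, "C", "T")] == "q10"

    def test_multiallelic_alt_splits_per_allele(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [("chr2", 50, "A", "G,T", "PASS")])
        cs = read_vcf(p)
        assert cs.variants == {
            VariantKey("chr2", 50, "A", "G"),
            VariantKey("chr2", 50, "A", "T"),
        }
        assert all(v == "PASS" for v in cs.filter_status.values())

    def test_ref_alt_uppercased_chrom_verbatim(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [("Chr1", 10, "a", "g", "PASS")])
        cs = read_vcf(p)
        assert cs.variants == {VariantKey("Chr1", 10, "A", "G")}

    def test_duplicate_records_deduplicated_first_filter_wins(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [
            ("chr1", 5, "A", "G", "PASS"),
            ("chr1", 5, "A", "G", "q10"),
        ])
        cs = read_vcf(p)
        assert len(cs) == 1
        assert cs.filter_status[VariantKey("chr1", 5, "A", "G")] == "PASS"

    def test_monomorphic_alt_dot_contributes_no_key(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [
            ("chr1", 5, "A", ".", "PASS"),
            ("chr1", 9, "A", "T", "PASS"),
        ])
        assert len(read_vcf(p)) == 1

    def test_symbolic_alt_kept_verbatim(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [("chr1", 5, "A", "<DEL>", "PASS")])
        assert read_vcf(p).variants == {VariantKey("chr1", 5, "A", "<DEL>")}

    @pytest.mark.parametrize("container", ["plain", "gzip", "zip"])
    def test_compression_transparency(self, tmp_path, container):
        plain = make_vcf(tmp_path / "x.vcf", [
            ("chr1", 100, "A", "G", "PASS"),
            ("chr2", 7, "C", "T", "."),
        ])
        expected = read_vcf(plain)
        if container == "plain":
            path = plain
        elif container == "gzip":
            path = tmp_path / "x.vcf.gz"
            path.write_bytes(gzip.compress(plain.read_bytes()))
        else:
            path = tmp_path / "x.vcf.zip"
            with zipfile.ZipFile(path, "w") as zf:
                zf.write(plain, "x.vcf")
        got = read_vcf(path)
        assert got.variants == expected.variants
        assert got.filter_status == expected.filter_status

    def test_multi_member_zip_rejected(self, tmp_path):
        plain = make_vcf(tmp_path / "x.vcf", [("chr1", 1, "A", "G", "PASS")])
        path = tmp_path / "two.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.write(plain, "a.vcf")
            zf.write(plain, "b.vcf")
        with pytest.raises(DecompressionError, match="exactly one"):
            read_vcf(path)

    def test_missing_header_names_file(self, tmp_path):
        p = make_vcf(tmp_path / "bad.vcf", [("chr1", 1, "A", "G", "PASS")],
                     header=False, fileformat=False)
        with pytest.raises(VcfFormatError, match="bad.vcf"):
            read_vcf(p)

    @pytest.mark.parametrize("record,msg", [
        (("chr1", "xx", "A", "G", "PASS"), "POS"),
        (("chr1", 0, "A", "G", "PASS"), "POS"),
        (("chr1", 5, ".", "G", "PASS"), "REF"),
    ])
    def test_bad_record_fields_raise_with_line(self, tmp_path, record, msg):
        p = make_vcf(tmp_path / "bad.vcf", [record])
        with pytest.raises(VcfFormatError, match=msg):
            read_vcf(p)

    def test_size_limit_enforced(self, tmp_path):
        p = make_vcf(tmp_path / "x.vcf", [("chr1", 1, "A", "G", "PASS")])
        with pytest.raises(FileSizeError):
            read_vcf(p, max_size=10)


class TestGoldenAndRoundTrip:
    def test_golden_union_of_files(self, tmp_path):
        a = make_vcf(tmp_path / "a.vcf", [("chr1", 1, "A", "G", "PASS"),
                                          ("chr1", 2, "C", "T", "PASS")])
        b = make_vcf(tmp_path / "b.vcf", [("chr1", 2, "C", "T", "q10"),
                                          ("chr1", 3, "G", "A", "PASS")])
        g = read_golden([a, b])
        assert len(g) == 3

    def test_empty_path_list_gives_empty_golden(self):
        assert len(read_golden([])) == 0

    def test_write_read_round_trip_sorted_gzip(self, tmp_path, rng):
        from conftest import random_keys
        keys = set(random_keys(rng, 40))
        out = tmp_path / "out.vcf.gz"
        write_variants_vcf(keys, out)
        with gzip.open(out, "rt") as fh:
            body = [l.split("\t")[:2] for l in fh if not l.startswith("#")]
        assert body == sorted(body, key=lambda r: (r[0], int(r[1])))  # sorted records
        assert read_vcf(out).variants == keys

    def test_empty_set_writes_valid_header_only_vcf(self, tmp_path):
        out = write_variants_vcf(set(), tmp_path / "empty.vcf.gz")
        assert read_vcf(out).variants == set()


class TestBed:
    def test_pooled_sorted_intervals(self, tmp_path):
        (tmp_path / "a.bed").write_text("chr2\t10\t20\nchr1\t99\t200\n")
        (tmp_path / "b.bed").write_text("chr1\t5\t9\nchr1\t0\t4\nchr3\t1\t2\n")
        rs = read_bed([tmp_path / "a.bed", tmp_path / "b.bed"])
        assert len(rs) == 5
        assert rs.intervals == sorted(rs.intervals)
        assert rs.intervals[0] == ("chr1", 0, 4)

    @pytest.mark.parametrize("line", ["chr1\tx\t10", "chr1\t10\t10", "chr1\t10"])
    def test_malformed_bed_raises_with_line_number(self, tmp_path, line):
        (tmp_path / "bad.bed").write_text("chr1\t0\t5\n" + line + "\n")
        with pytest.raises(BedFormatError, match=":2"):
            read_bed([tmp_path / "bad.bed"])


class TestMetadata:
    def _write(self, tmp_path, text):
        p = tmp_path / "meta.csv"
        p.write_text(text)
        return p

    def test_property_columns_discoverable(self, tmp_path):
        p = self._write(tmp_path,
                        "FILENAME,aligner,caller\n"
                        "a.vcf,BWA,HC\nb.vcf,BWA,VS\nc.vcf,Bowtie2,HC\nd.vcf,Bowtie2,VS\n")
        table = read_metadata(p, ["a.vcf", "b.vcf", "c.vcf", "d.vcf"])
        assert table.property_columns == ["aligner", "caller"]
        assert table.row("c.vcf") == {"aligner": "Bowtie2", "caller": "HC"}

    def test_missing_filename_column_is_schema_error(self, tmp_path):
        p = self._write(tmp_path, "file,aligner\na.vcf,BWA\n")
        with pytest.raises(MetadataError, match="FILENAME"):
            read_metadata(p)

    def test_uncovered_compare_file_named_in_error(self, tmp_path):
        p = self._write(tmp_path, "FILENAME,x\na.vcf,1\nb.vcf,2\nc.vcf,3\n")
        with pytest.raises(MetadataError, match="d.vcf"):
            read_metadata(p, ["a.vcf", "b.vcf", "c.vcf", "d.vcf"])

    def test_duplicate_filenames_are_schema_error(self, tmp_path):
        p = self._write(tmp_path, "FILENAME,x\na.vcf,1\na.vcf,2\n")
        with pytest.raises(MetadataError, match="duplicate"):
            read_metadata(p)


class TestTableCsv:
    def test_lossless_round_trip_with_commas_in_labels(self, tmp_path):
        df = pd.DataFrame(
            {"name": ["x, y", "plain"], "count": [3, 5]},
        )
        path = write_table_csv(df, tmp_path / "t.csv")
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["name", "count"])
        path = write_table_csv(df, tmp_path / "t.csv")
        assert path.read_text().strip() == "name,count"
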