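"""VCF and GTF conversion: schema generation, record parsing, two-pass
type inference, fidelity against an independent parser, Ts/Tv counting."""

import gzip
import hashlib
import math
import os
import textwrap

import pytest

import wormtable as wt
from wormtable import (
    ConversionError,
    MISSING,
    VARIABLE,
    ColumnSpec,
    ColumnType,
    Schema,
)
from wormtable.converters import classify_substitution, parse_vcf_header

from conftest import build_table

HEADER = [
    "##fileformat=VCFv4.1",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    '##INFO=<ID=DB,Number=0,Type=Flag,Description="In dbSNP">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2",
]


def test_header_parsing():
    info, fmt, samples = parse_vcf_header(HEADER)
    assert [d.id for d in info] == ["DP", "AF", "DB"]
    assert info[1].number == "A" and info[1].vtype == "Float"
    assert [d.id for d in fmt] == ["GT"]
    assert samples == ["NA1", "NA2"]


def test_header_to_schema_mappings():
    schema = wt.vcf_header_to_schema(HEADER)
    assert schema.names[:7] == (
        "CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER"
    )
    dp = schema.spec("INFO.DP")
    assert dp.ctype is ColumnType.INT and dp.num_elements == 1
    af = schema.spec("INFO.AF")
    assert af.ctype is ColumnType.FLOAT and af.is_variable
    db = schema.spec("INFO.DB")
    assert db.ctype is ColumnType.UINT and db.element_size == 1
    assert "NA1.GT" in schema and "NA2.GT" in schema
    assert schema.spec("QUAL").element_size == 4


def test_header_without_chrom_line_rejected():
    with pytest.raises(ConversionError, match="#CHROM"):
        wt.vcf_header_to_schema(HEADER[:-1])


def test_parse_record_worked_example():
    schema = wt.vcf_header_to_schema(HEADER[:4] + [HEADER[-1][:-8]])
    line = "2L\t5000\t.\tA\tG\t31.5\tPASS\tDP=10"
    values = dict(zip(schema.names, wt.parse_vcf_record(line, schema)))
    assert values["CHROM"] == "2L"
    assert values["POS"] == 5000
    assert values["ID"] is MISSING
    assert values["REF"] == "A"
    assert values["ALT"] == ("G",)
    assert values["QUAL"] == 31.5
    assert values["FILTER"] == "PASS"
    assert values["INFO.DP"] == 10
    assert values["INFO.AF"] is MISSING
    assert values["INFO.DB"] is MISSING  # absent flag


def test_parse_record_splits_and_missing():
    schema = wt.vcf_header_to_schema(HEADER)
    line = "2L\t1\t.\tA\tG,T\t.\t.\tDP=.;AF=0.5,0.25;DB\tGT\t0/1\t."
    values = dict(zip(schema.names, wt.parse_vcf_record(line, schema)))
    assert values["ALT"] == ("G", "T")
    assert values["QUAL"] is MISSING
    assert values["FILTER"] is MISSING
    assert values["INFO.DP"] is MISSING
    assert values["INFO.AF"] == (0.5, 0.25)
    assert values["INFO.DB"] == 1  # present flag
    assert values["NA1.GT"] == "0/1"
    assert values["NA2.GT"] is MISSING


def test_parse_record_field_count_checked():
    schema = wt.vcf_header_to_schema(HEADER)
    with pytest.raises(ConversionError, match="line 7"):
        wt.parse_vcf_record("2L\t1\t.\tA", schema, line_number=7)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


SMALL_VCF = "\n".join(HEADER[:4] + [
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    "2L\t5000\t.\tA\tG\t31.5\tPASS\tDP=10",
    "2L\t6000\trs1\tC\tT\t11.2\tPASS\tDP=200;AF=0.5;DB",
    "2R\t100\t.\tAT\tA\t.\tq10\tDP=3",
]) + "\n"


def test_vcf_two_pass_smallest_types(tmp_path):
    path = _write(tmp_path, "s.vcf", SMALL_VCF)
    t = wt.vcf_to_table(path, tmp_path / "s.wt")
    # max DP 200 fits one unsigned byte; max POS 6000 needs two
    dp = t.schema.spec("INFO.DP")
    assert dp.ctype is ColumnType.UINT and dp.element_size == 1
    pos = t.schema.spec("POS")
    assert pos.ctype is ColumnType.UINT and pos.element_size == 2
    assert t.num_rows == 3
    assert t.get_row(0)[:5] == ("2L", 5000, MISSING, "A", "G")
    assert t.get_row(1)[t.schema.position("INFO.DB")] == 1
    t.close()


def test_vcf_single_pass_default_sizes(tmp_path):
    path = _write(tmp_path, "s.vcf", SMALL_VCF)
    t = wt.vcf_to_table(path, tmp_path / "s.wt", single_pass=True)
    assert t.schema.spec("INFO.DP").element_size == 8
    assert t.num_rows == 3
    t.close()


def test_gzip_input_gives_identical_table_bytes(tmp_path):
    plain = _write(tmp_path, "s.vcf", SMALL_VCF)
    gz = tmp_path / "s.vcf.gz"
    with gzip.open(gz, "wt") as f:
        f.write(SMALL_VCF)
    t1 = wt.vcf_to_table(plain, tmp_path / "a.wt")
    t2 = wt.vcf_to_table(gz, tmp_path / "b.wt")
    for name in ("rows.dat", "schema.xml"):
        h1 = hashlib.sha256(
            open(os.path.join(t1.directory, name), "rb").read()
        ).digest()
        h2 = hashlib.sha256(
            open(os.path.join(t2.directory, name), "rb").read()
        ).digest()
        assert h1 == h2
    t1.close()
    t2.close()


def test_undeclared_info_key_becomes_char_column(tmp_path):
    text = SMALL_VCF.replace("DP=3", "DP=3;XX=hello")
    t = wt.vcf_to_table(
        _write(tmp_path, "s.vcf", text), tmp_path / "s.wt"
    )
    spec = t.schema.spec("INFO.XX")
    assert spec.ctype is ColumnType.CHAR and spec.is_variable
    assert t.get_row(2)[t.schema.position("INFO.XX")] == "hello"
    t.close()


def test_toy_vcf_fidelity_against_cyvcf2(toy_vcf_path, toy_table):
    """Converted rows agree field-for-field with an independent VCF parser
    reading the same file."""
    cyvcf2 = pytest.importorskip("cyvcf2")
    t = toy_table
    names = list(t.schema.names)
    records = list(cyvcf2.VCF(str(toy_vcf_path)))
    assert t.num_rows == len(records)
    for row, rec in zip(t.cursor(names), records):
        v = dict(zip(names, row))
        assert v["CHROM"] == rec.CHROM
        assert v["POS"] == rec.POS
        assert v["ID"] == rec.ID or (v["ID"] is MISSING and rec.ID is None)
        assert v["REF"] == rec.REF
        assert v["ALT"] == ",".join(rec.ALT)
        if rec.QUAL is None:
            assert v["QUAL"] is MISSING
        else:
            assert math.isclose(v["QUAL"], rec.QUAL, rel_tol=1e-6)
        dp = rec.INFO.get("DP")
        assert v["INFO.DP"] == dp or (dp is None and v["INFO.DP"] is MISSING)
        if rec.INFO.get("DB") is not None:
            assert v["INFO.DB"] == 1


# -- GTF ---------------------------------------------------------------------


def test_gtf_record_parsing():
    line = (
        "2L\ttoy\texon\t100\t200\t.\t+\t.\t"
        'gene_id "FBgn0000001"; transcript_id "FBtr0000001";'
    )
    rec = wt.parse_gtf_record(line)
    assert rec["gene_id"] == "FBgn0000001"
    assert rec["transcript_id"] == "FBtr0000001"
    assert rec["score"] is MISSING
    assert (rec["start"], rec["end"]) == (100, 200)


@pytest.mark.parametrize(
    "line, match",
    [
        ("2L\ttoy\texon\t100\t200\t.\t+\t.", "9 tab-separated"),
        ("2L\ttoy\texon\t300\t200\t.\t+\t.\tgene_id \"g\";", "start"),
    ],
)
def test_gtf_bad_lines_rejected(line, match):
    with pytest.raises(ConversionError, match=match):
        wt.parse_gtf_record(line, line_number=3)


def test_gtf_conversion(tmp_path):
    text = wt.generate_toy_gtf(wt.FixtureConfig(seed=2, num_rows=30))
    path = _write(tmp_path, "toy.gtf", text)
    t = wt.gtf_to_table(path, tmp_path / "g.wt")
    data_lines = [
        l for l in text.splitlines() if l and not l.startswith("#")
    ]
    assert t.num_rows == len(data_lines)
    for row, line in zip(t, data_lines):
        fields = line.split("\t")
        v = dict(zip(t.schema.names, row))
        assert v["seqname"] == fields[0]
        assert v["feature"] == fields[2]
        assert (v["start"], v["end"]) == (int(fields[3]), int(fields[4]))
        assert v["strand"] == fields[6]
        assert v["attributes"] == fields[8]
    t.close()


# -- transitions / transversions ---------------------------------------------


@pytest.mark.parametrize(
    "ref, alt, expected",
    [("A", "G", "ts"), ("G", "A", "ts"), ("C", "T", "ts"), ("T", "C", "ts"),
     ("A", "C", "tv"), ("G", "T", "tv"), ("a", "g", "ts"),
     ("AT", "A", None), ("A", "<DEL>", None), ("A", "AG", None)],
)
def test_classify_substitution(ref, alt, expected):
    assert classify_substitution(ref, alt) == expected


TSTV_SCHEMA = Schema((
    ColumnSpec("REF", ColumnType.CHAR, 1, VARIABLE),
    ColumnSpec("ALT", ColumnType.CHAR, 1, VARIABLE),
))


def test_ts_tv_hand_classified_fixture(tmp_path):
    """(A,G),(C,T) transitions; (A,C),(G,T) transversions; (T,C) transition
    -> (3, 2) by the purine/pyrimidine rule."""
    rows = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("T", "C")]
    t = build_table(tmp_path / "t.wt", TSTV_SCHEMA, rows)
    assert wt.count_transitions_transversions(t) == (3, 2)
    t.close()


def test_ts_tv_multiallelic_and_empty(tmp_path):
    t = build_table(tmp_path / "m.wt", TSTV_SCHEMA, [("A", "G,C")])
    assert wt.count_transitions_transversions(t) == (1, 1)
    t.close()
    t = build_table(tmp_path / "e.wt", TSTV_SCHEMA, [])
    assert wt.count_transitions_transversions(t) == (0, 0)
    t.close()


def test_ts_tv_scan_and_index_routes_agree(toy_table):
    scan = wt.count_transitions_transversions(toy_table)
    if "REF+ALT" not in toy_table.indexes:
        index = wt.build_index(toy_table, wt.IndexSpec(("REF", "ALT")))
    else:
        index = toy_table.open_index("REF+ALT")
    assert wt.count_ts_tv_from_index(index) == scan
    assert scan[0] > 0 and scan[1] > 0
    index.close()
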