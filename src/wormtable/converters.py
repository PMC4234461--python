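"""Converters from VCF and GTF text to tables, plus the transition /
transversion scan that exercises them.

The VCF converter works in two passes: the first pass accumulates
per-column statistics (integer extrema, string lengths, element counts),
the second builds the table using the smallest column type that covers the
observed values.  A single-pass mode with conservative default sizes is
available for very large inputs.

Column naming is flat and dot-separated: the seven fixed VCF fields keep
their names (CHROM, POS, ID, REF, ALT, QUAL, FILTER), INFO fields become
``INFO.<ID>`` and per-sample genotype fields become ``<sample>.<ID>``.
Multi-valued string fields (ALT above all) are stored as the comma-joined
text, matching how they appear in the source file; multi-valued numeric
fields are stored as variable-count element tuples.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass

from .errors import ConversionError, SchemaError
from .schema import (
    MISSING,
    VARIABLE,
    ColumnSpec,
    ColumnStats,
    ColumnType,
    Schema,
    infer_column_spec,
)
from .table import Table, create_table

_FIXED_FIELDS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER")

_META_RE = re.compile(r"^##(INFO|FORMAT)=<(.*)>\s*$")
_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class VcfFieldDef:
    """One ``##INFO`` or ``##FORMAT`` header definition."""

    id: str
    number: object  # int, or one of "A", "G", "R", "."
    vtype: str      # Integer | Float | Flag | String | Character
    scope: str      # INFO | FORMAT


def _split_meta_fields(body: str):
    """Split ``ID=DP,Number=1,Type=Integer,Description="a, b"`` on commas
    that are not inside a quoted string."""
    parts, buf, quoted = [], [], False
    for ch in body:
        if ch == '"':
            quoted = not quoted
            buf.append(ch)
        elif ch == "," and not quoted:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if buf:
        parts.append("".join(buf))
    out = {}
    for part in parts:
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip().strip('"')
    return out


def parse_vcf_header(header_lines):
    """Return (info defs, format defs, sample names) from the meta lines
    and the ``#CHROM`` column line."""
    info, fmt = [], []
    samples = None
    for line in header_lines:
        line = line.rstrip("\n")
        m = _META_RE.match(line)
        if m:
            scope = m.group(1)
            fields = _split_meta_fields(m.group(2))
            fid = fields.get("ID")
            if fid is None:
                raise ConversionError(f"header line missing ID: {line!r}")
            number = fields.get("Number", ".")
            if number not in ("A", "G", "R", "."):
                try:
                    number = int(number)
                except ValueError:
                    raise ConversionError(
                        f"bad Number={number!r} for {scope} field {fid}"
                    ) from None
            vtype = fields.get("Type", "String")
            if vtype == "Flag" and scope != "INFO":
                raise ConversionError(
                    f"Flag type is only valid for INFO fields ({fid})"
                )
            (info if scope == "INFO" else fmt).append(
                VcfFieldDef(fid, number, vtype, scope)
            )
        elif line.startswith("#CHROM"):
            cols = line.lstrip("#").split("\t")
            samples = cols[9:] if len(cols) > 9 else []
    if samples is None:
        raise ConversionError("VCF header has no #CHROM column line")
    ids = [d.id for d in info]
    if len(ids) != len(set(ids)):
        raise SchemaError("duplicate INFO field ids in VCF header")
    return info, fmt, samples


def _field_column_name(d: VcfFieldDef, sample: str | None = None) -> str:
    return f"INFO.{d.id}" if d.scope == "INFO" else f"{sample}.{d.id}"


def _default_field_spec(name: str, d: VcfFieldDef, float_size: int) -> ColumnSpec:
    """Column spec for a header field without observed statistics."""
    if d.vtype == "Flag":
        return ColumnSpec(name, ColumnType.UINT, 1, 1)
    n = d.number if isinstance(d.number, int) and d.number > 0 else VARIABLE
    if d.vtype == "Integer":
        return ColumnSpec(name, ColumnType.INT, 8, n)
    if d.vtype == "Float":
        return ColumnSpec(name, ColumnType.FLOAT, float_size, n)
    return ColumnSpec(name, ColumnType.CHAR, 1, VARIABLE)


def _inferred_field_spec(
    name: str, d: VcfFieldDef, stats: ColumnStats, float_size: int
) -> ColumnSpec:
    if d.vtype == "Flag":
        return ColumnSpec(name, ColumnType.UINT, 1, 1)
    if d.vtype == "Float":
        n = d.number if isinstance(d.number, int) and d.number > 0 else VARIABLE
        return ColumnSpec(name, ColumnType.FLOAT, float_size, n)
    hint = "int" if d.vtype == "Integer" else "char"
    spec = infer_column_spec(name, hint, stats)
    if d.vtype in ("String", "Character") and not spec.is_variable:
        # keep text fields variable: cheap, and robust to later edits
        spec = ColumnSpec(name, ColumnType.CHAR, 1, VARIABLE)
    return spec


def vcf_header_to_schema(
    header_lines,
    sample_names=None,
    stats: dict | None = None,
    float_size: int = 4,
    extra_info_ids=(),
) -> Schema:
    """Build the table schema for a VCF file.

    Fixed fields come first (CHROM, POS, ID, REF, ALT, QUAL, FILTER), then
    one column per INFO definition, then one column per sample x FORMAT
    definition.  ``stats`` (column name -> :class:`ColumnStats`) enables
    smallest-type inference for POS and integer/text fields; without it,
    conservative defaults are used (8-byte integers, variable text).
    ``extra_info_ids`` adds variable-char columns for INFO keys seen in the
    data but absent from the header.
    """
    info, fmt, samples = parse_vcf_header(header_lines)
    if sample_names is not None:
        samples = list(sample_names)

    def stat(name):
        return stats.get(name) if stats else None

    cols = [
        ColumnSpec("CHROM", ColumnType.CHAR, 1, VARIABLE),
    ]
    pos_stats = stat("POS")
    if pos_stats is not None and pos_stats.n_values:
        spec = infer_column_spec("POS", "int", pos_stats)
    else:
        spec = ColumnSpec("POS", ColumnType.UINT, 8, 1)
    cols.append(spec)
    cols += [
        ColumnSpec("ID", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("REF", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("ALT", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("QUAL", ColumnType.FLOAT, float_size, 1),
        ColumnSpec("FILTER", ColumnType.CHAR, 1, VARIABLE),
    ]
    for d in info:
        name = _field_column_name(d)
        s = stat(name)
        if s is not None:
            cols.append(_inferred_field_spec(name, d, s, float_size))
        else:
            cols.append(_default_field_spec(name, d, float_size))
    for fid in extra_info_ids:
        cols.append(ColumnSpec(f"INFO.{fid}", ColumnType.CHAR, 1, VARIABLE))
    for sample in samples:
        for d in fmt:
            name = _field_column_name(d, sample)
            s = stat(name)
            if s is not None:
                cols.append(_inferred_field_spec(name, d, s, float_size))
            else:
                cols.append(_default_field_spec(name, d, float_size))
    return Schema(tuple(cols))


# -- record parsing ----------------------------------------------------------


def _parse_info_field(raw: str) -> dict:
    """INFO column text -> {key: string value or True for bare flags}."""
    out = {}
    if raw in (".", ""):
        return out
    for item in raw.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = True
    return out


def _convert_scalar(spec: ColumnSpec, text: str, line_number=None):
    if text == ".":
        return MISSING
    try:
        if spec.ctype in (ColumnType.UINT, ColumnType.INT):
            return int(text)
        if spec.ctype is ColumnType.FLOAT:
            return float(text)
    except ValueError:
        raise ConversionError(
            f"column {spec.name!r}: cannot parse {text!r} as a number",
            line_number,
        ) from None
    return text


def _convert_cell(spec: ColumnSpec, text, line_number=None):
    """Convert raw VCF field text to a cell value for ``spec``."""
    if text is MISSING or text == ".":
        return MISSING
    if text is True:  # bare INFO flag (or undeclared bare key)
        return "1" if spec.ctype is ColumnType.CHAR else 1
    if spec.ctype is ColumnType.CHAR:
        return text
    if spec.num_elements == 1 and not spec.is_variable:
        return _convert_scalar(spec, text, line_number)
    vals = tuple(
        _convert_scalar(spec, part, line_number) for part in text.split(",")
    )
    return vals


def parse_vcf_record(line: str, schema: Schema, line_number=None):
    """Parse one data line into a value tuple matching ``schema``.

    '.' becomes MISSING wherever VCF permits it; ALT is returned as a
    tuple of allele strings; multi-valued numeric fields become tuples;
    INFO flags map to 1 when present and MISSING when absent.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise ConversionError(
            f"expected at least 8 tab-separated fields, got {len(fields)}",
            line_number,
        )
    info = _parse_info_field(fields[7])
    fmt_ids = fields[8].split(":") if len(fields) > 8 else []
    sample_fields = fields[9:]

    values = []
    for spec in schema.columns:
        name = spec.name
        if name == "CHROM":
            values.append(fields[0] if fields[0] != "." else MISSING)
        elif name == "POS":
            values.append(_convert_scalar(spec, fields[1], line_number))
        elif name == "ID":
            values.append(MISSING if fields[2] == "." else fields[2])
        elif name == "REF":
            values.append(MISSING if fields[3] == "." else fields[3])
        elif name == "ALT":
            values.append(
                MISSING if fields[4] == "." else tuple(fields[4].split(","))
            )
        elif name == "QUAL":
            values.append(_convert_scalar(spec, fields[5], line_number))
        elif name == "FILTER":
            values.append(MISSING if fields[6] == "." else fields[6])
        elif name.startswith("INFO."):
            raw = info.get(name[5:], MISSING)
            values.append(_convert_cell(spec, raw, line_number))
        else:
            sample, _, fid = name.partition(".")
            # sample columns follow the FORMAT declaration of this line
            try:
                si = _sample_position(schema, sample)
            except KeyError:
                raise SchemaError(f"unrecognised column {name!r}") from None
            raw = MISSING
            if fid in fmt_ids and si < len(sample_fields):
                parts = sample_fields[si].split(":")
                j = fmt_ids.index(fid)
                if j < len(parts):
                    raw = parts[j]
            values.append(_convert_cell(spec, raw, line_number))
    return tuple(values)


def _sample_position(schema: Schema, sample: str) -> int:
    """0-based position of ``sample`` among the schema's sample columns."""
    cache = getattr(schema, "_sample_order", None)
    if cache is None:
        order = []
        for c in schema.columns:
            if c.name in _FIXED_FIELDS or c.name.startswith("INFO."):
                continue
            s = c.name.partition(".")[0]
            if s not in order:
                order.append(s)
        cache = {s: i for i, s in enumerate(order)}
        object.__setattr__(schema, "_sample_order", cache)
    return cache[sample]


def _row_from_cells(schema: Schema, cells):
    """Adapt parsed cells to codec values: char columns holding a tuple of
    strings (ALT) are stored as the comma-joined text."""
    out = []
    for spec, v in zip(schema.columns, cells):
        if (
            spec.ctype is ColumnType.CHAR
            and isinstance(v, (tuple, list))
        ):
            v = ",".join(v)
        out.append(v)
    return tuple(out)


# -- file-level conversion ---------------------------------------------------


def _open_text(path):
    f = open(path, "rb")
    magic = f.read(2)
    f.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(f, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_vcf_header(fh):
    header = []
    for line in fh:
        if line.startswith("#"):
            header.append(line)
            if line.startswith("#CHROM"):
                return header
        else:
            raise ConversionError("data line before #CHROM header line")
    raise ConversionError("VCF header has no #CHROM column line")


def _accumulate_vcf_stats(path, header_lines):
    """Pass 1: per-column stats plus INFO keys absent from the header."""
    info, fmt, samples = parse_vcf_header(header_lines)
    known_info = {d.id for d in info}
    extra_info = []
    stats: dict = {}

    def st(name):
        s = stats.get(name)
        if s is None:
            s = stats[name] = ColumnStats()
        return s

    defs = {f"INFO.{d.id}": d for d in info}
    for sample in samples:
        for d in fmt:
            defs[_field_column_name(d, sample)] = d

    n_rows = 0
    with _open_text(path) as fh:
        line_number = 0
        for line in fh:
            line_number += 1
            if line.startswith("#"):
                continue
            n_rows += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ConversionError(
                    f"expected at least 8 fields, got {len(fields)}",
                    line_number,
                )
            st("POS").observe_int(int(fields[1]))
            st("POS").observe_count(1)
            info_dict = _parse_info_field(fields[7])
            for k in info_dict:
                if k not in known_info and k not in extra_info:
                    extra_info.append(k)
            fmt_ids = fields[8].split(":") if len(fields) > 8 else []
            for name, d in defs.items():
                s = st(name)
                if d.scope == "INFO":
                    raw = info_dict.get(d.id, MISSING)
                else:
                    sample = name.partition(".")[0]
                    si = samples.index(sample)
                    raw = MISSING
                    if d.id in fmt_ids and 9 + si < len(fields):
                        parts = fields[9 + si].split(":")
                        j = fmt_ids.index(d.id)
                        if j < len(parts):
                            parts_j = parts[j]
                            raw = parts_j
                _observe_vcf_value(s, d, raw, line_number)
    return stats, extra_info, n_rows


def _observe_vcf_value(s: ColumnStats, d: VcfFieldDef, raw, line_number):
    if raw is MISSING or raw == ".":
        s.observe_missing()
        return
    if d.vtype == "Flag":
        s.observe_int(1)
        return
    parts = raw.split(",") if isinstance(raw, str) else ["1"]
    if d.vtype == "Integer":
        n = 0
        for p in parts:
            if p == ".":
                s.observe_missing()
                continue
            try:
                s.observe_int(int(p))
            except ValueError:
                try:
                    float(p)
                except ValueError:
                    raise ConversionError(
                        f"field {d.id}: cannot parse {p!r}", line_number
                    ) from None
                s.observe_float(float(p))
            n += 1
        if n:
            s.observe_count(n)
    elif d.vtype == "Float":
        n = 0
        for p in parts:
            if p == ".":
                s.observe_missing()
                continue
            s.observe_float(float(p))
            n += 1
        if n:
            s.observe_count(n)
    else:
        s.observe_str(raw)
        s.observe_count(1)


def vcf_to_table(
    vcf_path,
    out_dir,
    single_pass: bool = False,
    float_size: int = 4,
) -> Table:
    """Convert a VCF 4.x file (plain or gzip) to a table.

    Row order equals file order.  By default a first pass over the data
    chooses the smallest integer sizes and discovers undeclared INFO keys;
    ``single_pass=True`` skips it and uses conservative defaults.
    """
    with _open_text(vcf_path) as fh:
        header_lines = _read_vcf_header(fh)
    if single_pass:
        schema = vcf_header_to_schema(header_lines, float_size=float_size)
    else:
        stats, extra_info, _ = _accumulate_vcf_stats(vcf_path, header_lines)
        schema = vcf_header_to_schema(
            header_lines,
            stats=stats,
            float_size=float_size,
            extra_info_ids=extra_info,
        )
    builder = create_table(out_dir, schema)
    with _open_text(vcf_path) as fh:
        line_number = 0
        for line in fh:
            line_number += 1
            if line.startswith("#"):
                continue
            cells = parse_vcf_record(line, schema, line_number)
            builder.append_row(_row_from_cells(schema, cells))
    return builder.finalise()


# -- GTF ---------------------------------------------------------------------

_GTF_COLUMNS = (
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "gene_id", "transcript_id", "attributes",
)


def parse_gtf_record(line: str, line_number=None):
    """One GTF line -> dict of the 9 fields plus extracted gene_id and
    transcript_id."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ConversionError(
            f"expected 9 tab-separated fields, got {len(fields)}",
            line_number,
        )
    seqname, source, feature, start, end, score, strand, frame, attrs = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise ConversionError(
            f"bad coordinates {start!r}..{end!r}", line_number
        ) from None
    if start_i > end_i:
        raise ConversionError(
            f"start {start_i} > end {end_i}", line_number
        )
    attr_map = dict(_GTF_ATTR_RE.findall(attrs))
    return {
        "seqname": seqname,
        "source": source,
        "feature": feature,
        "start": start_i,
        "end": end_i,
        "score": MISSING if score == "." else float(score),
        "strand": strand,
        "frame": MISSING if frame == "." else int(frame),
        "gene_id": attr_map.get("gene_id", MISSING),
        "transcript_id": attr_map.get("transcript_id", MISSING),
        "attributes": attrs,
    }


def gtf_to_table(gtf_path, out_dir) -> Table:
    """Convert a GTF file (plain or gzip) to a table.

    Coordinates stay 1-based inclusive as in the source; a first pass
    picks the smallest integer size for start/end.
    """
    start_stats, end_stats = ColumnStats(), ColumnStats()
    with _open_text(gtf_path) as fh:
        line_number = 0
        for line in fh:
            line_number += 1
            if line.startswith("#") or not line.strip():
                continue
            rec = parse_gtf_record(line, line_number)
            start_stats.observe_int(rec["start"])
            end_stats.observe_int(rec["end"])
    start_stats.observe_count(1)
    end_stats.observe_count(1)
    if start_stats.n_values == 0:
        start_spec = ColumnSpec("start", ColumnType.UINT, 8, 1)
        end_spec = ColumnSpec("end", ColumnType.UINT, 8, 1)
    else:
        start_spec = infer_column_spec("start", "int", start_stats)
        end_spec = infer_column_spec("end", "int", end_stats)
    schema = Schema((
        ColumnSpec("seqname", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("source", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("feature", ColumnType.CHAR, 1, VARIABLE),
        start_spec,
        end_spec,
        ColumnSpec("score", ColumnType.FLOAT, 4, 1),
        ColumnSpec("strand", ColumnType.CHAR, 1, 1),
        ColumnSpec("frame", ColumnType.UINT, 1, 1),
        ColumnSpec("gene_id", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("transcript_id", ColumnType.CHAR, 1, VARIABLE),
        ColumnSpec("attributes", ColumnType.CHAR, 1, VARIABLE),
    ))
    builder = create_table(out_dir, schema)
    with _open_text(gtf_path) as fh:
        line_number = 0
        for line in fh:
            line_number += 1
            if line.startswith("#") or not line.strip():
                continue
            rec = parse_gtf_record(line, line_number)
            builder.append_row(tuple(rec[c] for c in _GTF_COLUMNS))
    return builder.finalise()


# -- the worked analysis: transition/transversion counts ---------------------

_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


def classify_substitution(ref: str, alt: str) -> str | None:
    """'ts', 'tv' or None for a single REF/ALT allele pair.

    Only single-base A/C/G/T pairs are classified; indels and symbolic
    alleles return None.  A purine<->purine or pyrimidine<->pyrimidine
    change (A<->G, C<->T) is a transition; any other base pair is a
    transversion.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        return None
    if ref not in _BASES or alt not in _BASES:
        return None
    if frozenset((ref, alt)) in _TRANSITIONS:
        return "ts"
    return "tv"


def count_transitions_transversions(table: Table) -> tuple:
    """Scan REF and ALT and count (transitions, transversions).

    Each alternate allele of a multi-allelic row is classified on its own;
    alleles that are not single A/C/G/T bases are skipped.
    """
    for required in ("REF", "ALT"):
        if required not in table.schema:
            raise SchemaError(f"table has no {required!r} column")
    ts = tv = 0
    for ref, alt in table.cursor(["REF", "ALT"]):
        if ref is MISSING or alt is MISSING:
            continue
        for allele in alt.split(","):
            kind = classify_substitution(ref, allele)
            if kind == "ts":
                ts += 1
            elif kind == "tv":
                tv += 1
    return ts, tv


def count_ts_tv_from_index(index) -> tuple:
    """Same counts computed from a REF+ALT index histogram instead of a
    table scan: classify each distinct (REF, ALT) key once and weight by
    its row count."""
    cols = tuple(index.spec.key_columns)
    if cols != ("REF", "ALT"):
        raise SchemaError(
            f"expected an index on (REF, ALT), got {cols}"
        )
    ts = tv = 0
    for (ref, alt), n in index.histogram():
        if ref is MISSING or alt is MISSING:
            continue
        for allele in alt.split(","):
            kind = classify_substitution(ref, allele)
            if kind == "ts":
                ts += n
            elif kind == "tv":
                tv += n
    return ts, tv
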