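"""Deterministic toy-data generators.

Everything here is format-level synthetic data: a seeded RNG produces
small VCF and GTF files with the structural features the converters must
handle (multi-allelic sites, indels, missing values, flags, per-sample
fields) and random schema/row sets that deliberately oversample codec
edges (range extrema, MISSING, variable-length payloads).  The same
config always yields byte-identical output, with no dependence on hash
ordering or locale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .converters import VcfFieldDef
from .schema import (
    MISSING,
    VARIABLE,
    ColumnSpec,
    ColumnType,
    Schema,
)
from .row_codec import int_range, uint_range

_DEFAULT_INFO = (
    VcfFieldDef("DP", 1, "Integer", "INFO"),
    VcfFieldDef("MQ", 1, "Float", "INFO"),
    VcfFieldDef("AF", "A", "Float", "INFO"),
    VcfFieldDef("AC", "A", "Integer", "INFO"),
    VcfFieldDef("DB", 0, "Flag", "INFO"),
)

_DEFAULT_FORMAT = (
    VcfFieldDef("GT", 1, "String", "FORMAT"),
    VcfFieldDef("GQ", 1, "Integer", "FORMAT"),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the toy generators; equal configs give equal bytes."""

    seed: int = 1
    num_rows: int = 100
    num_samples: int = 3
    chromosomes: tuple = ("2L", "2R", "3L")
    max_pos: int = 1_000_000
    info_fields: tuple = _DEFAULT_INFO
    format_fields: tuple = _DEFAULT_FORMAT


_BASES = "ACGT"


def _vcf_header(config: FixtureConfig, samples) -> list:
    lines = ["##fileformat=VCFv4.1"]
    for chrom in config.chromosomes:
        lines.append(f"##contig=<ID={chrom},length={config.max_pos + 10_000}>")
    lines.append('##FILTER=<ID=q10,Description="Quality below 10">')
    for d in config.info_fields:
        lines.append(
            f"##INFO=<ID={d.id},Number={d.number},Type={d.vtype},"
            f'Description="{d.id} field">'
        )
    if samples:
        for d in config.format_fields:
            lines.append(
                f"##FORMAT=<ID={d.id},Number={d.number},Type={d.vtype},"
                f'Description="{d.id} field">'
            )
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols.append("FORMAT")
        cols += samples
    lines.append("\t".join(cols))
    return lines


def _info_value(rng: random.Random, d: VcfFieldDef, n_alt: int) -> str | None:
    """Rendered value for one INFO field, or None when absent this row."""
    if d.vtype == "Flag":
        return d.id if rng.random() < 0.3 else None
    n = n_alt if d.number == "A" else (d.number if isinstance(d.number, int) else 1)
    if d.vtype == "Integer":
        vals = [str(rng.randint(0, 250)) for _ in range(max(n, 1))]
    elif d.vtype == "Float":
        if rng.random() < 0.15:
            return None
        vals = [f"{rng.uniform(0, 60):.2f}" for _ in range(max(n, 1))]
    else:
        vals = ["".join(rng.choice(_BASES) for _ in range(3))]
    return f"{d.id}={','.join(vals)}"


def generate_toy_vcf(config: FixtureConfig) -> str:
    """A small, valid VCF 4.1 text: positions strictly increasing within
    each chromosome, SNPs with occasional indels, sporadic missing values."""
    rng = random.Random(config.seed)
    samples = [f"NA{i + 1:04d}" for i in range(config.num_samples)]
    lines = _vcf_header(config, samples)
    n_chrom = max(len(config.chromosomes), 1)
    per_chrom = [config.num_rows // n_chrom] * n_chrom
    for i in range(config.num_rows % n_chrom):
        per_chrom[i] += 1
    rs = 0
    for chrom, n_rows in zip(config.chromosomes, per_chrom):
        pos = 0
        step = max(config.max_pos // (n_rows + 1), 1)
        for _ in range(n_rows):
            pos += rng.randint(1, max(2 * step, 2))
            if rng.random() < 0.85:  # SNP
                ref = rng.choice(_BASES)
                n_alt = 1 if rng.random() < 0.8 else 2
                alts = rng.sample([b for b in _BASES if b != ref], n_alt)
            else:  # indel
                ref = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 4)))
                alts = ["".join(rng.choice(_BASES)
                                for _ in range(rng.randint(1, 4)))]
            if rng.random() < 0.1:
                vid = "."
            else:
                rs += 1
                vid = f"rs{1000 + rs}"
            qual = "." if rng.random() < 0.1 else f"{rng.uniform(1, 100):.1f}"
            filt = rng.choice(["PASS"] * 8 + ["q10", "."])
            info_parts = [
                v for d in config.info_fields
                if (v := _info_value(rng, d, len(alts))) is not None
            ]
            info = ";".join(info_parts) if info_parts else "."
            fields = [chrom, str(pos), vid, ref, ",".join(alts), qual,
                      filt, info]
            if samples:
                fields.append(":".join(d.id for d in config.format_fields))
                for _ in samples:
                    parts = []
                    for d in config.format_fields:
                        if d.id == "GT":
                            a = rng.randint(0, len(alts))
                            b = rng.randint(0, len(alts))
                            parts.append(f"{min(a, b)}/{max(a, b)}")
                        elif d.vtype == "Integer":
                            parts.append(
                                "." if rng.random() < 0.1
                                else str(rng.randint(0, 99))
                            )
                        else:
                            parts.append(".")
                    fields.append(":".join(parts))
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def generate_toy_gtf(config: FixtureConfig) -> str:
    """A small GTF: nested gene > transcript > exon/CDS features, 9 fields
    per line, exactly ``config.num_rows`` data lines."""
    rng = random.Random(config.seed)
    lines = []
    gene_n = 0
    while len(lines) < config.num_rows:
        gene_n += 1
        chrom = rng.choice(list(config.chromosomes))
        strand = rng.choice("+-")
        g_start = rng.randint(1, max(config.max_pos - 10_000, 2))
        g_end = g_start + rng.randint(500, 9_999)
        gid = f"G{gene_n:04d}"
        tid = f"T{gene_n:04d}.1"
        lines.append("\t".join([
            chrom, "toy", "gene", str(g_start), str(g_end), ".", strand,
            ".", f'gene_id "{gid}";',
        ]))
        lines.append("\t".join([
            chrom, "toy", "transcript", str(g_start), str(g_end), ".",
            strand, ".", f'gene_id "{gid}"; transcript_id "{tid}";',
        ]))
        n_exons = rng.randint(1, 3)
        span = (g_end - g_start) // n_exons
        for e in range(n_exons):
            e_start = g_start + e * span
            e_end = e_start + max(span // 2, 1)
            score = "." if rng.random() < 0.7 else f"{rng.uniform(0, 100):.1f}"
            frame = str(rng.randint(0, 2))
            attrs = f'gene_id "{gid}"; transcript_id "{tid}"; exon_number "{e + 1}";'
            feature = "exon" if rng.random() < 0.6 else "CDS"
            lines.append("\t".join([
                chrom, "toy", feature, str(e_start), str(e_end), score,
                strand, frame if feature == "CDS" else ".", attrs,
            ]))
    lines = lines[:config.num_rows]
    return "#!genome-build toy1\n" + "\n".join(lines) + "\n"


# -- random schema/row generation (drives the property suites) ---------------

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def _random_spec(rng: random.Random, name: str) -> ColumnSpec:
    ctype = rng.choice(list(ColumnType))
    if ctype is ColumnType.CHAR:
        size = 1
        num = rng.choice([1, 2, 5, VARIABLE, VARIABLE])
    elif ctype is ColumnType.FLOAT:
        size = rng.choice([2, 4, 8])
        num = rng.choice([1, 1, 1, 2, VARIABLE])
    else:
        size = rng.choice([1, 2, 3, 4, 8])
        num = rng.choice([1, 1, 1, 2, 3, VARIABLE])
    return ColumnSpec(name, ctype, size, num)


def _random_element(rng: random.Random, spec: ColumnSpec):
    """Edge-biased scalar element for a numeric column (may be MISSING)."""
    if rng.random() < 0.12:
        return MISSING
    if spec.ctype is ColumnType.UINT:
        lo, hi = uint_range(spec.element_size)
        return rng.choice([lo, hi, rng.randint(lo, hi), rng.randint(0, 100)])
    if spec.ctype is ColumnType.INT:
        lo, hi = int_range(spec.element_size)
        return rng.choice([lo, hi, 0, rng.randint(lo, hi)])
    # floats: quarter-integers are exact in half, single and double
    return rng.choice(
        [0.0, 1.0, -1.0, 0.5, rng.randint(-400, 400) / 4]
    )


def _random_cell(rng: random.Random, spec: ColumnSpec):
    if spec.ctype is ColumnType.CHAR:
        if rng.random() < 0.12:
            return MISSING
        n = (
            rng.randint(1, 8) if spec.is_variable else spec.num_elements
        )
        return "".join(rng.choice(_LETTERS) for _ in range(n))
    if spec.is_variable:
        if rng.random() < 0.12:
            return MISSING
        return tuple(
            _random_element(rng, spec) for _ in range(rng.randint(1, 4))
        )
    if spec.num_elements == 1:
        return _random_element(rng, spec)
    return tuple(
        _random_element(rng, spec) for _ in range(spec.num_elements)
    )


def random_table(seed: int, max_columns: int = 6, max_rows: int = 20):
    """A random valid (schema, rows) pair covering all types and sizes,
    with MISSING and range extrema oversampled."""
    if max_columns < 1 or max_rows < 1:
        raise ValueError("bounds must be >= 1")
    rng = random.Random(seed)
    ncols = rng.randint(1, max_columns)
    schema = Schema(tuple(
        _random_spec(rng, f"c{i}") for i in range(ncols)
    ))
    nrows = rng.randint(0, max_rows)
    rows = [
        tuple(_random_cell(rng, spec) for spec in schema.columns)
        for _ in range(nrows)
    ]
    return schema, rows
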