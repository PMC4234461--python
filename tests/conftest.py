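"""Shared fixtures and the brute-force ordering oracle used by the index
tests.

The oracle ranks rows by their key-column values at the *value* level
(MISSING first, numeric order for numbers, byte-lexicographic for
strings, element by element for multi-element cells) with no reference to
the key encoding, so it is an independent check of the order-preserving
byte encodings.
"""

from __future__ import annotations

import random

import pytest

import wormtable as wt
from wormtable.schema import MISSING, ColumnType


def build_table(directory, schema, rows):
    builder = wt.create_table(directory, schema)
    for r in rows:
        builder.append_row(r)
    return builder.finalise()


# -- value-level ordering oracle --------------------------------------------


def _element_key(e):
    return (0,) if e is MISSING else (1, e)


def cell_sort_key(spec, width, value):
    """Rank of one key-column cell; mirrors the documented ordering
    semantics (not the byte encoding)."""
    if width is not None:
        b = MISSING if value is MISSING else wt.bin_value(value, width)
        return _element_key(b)
    if spec.ctype is ColumnType.CHAR:
        if value is MISSING:
            return (0,)
        data = value.encode("utf-8") if isinstance(value, str) else value
        return (1, data)
    # numeric: normalise MISSING to the element shape it is stored as
    if value is MISSING:
        n = 1 if spec.is_variable else spec.num_elements
        elems = (MISSING,) * n
    elif isinstance(value, tuple):
        elems = value
    else:
        elems = (value,)
    return tuple(_element_key(e) for e in elems)


def row_sort_key(schema, spec: "wt.IndexSpec", values):
    """Rank of a full key tuple (one value per key column)."""
    return tuple(
        cell_sort_key(schema.spec(name), width, v)
        for name, width, v in zip(spec.key_columns, spec.bin_widths, values)
    )


def brute_force_index_order(schema, spec, rows):
    """Stable sort of (position, key-values) by the oracle ranking."""
    key_pos = [schema.position(n) for n in spec.key_columns]
    return sorted(
        range(len(rows)),
        key=lambda i: row_sort_key(
            schema, spec, tuple(rows[i][p] for p in key_pos)
        ),
    )


def prefix_in_range(schema, spec, key_values, start, stop):
    """Value-level realisation of the half-open partial-key range."""
    ok = True
    if start is not None:
        a = tuple(
            cell_sort_key(schema.spec(n), w, v)
            for n, w, v in zip(spec.key_columns, spec.bin_widths, start)
        )
        ok = ok and tuple(
            row_sort_key(schema, spec, key_values)[: len(start)]
        ) >= a
    if stop is not None:
        b = tuple(
            cell_sort_key(schema.spec(n), w, v)
            for n, w, v in zip(spec.key_columns, spec.bin_widths, stop)
        )
        ok = ok and tuple(
            row_sort_key(schema, spec, key_values)[: len(stop)]
        ) < b
    return ok


def random_index_spec(rng: random.Random, schema) -> wt.IndexSpec:
    """A random legal index over the schema: up to three key columns, a
    variable-count numeric column only in last position, occasional bins
    on small numeric columns."""
    cols = list(schema.columns)
    rng.shuffle(cols)
    chosen = cols[: rng.randint(1, min(3, len(cols)))]
    varnum = [
        c for c in chosen
        if c.is_variable and c.ctype is not ColumnType.CHAR
    ]
    fixed = [c for c in chosen if c not in varnum]
    chosen = fixed + varnum[:1]
    widths = []
    for c in chosen:
        if (
            c.ctype in (ColumnType.UINT, ColumnType.INT)
            and c.element_size <= 4
            and c.num_elements == 1
            and rng.random() < 0.3
        ):
            widths.append(rng.choice([1, 2, 5, 10, 1000]))
        elif (
            c.ctype is ColumnType.FLOAT
            and c.num_elements == 1
            and rng.random() < 0.3
        ):
            widths.append(rng.choice([0.5, 1, 2.5, 10]))
        else:
            widths.append(None)
    return wt.IndexSpec(
        key_columns=tuple(c.name for c in chosen), bin_widths=tuple(widths)
    )


# -- shared converted fixtures ----------------------------------------------


@pytest.fixture(scope="session")
def toy_vcf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    path.write_text(wt.generate_toy_vcf(wt.FixtureConfig(seed=1)))
    return path


@pytest.fixture(scope="session")
def toy_table(toy_vcf_path, tmp_path_factory):
    out = tmp_path_factory.mktemp("wt") / "toy.wt"
    table = wt.vcf_to_table(toy_vcf_path, out)
    yield table
    table.close()


@pytest.fixture(scope="session")
def aagt_table(tmp_path_factory):
    """The four-row REF = A, A, G, T table used across the index examples."""
    schema = wt.Schema((
        wt.ColumnSpec("REF", wt.ColumnType.CHAR, 1, 1),
        wt.ColumnSpec("POS", wt.ColumnType.UINT, 4, 1),
    ))
    directory = tmp_path_factory.mktemp("wt") / "aagt.wt"
    table = build_table(
        directory, schema, [("A", 10), ("T", 20), ("G", 30), ("A", 40)]
    )
    wt.build_index(table, wt.IndexSpec(("REF",))).close()
    yield table
    table.close()
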