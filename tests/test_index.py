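"""Secondary indexes: order-preserving keys, binning, cursors, histograms.

The heavy lifting is done against the value-level brute-force oracle in
conftest, which knows nothing about the byte encodings.
"""

import random

import pytest

import wormtable as wt
from wormtable import (
    IndexingError,
    IndexSpec,
    MISSING,
    ColumnSpec,
    ColumnType,
    Schema,
    VARIABLE,
)
from wormtable.kvstore import MemoryKVStore, SqliteKVStore

from conftest import (
    brute_force_index_order,
    build_table,
    prefix_in_range,
    random_index_spec,
    row_sort_key,
)


# -- key encoding ------------------------------------------------------------

CHROM_POS_SCHEMA = Schema((
    ColumnSpec("CHROM", ColumnType.CHAR, 1, VARIABLE),
    ColumnSpec("POS", ColumnType.UINT, 4, 1),
    ColumnSpec("REF", ColumnType.CHAR, 1, 1),
    ColumnSpec("QUAL", ColumnType.FLOAT, 2, 1),
))


def test_key_encoding_worked_examples():
    s = CHROM_POS_SCHEMA
    assert wt.encode_index_key(IndexSpec(("REF",)), s, ("A",)) == b"\x41"
    assert wt.encode_index_key(
        IndexSpec(("CHROM", "POS")), s, ("2L", 5000)
    ) == b"2L\x00\x00\x00\x13\x89"
    assert wt.encode_index_key(
        IndexSpec(("QUAL",), (0.5,)), s, (1.2,)
    ) == bytes.fromhex("8000000000000002")


def test_key_decoding_inverts_encoding():
    s = CHROM_POS_SCHEMA
    for spec, values in [
        (IndexSpec(("CHROM", "POS")), ("2L", 5000)),
        (IndexSpec(("CHROM", "POS")), (MISSING, MISSING)),
        (IndexSpec(("QUAL", "REF")), (-2.5, "T")),
        (IndexSpec(("POS",), (1000,)), (12345,)),  # decodes to the bin id
    ]:
        key = wt.encode_index_key(spec, s, values)
        decoded = wt.decode_index_key(spec, s, key)
        if spec.bin_widths[0] is not None:
            assert decoded == (wt.bin_value(values[0], spec.bin_widths[0]),)
        else:
            assert decoded == values


def test_embedded_nul_in_indexed_string_rejected():
    with pytest.raises(IndexingError, match="NUL"):
        wt.encode_index_key(
            IndexSpec(("CHROM",)), CHROM_POS_SCHEMA, ("2\x00L",)
        )


@pytest.mark.parametrize(
    "value, width, expected",
    [(1.2, 0.5, 2), (-0.3, 0.5, -1), (12345, 1000, 12), (10, 5, 2),
     (-7, 5, -2)],
)
def test_bin_value(value, width, expected):
    assert wt.bin_value(value, width) == expected
    # bin b covers [b*w, (b+1)*w)
    assert expected * width <= value < (expected + 1) * width


def test_bin_value_errors_and_missing():
    with pytest.raises(IndexingError):
        wt.bin_value(1.0, 0)
    with pytest.raises(IndexingError):
        wt.bin_value(1.0, -2)
    assert wt.bin_value(MISSING, 0.5) is MISSING


@pytest.mark.parametrize("seed", range(40))
def test_key_order_isomorphism(seed):
    """Byte order of encoded keys equals value order of the tuples."""
    rng = random.Random(seed)
    schema, rows = wt.random_table(seed, max_columns=5, max_rows=12)
    if not rows:
        return
    spec = random_index_spec(rng, schema)
    positions = [schema.position(n) for n in spec.key_columns]
    encoded = []
    for r in rows:
        values = tuple(r[p] for p in positions)
        encoded.append(
            (wt.encode_index_key(spec, schema, values),
             row_sort_key(schema, spec, values))
        )
    for (ka, oa) in encoded:
        for (kb, ob) in encoded:
            if oa < ob:
                assert ka < kb
            elif oa > ob:
                assert ka > kb
            else:
                assert ka == kb


# -- the A, A, G, T worked example -------------------------------------------


def test_ref_index_worked_example(aagt_table):
    with aagt_table.open_index("REF") as index:
        assert len(index) == 4
        assert list(index.keys()) == [("A",), ("G",), ("T",)]
        assert [r[0] for r in index.cursor(["REF"])] == ["A", "A", "G", "T"]
        assert index.key_count(("A",)) == 2
        assert index.key_count(("C",)) == 0
        assert index.histogram() == [(("A",), 2), (("G",), 1), (("T",), 1)]
        assert index.key_range() == (("A",), ("T",))
        # equal keys tie-break by row position: A rows are 0 then 3
        assert [p for _, p in index.cursor(["REF", "POS"])] == [
            10, 40, 30, 20
        ]
        # counts are unchanged by reads (immutability)
        assert index.key_count(("A",)) == 2


def test_rebuild_same_name_refused(aagt_table):
    with pytest.raises(IndexingError, match="exists"):
        wt.build_index(aagt_table, IndexSpec(("REF",)))


def test_empty_table_index(tmp_path):
    t = wt.create_table(
        tmp_path / "e.wt",
        Schema((ColumnSpec("x", ColumnType.UINT, 1, 1),)),
    ).finalise()
    index = wt.build_index(t, IndexSpec(("x",)))
    assert len(index) == 0
    assert list(index.keys()) == []
    assert index.histogram() == []
    with pytest.raises(IndexingError, match="empty"):
        index.key_range()
    index.close()
    t.close()


def test_key_count_arity_checked(aagt_table):
    with aagt_table.open_index("REF") as index:
        with pytest.raises(IndexingError, match="full"):
            index.key_count(("A", 1))


def test_partial_key_longer_than_columns(aagt_table):
    with aagt_table.open_index("REF") as index:
        with pytest.raises(IndexingError):
            list(index.cursor(["REF"], start=("A", 1, 2)))


def test_binned_histogram_worked_example(tmp_path):
    schema = Schema((ColumnSpec("POS", ColumnType.UINT, 4, 1),))
    t = build_table(tmp_path / "t.wt", schema, [(100,), (900,), (1500,)])
    index = wt.build_index(t, IndexSpec(("POS",), (1000,)))
    assert index.histogram() == [((0,), 2), ((1,), 1)]
    assert list(index.keys()) == [(0,), (1,)]
    index.close()
    t.close()


def test_variable_numeric_key_column_must_be_last(tmp_path):
    schema = Schema((
        ColumnSpec("v", ColumnType.INT, 2, VARIABLE),
        ColumnSpec("x", ColumnType.UINT, 1, 1),
    ))
    t = build_table(tmp_path / "t.wt", schema, [((1, 2), 3)])
    with pytest.raises(IndexingError, match="last"):
        wt.build_index(t, IndexSpec(("v", "x")))
    index = wt.build_index(t, IndexSpec(("x", "v")))
    assert list(index.keys()) == [(3, (1, 2))]
    index.close()
    t.close()


# -- oracle-backed properties ------------------------------------------------


def _table_with_index(tmp_path, seed, max_rows=60):
    rng = random.Random(seed)
    schema, rows = wt.random_table(seed, max_columns=5, max_rows=max_rows)
    table = build_table(tmp_path / f"t{seed}.wt", schema, rows)
    spec = random_index_spec(rng, schema)
    index = wt.build_index(table, spec)
    return rng, schema, rows, table, spec, index


@pytest.mark.parametrize("seed", range(25))
def test_full_cursor_equals_brute_force_sort(tmp_path, seed):
    """Index-cursor row order equals a stable value-level sort (MISSING
    first, numeric order, byte-lexicographic strings, ties by position)."""
    rng, schema, rows, table, spec, index = _table_with_index(tmp_path, seed)
    got = list(index.cursor(list(schema.names)))
    expected = [rows[i] for i in brute_force_index_order(schema, spec, rows)]
    assert got == expected
    table.close()
    index.close()


@pytest.mark.parametrize("seed", range(25))
def test_range_cursor_equals_brute_force_filter(tmp_path, seed):
    rng, schema, rows, table, spec, index = _table_with_index(tmp_path, seed)
    positions = [schema.position(n) for n in spec.key_columns]
    order = brute_force_index_order(schema, spec, rows)
    for _ in range(6):
        arity = rng.randint(1, len(spec.key_columns))

        def bound():
            if rng.random() < 0.25:
                return None
            if rows and rng.random() < 0.7:
                r = rng.choice(rows)
                return tuple(r[p] for p in positions[:arity])
            sch_cols = [schema.spec(n) for n in spec.key_columns[:arity]]
            from wormtable.fixtures import _random_cell
            return tuple(_random_cell(rng, c) for c in sch_cols)

        start, stop = bound(), bound()
        try:
            got = list(index.cursor(list(schema.names), start, stop))
        except IndexingError:
            continue  # e.g. a NUL-free constraint violation in a random bound
        expected = [
            rows[i] for i in order
            if prefix_in_range(
                schema, spec,
                tuple(rows[i][p] for p in positions), start, stop,
            )
        ]
        assert got == expected, (spec, start, stop)
    table.close()
    index.close()


def test_cursor_start_equals_stop_is_empty(aagt_table):
    with aagt_table.open_index("REF") as index:
        assert list(index.cursor(["REF"], ("A",), ("A",))) == []


@pytest.mark.parametrize("seed", range(15))
def test_histogram_conservation(tmp_path, seed):
    """Counts sum to num_rows and agree with key_count entry-wise."""
    rng, schema, rows, table, spec, index = _table_with_index(tmp_path, seed)
    hist = index.histogram()
    assert sum(n for _, n in hist) == table.num_rows
    assert list(index.keys()) == [k for k, _ in hist]
    for key, n in hist:
        assert index.key_count(key) == n
    table.close()
    index.close()


@pytest.mark.parametrize("seed", range(10))
def test_bin_containment_of_indexed_rows(tmp_path, seed):
    """Every row filed under bin b has its value in [b*w, (b+1)*w)."""
    rng = random.Random(seed)
    schema = Schema((ColumnSpec("x", ColumnType.INT, 4, 1),))
    rows = [(rng.randint(-5000, 5000),) for _ in range(50)]
    table = build_table(tmp_path / "t.wt", schema, rows)
    width = rng.choice([1, 3, 10, 250])
    index = wt.build_index(table, IndexSpec(("x",), (width,)))
    seen = 0
    for (b,), n in index.histogram():
        # rows under this exact bin key
        matching = [
            x for (x,) in table.cursor(["x"])
            if wt.bin_value(x, width) == b
        ]
        assert len(matching) == n
        assert all(b * width <= x < (b + 1) * width for x in matching)
        seen += n
    assert seen == len(rows)
    table.close()
    index.close()


def test_missing_sorts_first(tmp_path):
    schema = Schema((ColumnSpec("x", ColumnType.INT, 2, 1),))
    rows = [(5,), (MISSING,), (-5,), (0,)]
    table = build_table(tmp_path / "t.wt", schema, rows)
    index = wt.build_index(table, IndexSpec(("x",)))
    assert [v for (v,) in index.cursor(["x"])] == [MISSING, -5, 0, 5]
    table.close()
    index.close()


def test_failed_build_leaves_no_file(tmp_path):
    schema = Schema((ColumnSpec("s", ColumnType.CHAR, 1, VARIABLE),))
    table = build_table(tmp_path / "t.wt", schema, [("ok",), ("b\x00ad",)])
    import os

    before = sorted(os.listdir(table.directory))
    with pytest.raises(IndexingError, match="row 1"):
        wt.build_index(table, IndexSpec(("s",)))
    assert sorted(os.listdir(table.directory)) == before
    assert table.indexes == {}
    table.close()


# -- KV store contract -------------------------------------------------------


@pytest.mark.parametrize("backend", ["sqlite", "memory"])
def test_kvstore_contract(tmp_path, backend):
    """Both backends: ascending byte order, duplicates, range scans."""
    if backend == "sqlite":
        store = SqliteKVStore(tmp_path / "kv.db", "w")
    else:
        store = MemoryKVStore()
    pairs = [(b"b", b"2"), (b"a", b"1"), (b"b", b"1"), (b"c", b"9"),
             (b"", b"0")]
    for k, v in pairs:
        store.put(k, v)
    store.finalise()
    assert list(store.scan()) == sorted(pairs)
    assert store.get(b"b") == [b"1", b"2"]
    assert store.count(b"b") == 2
    assert store.count(b"zz") == 0
    assert list(store.scan(b"a", b"c")) == [
        (b"a", b"1"), (b"b", b"1"), (b"b", b"2")
    ]
    assert list(store.distinct()) == [(b"", 1), (b"a", 1), (b"b", 2),
                                      (b"c", 1)]
    assert store.min_key() == b"" and store.max_key() == b"c"
    assert len(store) == 5
    store.close()
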