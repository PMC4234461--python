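"""Secondary indexes: order-preserving key encoding, binning and key-range
cursors.

An index over columns ``(c1, .., ck)`` is an ordered KV store whose keys
are the per-column order-preserving encodings concatenated, and whose
values are 8-byte big-endian row positions.  Because byte order of the
keys equals value order of the tuples, range queries, histograms and
partial-key lookups are plain prefix scans.

Per-column key encodings:

* unsigned/signed integers reuse the row codec's biased encodings, which
  already sort correctly with the all-zero MISSING pattern first;
* floats use the classic IEEE bit trick: negative values have all bits
  inverted, non-negative values have the sign bit set; MISSING is all-zero;
* fixed-length strings are raw bytes; variable-length strings are raw
  bytes followed by a 0x00 terminator (embedded NULs are rejected), so
  ``"2" < "2L"`` holds after concatenation;
* a binned column stores ``floor(value / width)`` as an 8-byte signed
  integer, whatever the source type, so negative bins order correctly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

from .errors import IndexingError, SchemaError
from .kvstore import SqliteKVStore
from .row_codec import decode_row, encode_element, decode_element
from .schema import MISSING, ColumnSpec, ColumnType, Schema
from .table import Table

_BIN_SPEC = ColumnSpec("bin", ColumnType.INT, 8)
_SIGN = {2: 0x8000, 4: 0x80000000, 8: 0x8000000000000000}
_MASK = {s: (1 << (8 * s)) - 1 for s in (2, 4, 8)}


@dataclass(frozen=True)
class IndexSpec:
    """Which columns to index, in order, with optional per-column bin widths."""

    key_columns: tuple
    bin_widths: tuple = ()

    def __post_init__(self):
        cols = tuple(self.key_columns)
        object.__setattr__(self, "key_columns", cols)
        widths = tuple(self.bin_widths) or (None,) * len(cols)
        object.__setattr__(self, "bin_widths", widths)
        if not cols:
            raise IndexingError("index needs at least one key column")
        if len(set(cols)) != len(cols):
            raise IndexingError(f"repeated key column in {cols}")
        if len(widths) != len(cols):
            raise IndexingError("bin_widths must align with key_columns")

    @property
    def name(self) -> str:
        return "+".join(self.key_columns)


def _validate_spec(schema: Schema, spec: IndexSpec) -> None:
    for i, (name, width) in enumerate(zip(spec.key_columns, spec.bin_widths)):
        col = schema.spec(name)  # raises SchemaError if unknown
        if width is not None:
            if col.ctype is ColumnType.CHAR:
                raise IndexingError(
                    f"column {name!r}: bins are only valid on numeric columns"
                )
            if width <= 0:
                raise IndexingError(f"column {name!r}: bin width must be > 0")
            if col.ctype is not ColumnType.FLOAT and width != int(width):
                raise IndexingError(
                    f"column {name!r}: integer column needs an integer "
                    f"bin width, got {width!r}"
                )
        if (
            col.is_variable
            and col.ctype is not ColumnType.CHAR
            and width is None
            and i != len(spec.key_columns) - 1
        ):
            # A variable-count numeric key column has no delimiter in the
            # concatenated key, so its extent is only recoverable when it
            # is the last column.
            raise IndexingError(
                f"column {name!r}: variable-count numeric columns may only "
                f"be the last key column"
            )


def bin_value(value, width):
    """Map a value to its bin id: ``floor(value / width)``.

    Bin ``b`` covers the half-open interval ``[b*width, (b+1)*width)``.
    MISSING passes through unchanged.
    """
    if width is None or width <= 0:
        raise IndexingError(f"bin width must be positive, got {width!r}")
    if value is MISSING:
        return MISSING
    if (
        isinstance(value, int)
        and isinstance(width, int)
        and not isinstance(value, bool)
    ):
        return value // width
    return math.floor(value / width)


# -- per-column key codec ----------------------------------------------------


def _float_sort_bytes(spec: ColumnSpec, value) -> bytes:
    if value is MISSING:
        return b"\x00" * spec.element_size
    raw = encode_element(spec, value)
    s = spec.element_size
    bits = int.from_bytes(raw, "big")
    if bits & _SIGN[s]:
        bits = ~bits & _MASK[s]
    else:
        bits |= _SIGN[s]
    return bits.to_bytes(s, "big")


def _float_unsort(spec: ColumnSpec, buf: bytes):
    s = spec.element_size
    if buf == b"\x00" * s:
        return MISSING
    bits = int.from_bytes(buf, "big")
    if bits & _SIGN[s]:
        bits &= ~_SIGN[s] & _MASK[s]
    else:
        bits = ~bits & _MASK[s]
    return decode_element(spec, bits.to_bytes(s, "big"))


def _key_element(col: ColumnSpec, value) -> bytes:
    if col.ctype is ColumnType.FLOAT:
        return _float_sort_bytes(col, value)
    return encode_element(col, value)  # uint/int bias encodings sort as-is


def _encode_key_column(col: ColumnSpec, width, value, prebinned=False) -> bytes:
    if width is not None:
        b = value if prebinned else bin_value(value, width)
        if b is MISSING:
            return b"\x00" * 8
        return _key_element(_BIN_SPEC, b)
    if col.ctype is ColumnType.CHAR:
        if col.is_variable:
            if value is MISSING:
                return b"\x00"
            data = value.encode("utf-8") if isinstance(value, str) else value
            if b"\x00" in data:
                raise IndexingError(
                    f"column {col.name!r}: embedded NUL byte in indexed "
                    f"string {value!r}"
                )
            return data + b"\x00"
        if value is MISSING:
            return b"\x00" * col.num_elements
        data = value.encode("utf-8") if isinstance(value, str) else value
        if len(data) != col.num_elements:
            raise IndexingError(
                f"column {col.name!r}: fixed char key must be exactly "
                f"{col.num_elements} bytes"
            )
        return data
    # numeric
    if value is MISSING:
        n = 1 if col.is_variable else col.num_elements
        return b"\x00" * (col.element_size * n)
    if isinstance(value, (tuple, list)):
        elems = tuple(value)
    else:
        elems = (value,)
    if not col.is_variable and len(elems) != col.num_elements:
        raise IndexingError(
            f"column {col.name!r}: expected {col.num_elements} elements in "
            f"key value, got {len(elems)}"
        )
    return b"".join(_key_element(col, e) for e in elems)


def encode_index_key(spec: IndexSpec, schema: Schema, values) -> bytes:
    """Encode one value per key column into the concatenated sortable key."""
    if len(values) != len(spec.key_columns):
        raise IndexingError(
            f"expected {len(spec.key_columns)} key values, got {len(values)}"
        )
    return encode_partial_key(spec, schema, values)


def encode_partial_key(spec: IndexSpec, schema: Schema, values) -> bytes:
    """Encode a prefix of the key columns (used for range bounds)."""
    if len(values) > len(spec.key_columns):
        raise IndexingError(
            f"partial key has {len(values)} values but the index has only "
            f"{len(spec.key_columns)} columns"
        )
    parts = []
    for name, width, value in zip(spec.key_columns, spec.bin_widths, values):
        parts.append(_encode_key_column(schema.spec(name), width, value))
    return b"".join(parts)


def decode_index_key(spec: IndexSpec, schema: Schema, key: bytes):
    """Decode a stored key back into a value tuple (bin ids for binned
    columns)."""
    out = []
    pos = 0
    for i, (name, width) in enumerate(zip(spec.key_columns, spec.bin_widths)):
        col = schema.spec(name)
        if width is not None:
            buf = key[pos:pos + 8]
            out.append(
                MISSING if buf == b"\x00" * 8
                else decode_element(_BIN_SPEC, buf)
            )
            pos += 8
        elif col.ctype is ColumnType.CHAR:
            if col.is_variable:
                end = key.index(b"\x00", pos)
                out.append(
                    MISSING if end == pos
                    else key[pos:end].decode("utf-8")
                )
                pos = end + 1
            else:
                buf = key[pos:pos + col.num_elements]
                out.append(
                    MISSING if buf == b"\x00" * col.num_elements
                    else buf.decode("utf-8")
                )
                pos += col.num_elements
        else:
            s = col.element_size
            if col.is_variable:
                end = len(key)  # only legal in last position
                n = (end - pos) // s
            else:
                n = col.num_elements
            elems = []
            for _ in range(n):
                buf = key[pos:pos + s]
                if col.ctype is ColumnType.FLOAT:
                    elems.append(_float_unsort(col, buf))
                else:
                    elems.append(decode_element(col, buf))
                pos += s
            if col.is_variable:
                out.append(MISSING if n == 0 else tuple(elems))
            elif n == 1:
                out.append(elems[0])
            else:
                # all-missing elements are indistinguishable from a missing cell
                out.append(tuple(elems))
    return tuple(out)


# -- construction ------------------------------------------------------------


def build_index(table: Table, spec: IndexSpec) -> "Index":
    """Scan the table once and materialise the index on disk.

    The store is written to a temporary file and moved into place only on
    success, so a failed build leaves the table directory untouched.
    """
    _validate_spec(table.schema, spec)
    if spec.name in table.indexes:
        raise IndexingError(
            f"index {spec.name!r} already exists; remove it first"
        )
    path = table.index_path(spec.name)
    if os.path.exists(path):
        raise IndexingError(f"index file already present: {path}")
    tmp = path + ".tmp"
    if os.path.exists(tmp):
        os.remove(tmp)
    store = SqliteKVStore(tmp, "w")
    try:
        pos = 0
        for pos, values in enumerate(table.cursor(list(spec.key_columns))):
            key = encode_index_key(spec, table.schema, values)
            store.put(key, pos.to_bytes(8, "big"))
        store.finalise()
        store.close()
    except Exception as e:
        store.close()
        os.remove(tmp)
        if isinstance(e, IndexingError):
            raise IndexingError(f"row {pos}: {e}") from e
        raise
    os.replace(tmp, path)
    table.register_index(
        spec.name, list(zip(spec.key_columns, spec.bin_widths))
    )
    return Index(table, spec.name)


class Index:
    """Read-only handle on a registered index of an open table."""

    def __init__(self, table: Table, name: str):
        if name not in table.indexes:
            raise IndexingError(f"no such index: {name!r}")
        cols = table.indexes[name]
        self.table = table
        self.name = name
        self.spec = IndexSpec(
            key_columns=tuple(c for c, _ in cols),
            bin_widths=tuple(w for _, w in cols),
        )
        self._store = SqliteKVStore(table.index_path(name), "r")

    def __len__(self) -> int:
        return len(self._store)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _bound(self, values):
        if values is None:
            return None
        return encode_partial_key(self.spec, self.table.schema, tuple(values))

    def cursor(self, columns, start=None, stop=None):
        """Iterate rows in key order, projected to ``columns``, restricted
        to encoded-key range [start, stop).  ``start``/``stop`` are value
        tuples for a prefix of the key columns; ``None`` means unbounded.
        Ties (equal keys) come back in ascending row-position order.
        """
        columns = list(columns)
        for name in columns:
            self.table.schema.spec(name)
        skey = self._bound(start)
        ekey = self._bound(stop)
        for _, posbytes in self._store.scan(skey, ekey):
            pos = int.from_bytes(posbytes, "big")
            row = self.table.raw_row(pos)
            yield decode_row(
                self.table.schema, self.table.layout, row, columns
            )

    def keys(self):
        """Distinct keys in ascending order, decoded to value tuples."""
        for key, _ in self._store.distinct():
            yield decode_index_key(self.spec, self.table.schema, key)

    def key_count(self, key) -> int:
        """Number of rows stored under exactly this (full) key.

        The key is given as :meth:`keys` yields it: for a binned column
        its element is the bin id, not a raw value.
        """
        key = tuple(key)
        if len(key) != len(self.spec.key_columns):
            raise IndexingError(
                f"key_count needs a full {len(self.spec.key_columns)}-column "
                f"key, got {len(key)} values"
            )
        schema = self.table.schema
        encoded = b"".join(
            _encode_key_column(schema.spec(n), w, v, prebinned=True)
            for n, w, v in zip(
                self.spec.key_columns, self.spec.bin_widths, key
            )
        )
        return self._store.count(encoded)

    def histogram(self):
        """[(decoded key tuple, count)] over distinct keys, ascending."""
        return [
            (decode_index_key(self.spec, self.table.schema, key), n)
            for key, n in self._store.distinct()
        ]

    def key_range(self):
        """(min key tuple, max key tuple); error on an empty index."""
        lo = self._store.min_key()
        if lo is None:
            raise IndexingError(f"index {self.name!r} is empty")
        hi = self._store.max_key()
        return (
            decode_index_key(self.spec, self.table.schema, lo),
            decode_index_key(self.spec, self.table.schema, hi),
        )

    def close(self) -> None:
        self._store.close()
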