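"""Write-once table construction and read-only access.

A table is a directory:

========================  ====================================================
``schema.xml``            the column definitions (see :mod:`wormtable.schema`)
``rows.dat``              encoded rows, stored back to back
``rowindex.db``           ordered KV store: 8-byte big-endian row position ->
                          12-byte row pointer (8-byte offset ++ 4-byte length)
``metadata.xml``          format version, row count and registered indexes
``index_<name>.db``       one KV store per secondary index
========================  ====================================================

Tables are built once through :class:`TableBuilder` and thereafter opened
read-only; nothing in the read path mutates any file, so a table directory
can be copied between machines byte for byte.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from xml.sax.saxutils import quoteattr

from .errors import SchemaError, TableStateError, WormtableError
from .kvstore import SqliteKVStore
from .row_codec import decode_row, encode_row
from .schema import Layout, Schema, compute_layout, parse_schema_xml, write_schema_xml

SCHEMA_FILE = "schema.xml"
DATA_FILE = "rows.dat"
ROWINDEX_FILE = "rowindex.db"
METADATA_FILE = "metadata.xml"
FORMAT_VERSION = "1.0"

_POS_KEY_SIZE = 8


def position_key(position: int) -> bytes:
    """Row positions are keyed as 8-byte big-endian integers so that the
    row index iterates in insertion order."""
    return position.to_bytes(_POS_KEY_SIZE, "big")


def pack_row_pointer(offset: int, length: int) -> bytes:
    return offset.to_bytes(8, "big") + length.to_bytes(4, "big")


def unpack_row_pointer(value: bytes) -> tuple:
    if len(value) != 12:
        raise WormtableError(f"corrupt row pointer: {value!r}")
    return int.from_bytes(value[:8], "big"), int.from_bytes(value[8:], "big")


def _index_filename(name: str) -> str:
    return f"index_{name}.db"


# -- metadata ----------------------------------------------------------------


def _write_metadata(path: str, num_rows: int, indexes: dict) -> None:
    """``indexes`` maps index name -> list of (column, bin_width-or-None)."""
    lines = [f'<table version={quoteattr(FORMAT_VERSION)}>',
             f"  <num_rows>{num_rows}</num_rows>",
             "  <indexes>"]
    for name in sorted(indexes):
        lines.append(f"    <index name={quoteattr(name)}>")
        for col, width in indexes[name]:
            if width is None:
                lines.append(f"      <column name={quoteattr(col)}/>")
            else:
                lines.append(
                    f"      <column name={quoteattr(col)} "
                    f"bin_width={quoteattr(repr(width))}/>"
                )
        lines.append("    </index>")
    lines.append("  </indexes>")
    lines.append("</table>")
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8", newline="\n") as f:
        f.write("\n".join(lines) + "\n")
    os.replace(tmp, path)


def _parse_metadata(text: str) -> tuple:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        raise TableStateError(f"corrupt metadata.xml: {e}") from e
    if root.tag != "table":
        raise TableStateError("corrupt metadata.xml: bad root element")
    nr = root.find("num_rows")
    if nr is None or nr.text is None:
        raise TableStateError("metadata.xml missing num_rows")
    num_rows = int(nr.text)
    indexes = {}
    idx_el = root.find("indexes")
    if idx_el is not None:
        for el in idx_el.findall("index"):
            cols = []
            for cel in el.findall("column"):
                w = cel.get("bin_width")
                if w is not None:
                    w = float(w)
                    if w == int(w):
                        w = int(w)
                cols.append((cel.get("name"), w))
            indexes[el.get("name")] = cols
    return num_rows, indexes


# -- builder -----------------------------------------------------------------


class TableBuilder:
    """One-shot writer for a new table.  Use :func:`create_table`."""

    def __init__(self, directory: str, schema: Schema):
        self.directory = str(directory)
        self.schema = schema
        self.layout = compute_layout(schema)
        self.num_rows = 0
        self._offset = 0
        self._finalised = False
        os.makedirs(self.directory, exist_ok=True)
        if os.listdir(self.directory):
            raise TableStateError(
                f"refusing to build in non-empty directory {self.directory!r}"
            )
        with open(
            os.path.join(self.directory, SCHEMA_FILE),
            "w", encoding="utf-8", newline="\n",
        ) as f:
            f.write(write_schema_xml(schema))
        self._data = open(os.path.join(self.directory, DATA_FILE), "wb")
        self._rowindex = SqliteKVStore(
            os.path.join(self.directory, ROWINDEX_FILE), "w"
        )

    def append_row(self, values) -> int:
        """Encode and append one row; returns its 0-based position."""
        if self._finalised:
            raise TableStateError("cannot append: table already finalised")
        row = encode_row(self.schema, self.layout, values)
        self._data.write(row)
        pos = self.num_rows
        self._rowindex.put(
            position_key(pos), pack_row_pointer(self._offset, len(row))
        )
        self._offset += len(row)
        self.num_rows += 1
        return pos

    def finalise(self) -> "Table":
        """Seal the table and return a read-only handle."""
        if self._finalised:
            raise TableStateError("table already finalised")
        self._finalised = True
        self._data.close()
        self._rowindex.finalise()
        self._rowindex.close()
        _write_metadata(
            os.path.join(self.directory, METADATA_FILE), self.num_rows, {}
        )
        return open_table(self.directory)


def create_table(directory, schema: Schema) -> TableBuilder:
    """Start building a new table in ``directory`` (must not already hold
    one: write-once discipline)."""
    return TableBuilder(directory, schema)


# -- read-only handle --------------------------------------------------------


class Table:
    """Read-only handle on a finalised table directory.

    Implements the sequence protocol: ``len(t)``, ``t[i]`` (negative
    positions allowed) and iteration yield fully decoded rows.
    """

    def __init__(self, directory: str):
        self.directory = str(directory)
        schema_path = os.path.join(self.directory, SCHEMA_FILE)
        meta_path = os.path.join(self.directory, METADATA_FILE)
        data_path = os.path.join(self.directory, DATA_FILE)
        for p in (schema_path, meta_path, data_path):
            if not os.path.exists(p):
                raise TableStateError(
                    f"not a finalised table: {self.directory!r} "
                    f"(missing {os.path.basename(p)})"
                )
        with open(schema_path, encoding="utf-8") as f:
            self.schema: Schema = parse_schema_xml(f.read())
        self.layout: Layout = compute_layout(self.schema)
        with open(meta_path, encoding="utf-8") as f:
            self.num_rows, self._indexes = _parse_metadata(f.read())
        self._data = open(data_path, "rb")
        self._rowindex = SqliteKVStore(
            os.path.join(self.directory, ROWINDEX_FILE), "r"
        )

    # -- sequence protocol ---------------------------------------------------

    def __len__(self) -> int:
        return self.num_rows

    def __getitem__(self, position: int):
        return self.get_row(position)

    def __iter__(self):
        return self.cursor(self.schema.names)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- row access ----------------------------------------------------------

    def raw_row(self, position: int) -> bytes:
        """Undecoded bytes of the row at a non-negative position."""
        values = self._rowindex.get(position_key(position))
        if not values:
            raise IndexError(f"row position {position} out of range")
        offset, length = unpack_row_pointer(values[0])
        self._data.seek(offset)
        return self._data.read(length)

    def get_row(self, position: int):
        """Fully decoded row; negative positions count from the end."""
        if not isinstance(position, int) or isinstance(position, bool):
            raise TypeError(f"row position must be an integer: {position!r}")
        if position < 0:
            position += self.num_rows
        if not 0 <= position < self.num_rows:
            raise IndexError(f"row position out of range for {self.num_rows} rows")
        return decode_row(self.schema, self.layout, self.raw_row(position))

    def cursor(self, columns, start: int = 0, stop: int | None = None):
        """Iterate rows ``start .. stop-1`` projected to ``columns``.

        ``columns`` is a list of column names; the interval is half-open
        and defaults to the whole table.  Only the requested columns are
        decoded.
        """
        if stop is None:
            stop = self.num_rows
        if not 0 <= start <= self.num_rows or not 0 <= stop <= self.num_rows:
            raise IndexError(
                f"cursor bounds [{start}, {stop}) out of range for "
                f"{self.num_rows} rows"
            )
        columns = list(columns)
        if not columns:
            raise SchemaError("cursor needs at least one column")
        for name in columns:  # fail fast on unknown columns
            self.schema.spec(name)
        if start >= stop:
            return iter(())
        return self._cursor_iter(columns, start, stop)

    def _cursor_iter(self, columns, start, stop):
        scan = self._rowindex.scan(position_key(start), position_key(stop))
        for _, ptr in scan:
            offset, length = unpack_row_pointer(ptr)
            self._data.seek(offset)
            row = self._data.read(length)
            yield decode_row(self.schema, self.layout, row, columns)

    # -- index registry (used by wormtable.index and the admin CLI) ----------

    @property
    def indexes(self) -> dict:
        """Registered indexes: name -> list of (column, bin_width or None)."""
        return {k: list(v) for k, v in self._indexes.items()}

    def index_path(self, name: str) -> str:
        return os.path.join(self.directory, _index_filename(name))

    def register_index(self, name: str, columns_and_widths) -> None:
        if name in self._indexes:
            raise TableStateError(f"index {name!r} already registered")
        self._indexes[name] = list(columns_and_widths)
        _write_metadata(
            os.path.join(self.directory, METADATA_FILE),
            self.num_rows, self._indexes,
        )

    def deregister_index(self, name: str) -> None:
        if name not in self._indexes:
            raise TableStateError(f"no such index: {name!r}")
        del self._indexes[name]
        _write_metadata(
            os.path.join(self.directory, METADATA_FILE),
            self.num_rows, self._indexes,
        )
        path = self.index_path(name)
        if os.path.exists(path):
            os.remove(path)

    def open_index(self, name: str):
        from .index import Index  # local import to avoid a cycle

        return Index(self, name)

    def close(self) -> None:
        self._data.close()
        self._rowindex.close()


def open_table(directory) -> Table:
    """Open a finalised table directory read-only."""
    return Table(directory)
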