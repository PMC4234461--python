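"""Table schemas: column definitions, XML (de)serialisation, row layout and
smallest-type inference.

A table's schema is an ordered list of columns.  Each column holds elements
of one type (unsigned integer, signed integer, IEEE float or character) and
a fixed element size in bytes; a column stores either a fixed number of
elements or a variable number (``VARIABLE``).  The schema is persisted as a
small XML document inside the table directory, and the byte layout of the
fixed region of every row is a pure function of the schema
(:func:`compute_layout`).
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from xml.sax.saxutils import quoteattr

from .errors import SchemaError

log = logging.getLogger(__name__)

#: Sentinel for absent values.  ``None`` keeps comparisons and defaults
#: idiomatic; the name exists so user code reads ``value is MISSING``.
MISSING = None

SCHEMA_VERSION = "1.0"

#: Bytes consumed in the fixed region by a variable-length column:
#: a 2-byte offset from the start of the row plus a 2-byte element count.
POINTER_SIZE = 4

#: Hard cap implied by the 2-byte pointer fields.
MAX_ROW_SIZE = 0xFFFF
MAX_ELEMENT_COUNT = 0xFFFF


class _Variable:
    """Singleton marking a variable element count."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "VARIABLE"


#: Distinguished ``num_elements`` value for variable-count columns.
VARIABLE = _Variable()


class ColumnType(str, Enum):
    UINT = "uint"
    INT = "int"
    FLOAT = "float"
    CHAR = "char"


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")
_INT_SIZES = frozenset(range(1, 9))
_FLOAT_SIZES = frozenset({2, 4, 8})


@dataclass(frozen=True)
class ColumnSpec:
    """Definition of one column: name, element type/size and element count.

    ``num_elements`` is a positive integer for fixed-count columns or
    :data:`VARIABLE`.  For CHAR columns an element is a single byte, so a
    fixed CHAR column of ``num_elements`` n holds an n-byte string.
    """

    name: str
    ctype: ColumnType
    element_size: int
    num_elements: object = 1
    description: str = ""

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise SchemaError(f"invalid column name: {self.name!r}")
        ctype = ColumnType(self.ctype)
        object.__setattr__(self, "ctype", ctype)
        if ctype in (ColumnType.UINT, ColumnType.INT):
            if self.element_size not in _INT_SIZES:
                raise SchemaError(
                    f"column {self.name!r}: integer element_size must be in "
                    f"1..8, got {self.element_size}"
                )
        elif ctype is ColumnType.FLOAT:
            if self.element_size not in _FLOAT_SIZES:
                raise SchemaError(
                    f"column {self.name!r}: float element_size must be "
                    f"2, 4 or 8, got {self.element_size}"
                )
        else:  # CHAR
            if self.element_size != 1:
                raise SchemaError(
                    f"column {self.name!r}: char element_size must be 1, "
                    f"got {self.element_size}"
                )
        n = self.num_elements
        if n is not VARIABLE:
            if not isinstance(n, int) or isinstance(n, bool) or n < 1:
                raise SchemaError(
                    f"column {self.name!r}: num_elements must be a positive "
                    f"integer or VARIABLE, got {n!r}"
                )
            if n * self.element_size > MAX_ROW_SIZE:
                raise SchemaError(
                    f"column {self.name!r}: fixed footprint exceeds the "
                    f"{MAX_ROW_SIZE}-byte row limit"
                )

    @property
    def is_variable(self) -> bool:
        return self.num_elements is VARIABLE

    @property
    def fixed_size(self) -> int:
        """Bytes this column occupies in the fixed region of a row."""
        if self.is_variable:
            return POINTER_SIZE
        return self.element_size * self.num_elements


@dataclass(frozen=True)
class Schema:
    """An ordered, validated collection of :class:`ColumnSpec`.

    Column order is significant: it defines both the row layout and the
    order of values in encoded/decoded tuples.
    """

    columns: tuple
    version: str = SCHEMA_VERSION

    def __post_init__(self):
        cols = tuple(self.columns)
        object.__setattr__(self, "columns", cols)
        if not cols:
            raise SchemaError("schema must contain at least one column")
        seen = set()
        for c in cols:
            if not isinstance(c, ColumnSpec):
                raise SchemaError(f"not a ColumnSpec: {c!r}")
            if c.name in seen:
                raise SchemaError(f"duplicate column name: {c.name!r}")
            seen.add(c.name)
        object.__setattr__(
            self, "_positions", {c.name: i for i, c in enumerate(cols)}
        )

    def __len__(self) -> int:
        return len(self.columns)

    def __contains__(self, name: str) -> bool:
        return name in self._positions

    @property
    def names(self) -> tuple:
        return tuple(c.name for c in self.columns)

    def spec(self, name: str) -> ColumnSpec:
        try:
            return self.columns[self._positions[name]]
        except KeyError:
            raise SchemaError(f"unknown column: {name!r}") from None

    def position(self, name: str) -> int:
        try:
            return self._positions[name]
        except KeyError:
            raise SchemaError(f"unknown column: {name!r}") from None


@dataclass(frozen=True)
class Layout:
    """Byte offsets of each column within the fixed region of a row."""

    offsets: dict
    fixed_region_size: int
    pointer_size: int = POINTER_SIZE


def compute_layout(schema: Schema) -> Layout:
    """Assign consecutive fixed-region offsets in schema order.

    A fixed-count column occupies ``element_size * num_elements`` bytes; a
    variable column occupies a 4-byte (offset, count) pointer.
    """
    offsets = {}
    off = 0
    for c in schema.columns:
        offsets[c.name] = off
        off += c.fixed_size
    if off > MAX_ROW_SIZE:
        raise SchemaError(
            f"fixed region ({off} bytes) exceeds the {MAX_ROW_SIZE}-byte row limit"
        )
    return Layout(offsets=offsets, fixed_region_size=off)


# -- XML serialisation -------------------------------------------------------
#
# Dialect:
#   <schema version="1.0">
#     <columns>
#       <column name="POS" ctype="uint" element_size="4" num_elements="1"/>
#     </columns>
#   </schema>
#
# Attribute order and indentation are fixed so equal schemas serialise to
# byte-identical documents.


def write_schema_xml(schema: Schema) -> str:
    """Serialise a schema to its canonical XML form (UTF-8 text, LF)."""
    lines = [f'<schema version={quoteattr(schema.version)}>', "  <columns>"]
    for c in schema.columns:
        n = "var" if c.is_variable else str(c.num_elements)
        attrs = (
            f"name={quoteattr(c.name)} ctype={quoteattr(c.ctype.value)} "
            f"element_size={quoteattr(str(c.element_size))} "
            f"num_elements={quoteattr(n)}"
        )
        if c.description:
            attrs += f" description={quoteattr(c.description)}"
        lines.append(f"    <column {attrs}/>")
    lines.append("  </columns>")
    lines.append("</schema>")
    return "\n".join(lines) + "\n"


def parse_schema_xml(xml_text: str) -> Schema:
    """Parse the canonical XML dialect back into a :class:`Schema`."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as e:
        raise SchemaError(f"malformed schema XML: {e}") from e
    if root.tag != "schema":
        raise SchemaError(f"unexpected root element: {root.tag!r}")
    version = root.get("version", SCHEMA_VERSION)
    columns_el = root.find("columns")
    if columns_el is None:
        raise SchemaError("schema XML missing <columns> element")
    cols = []
    for el in columns_el.findall("column"):
        name = el.get("name")
        if name is None:
            raise SchemaError("<column> missing name attribute")
        ctype = el.get("ctype")
        try:
            ctype = ColumnType(ctype)
        except ValueError:
            raise SchemaError(
                f"column {name!r}: unknown ctype {ctype!r}"
            ) from None
        try:
            element_size = int(el.get("element_size", ""))
        except ValueError:
            raise SchemaError(
                f"column {name!r}: bad element_size "
                f"{el.get('element_size')!r}"
            ) from None
        n_attr = el.get("num_elements", "1")
        if n_attr == "var":
            num_elements = VARIABLE
        else:
            try:
                num_elements = int(n_attr)
            except ValueError:
                raise SchemaError(
                    f"column {name!r}: bad num_elements {n_attr!r}"
                ) from None
        cols.append(
            ColumnSpec(
                name=name,
                ctype=ctype,
                element_size=element_size,
                num_elements=num_elements,
                description=el.get("description", ""),
            )
        )
    return Schema(columns=tuple(cols), version=version)


# -- Smallest-type inference -------------------------------------------------


@dataclass
class ColumnStats:
    """Accumulated observations about one column, driving type inference."""

    min_int: int | None = None
    max_int: int | None = None
    needs_float: bool = False
    min_len: int | None = None
    max_len: int | None = None
    min_count: int | None = None
    max_count: int | None = None
    saw_missing: bool = False
    n_values: int = 0

    def observe_int(self, v: int) -> None:
        self.n_values += 1
        self.min_int = v if self.min_int is None else min(self.min_int, v)
        self.max_int = v if self.max_int is None else max(self.max_int, v)

    def observe_float(self, v: float) -> None:
        self.n_values += 1
        self.needs_float = True

    def observe_str(self, s: str) -> None:
        self.n_values += 1
        n = len(s.encode("utf-8"))
        self.min_len = n if self.min_len is None else min(self.min_len, n)
        self.max_len = n if self.max_len is None else max(self.max_len, n)

    def observe_count(self, k: int) -> None:
        self.min_count = k if self.min_count is None else min(self.min_count, k)
        self.max_count = k if self.max_count is None else max(self.max_count, k)

    def observe_missing(self) -> None:
        self.saw_missing = True


def _smallest_uint_size(max_value: int) -> int:
    # valid uint range at size s is [0, 2^(8s) - 2]; all-zero is reserved
    for s in range(1, 9):
        if max_value <= 2 ** (8 * s) - 2:
            return s
    raise SchemaError(f"integer {max_value} too large for an 8-byte column")


def _smallest_int_size(min_value: int, max_value: int) -> int:
    # valid int range at size s is [-2^(8s-1)+1, 2^(8s-1)-1]
    for s in range(1, 9):
        lim = 2 ** (8 * s - 1) - 1
        if -lim <= min_value and max_value <= lim:
            return s
    raise SchemaError(
        f"integer range [{min_value}, {max_value}] too large for an "
        f"8-byte column"
    )


def infer_column_spec(name: str, kind_hint: str, stats: ColumnStats) -> ColumnSpec:
    """Return the smallest legal column spec covering the observed values.

    ``kind_hint`` is one of ``"int"``, ``"float"``, ``"char"`` and comes
    from the source format's declared type (e.g. a VCF header).  Integer
    columns whose observed minimum is non-negative become unsigned.  With no
    observations at all the column defaults to a 1-byte variable char.
    """
    if kind_hint not in ("int", "float", "char"):
        raise SchemaError(f"unknown kind hint {kind_hint!r}")
    if stats.n_values == 0:
        log.warning(
            "column %s: no values observed; defaulting to variable char", name
        )
        return ColumnSpec(name, ColumnType.CHAR, 1, VARIABLE)

    if stats.min_count is not None and stats.min_count == stats.max_count:
        num_elements = stats.max_count
    else:
        num_elements = VARIABLE

    if kind_hint == "char":
        if (
            stats.min_len == stats.max_len
            and stats.min_len
            and stats.max_count in (None, 1)
        ):
            return ColumnSpec(name, ColumnType.CHAR, 1, stats.min_len)
        return ColumnSpec(name, ColumnType.CHAR, 1, VARIABLE)

    if kind_hint == "float" or stats.needs_float:
        # IEEE single by default: compact without sacrificing the integer
        # exactness VCF qualities need (half is exact only to 2048).
        return ColumnSpec(name, ColumnType.FLOAT, 4, num_elements)

    if stats.min_int is None:
        return ColumnSpec(name, ColumnType.INT, 1, num_elements)
    if stats.min_int >= 0:
        return ColumnSpec(
            name, ColumnType.UINT, _smallest_uint_size(stats.max_int),
            num_elements,
        )
    return ColumnSpec(
        name, ColumnType.INT,
        _smallest_int_size(stats.min_int, stats.max_int), num_elements,
    )
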