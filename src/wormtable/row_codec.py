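"""Binary row codec: packed, big-endian, architecture-independent.

A row is a fixed region followed by a variable region.  Fixed-count
columns live entirely in the fixed region; a variable-count column stores
a 4-byte pointer there (2-byte offset from the start of the row, 2-byte
element count) and its payload in the variable region.  All multi-byte
quantities are big-endian, so a table written anywhere reads identically
everywhere.

Element encodings (``element_size`` = s):

``uint``   valid range [0, 2^(8s) - 2]; stored as value + 1.
           MISSING is the reserved all-zero pattern.
``int``    valid range [-2^(8s-1) + 1, 2^(8s-1) - 1]; stored as
           value + 2^(8s-1) (excess-K).  MISSING is all-zero.
``float``  raw IEEE 754 half/single/double big-endian bits; MISSING is the
           canonical quiet NaN (0x7E00 / 0x7FC00000 / 0x7FF8...).
``char``   raw bytes, one per element.

The integer encodings sort correctly as unsigned bytes with MISSING first,
which is what makes them directly reusable as index key material.
"""

from __future__ import annotations

import struct

from .errors import DecodingError, EncodingError, SchemaError
from .schema import (
    MAX_ELEMENT_COUNT,
    MAX_ROW_SIZE,
    MISSING,
    ColumnSpec,
    ColumnType,
    Layout,
    Schema,
)

_FLOAT_FMT = {2: ">e", 4: ">f", 8: ">d"}
FLOAT_MISSING = {
    2: b"\x7e\x00",
    4: b"\x7f\xc0\x00\x00",
    8: b"\x7f\xf8\x00\x00\x00\x00\x00\x00",
}


def uint_range(size: int) -> tuple:
    return 0, 2 ** (8 * size) - 2


def int_range(size: int) -> tuple:
    lim = 2 ** (8 * size - 1) - 1
    return -lim, lim


def encode_element(spec: ColumnSpec, value) -> bytes:
    """Encode a single element of ``spec``'s type into ``element_size`` bytes."""
    s = spec.element_size
    if spec.ctype is ColumnType.UINT:
        if value is MISSING:
            return b"\x00" * s
        _check_integral(spec, value)
        lo, hi = uint_range(s)
        if not lo <= value <= hi:
            raise EncodingError(
                f"column {spec.name!r}: value {value!r} outside valid "
                f"uint{s} range [{lo}, {hi}]"
            )
        return (value + 1).to_bytes(s, "big")
    if spec.ctype is ColumnType.INT:
        if value is MISSING:
            return b"\x00" * s
        _check_integral(spec, value)
        lo, hi = int_range(s)
        if not lo <= value <= hi:
            raise EncodingError(
                f"column {spec.name!r}: value {value!r} outside valid "
                f"int{s} range [{lo}, {hi}]"
            )
        return (value + 2 ** (8 * s - 1)).to_bytes(s, "big")
    if spec.ctype is ColumnType.FLOAT:
        if value is MISSING:
            return FLOAT_MISSING[s]
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise EncodingError(
                f"column {spec.name!r}: not a number: {value!r}"
            ) from None
        if value != value or value in (float("inf"), float("-inf")):
            raise EncodingError(
                f"column {spec.name!r}: non-finite value {value!r}"
            )
        try:
            return struct.pack(_FLOAT_FMT[s], value)
        except OverflowError:
            raise EncodingError(
                f"column {spec.name!r}: value {value!r} overflows "
                f"{s}-byte float"
            ) from None
    # CHAR: a single element is one byte
    if isinstance(value, str):
        value = value.encode("utf-8")
    if not isinstance(value, bytes) or len(value) != 1:
        raise EncodingError(
            f"column {spec.name!r}: char element must be one byte, "
            f"got {value!r}"
        )
    return value


def _check_integral(spec: ColumnSpec, value) -> None:
    if not isinstance(value, int) or isinstance(value, bool):
        raise EncodingError(
            f"column {spec.name!r}: not an integer: {value!r}"
        )


def decode_element(spec: ColumnSpec, buf: bytes):
    """Inverse of :func:`encode_element` for one element."""
    s = spec.element_size
    if len(buf) != s:
        raise DecodingError(
            f"column {spec.name!r}: expected {s} bytes, got {len(buf)}"
        )
    if spec.ctype is ColumnType.UINT:
        u = int.from_bytes(buf, "big")
        return MISSING if u == 0 else u - 1
    if spec.ctype is ColumnType.INT:
        u = int.from_bytes(buf, "big")
        return MISSING if u == 0 else u - 2 ** (8 * s - 1)
    if spec.ctype is ColumnType.FLOAT:
        if buf == FLOAT_MISSING[s]:
            return MISSING
        return struct.unpack(_FLOAT_FMT[s], buf)[0]
    return buf.decode("utf-8")


# -- whole-cell helpers ------------------------------------------------------


def _as_element_tuple(spec: ColumnSpec, value, n: int) -> tuple:
    """Normalise a cell value to a tuple of n scalar elements."""
    if value is MISSING:
        return (MISSING,) * n
    if isinstance(value, (tuple, list)):
        if len(value) != n:
            raise EncodingError(
                f"column {spec.name!r}: expected {n} elements, "
                f"got {len(value)}"
            )
        return tuple(value)
    if n == 1:
        return (value,)
    raise EncodingError(
        f"column {spec.name!r}: expected a sequence of {n} elements, "
        f"got scalar {value!r}"
    )


def _encode_char_payload(spec: ColumnSpec, value) -> bytes:
    if isinstance(value, str):
        return value.encode("utf-8")
    if isinstance(value, bytes):
        return value
    raise EncodingError(
        f"column {spec.name!r}: char value must be a string, got {value!r}"
    )


def _encode_fixed_cell(spec: ColumnSpec, value) -> bytes:
    n = spec.num_elements
    if spec.ctype is ColumnType.CHAR:
        if value is MISSING:
            return b"\x00" * n
        data = _encode_char_payload(spec, value)
        if len(data) != n:
            raise EncodingError(
                f"column {spec.name!r}: fixed char value must be exactly "
                f"{n} bytes, got {len(data)} ({value!r})"
            )
        if b"\x00" in data:
            raise EncodingError(
                f"column {spec.name!r}: NUL byte in fixed char value "
                f"(reserved for MISSING)"
            )
        return data
    elems = _as_element_tuple(spec, value, n)
    return b"".join(encode_element(spec, e) for e in elems)


def _encode_var_payload(spec: ColumnSpec, value) -> tuple:
    """Return (payload bytes, element count) for a variable column."""
    if value is MISSING:
        return b"", 0
    if spec.ctype is ColumnType.CHAR:
        data = _encode_char_payload(spec, value)
        return data, len(data)
    if not isinstance(value, (tuple, list)):
        value = (value,)
    if len(value) == 0:
        return b"", 0
    return (
        b"".join(encode_element(spec, e) for e in value),
        len(value),
    )


def encode_row(schema: Schema, layout: Layout, values) -> bytes:
    """Encode one value per column into the packed row representation."""
    if len(values) != len(schema):
        raise EncodingError(
            f"expected {len(schema)} values, got {len(values)}"
        )
    fr = layout.fixed_region_size
    fixed = bytearray(fr)
    var = bytearray()
    for spec, value in zip(schema.columns, values):
        off = layout.offsets[spec.name]
        if spec.is_variable:
            payload, count = _encode_var_payload(spec, value)
            if count == 0:
                continue  # pointer stays (0, 0)
            if count > MAX_ELEMENT_COUNT:
                raise EncodingError(
                    f"column {spec.name!r}: {count} elements exceeds the "
                    f"{MAX_ELEMENT_COUNT}-element limit"
                )
            start = fr + len(var)
            if start + len(payload) > MAX_ROW_SIZE:
                raise EncodingError(
                    f"row exceeds the {MAX_ROW_SIZE}-byte limit"
                )
            fixed[off:off + 2] = start.to_bytes(2, "big")
            fixed[off + 2:off + 4] = count.to_bytes(2, "big")
            var += payload
        else:
            fixed[off:off + spec.fixed_size] = _encode_fixed_cell(spec, value)
    row = bytes(fixed) + bytes(var)
    if len(row) > MAX_ROW_SIZE:
        raise EncodingError(f"row exceeds the {MAX_ROW_SIZE}-byte limit")
    return row


def _decode_cell(spec: ColumnSpec, layout: Layout, row: bytes):
    off = layout.offsets[spec.name]
    if spec.is_variable:
        start = int.from_bytes(row[off:off + 2], "big")
        count = int.from_bytes(row[off + 2:off + 4], "big")
        if start == 0 and count == 0:
            return MISSING
        end = start + count * (
            1 if spec.ctype is ColumnType.CHAR else spec.element_size
        )
        if start < layout.fixed_region_size or end > len(row):
            raise DecodingError(
                f"column {spec.name!r}: corrupt pointer "
                f"(offset={start}, count={count}, row={len(row)} bytes)"
            )
        if spec.ctype is ColumnType.CHAR:
            return row[start:end].decode("utf-8")
        s = spec.element_size
        return tuple(
            decode_element(spec, row[i:i + s]) for i in range(start, end, s)
        )
    n = spec.num_elements
    buf = row[off:off + spec.fixed_size]
    if spec.ctype is ColumnType.CHAR:
        if buf == b"\x00" * n:
            return MISSING
        return buf.decode("utf-8")
    s = spec.element_size
    elems = tuple(
        decode_element(spec, buf[i * s:(i + 1) * s]) for i in range(n)
    )
    return elems[0] if n == 1 else elems


def decode_row(schema: Schema, layout: Layout, row: bytes, columns=None):
    """Decode ``columns`` (a list of names, or ``None`` for all) from a row.

    Only the bytes of the requested columns are touched, which is what
    makes projected cursors cheap.
    """
    if len(row) < layout.fixed_region_size:
        raise DecodingError(
            f"row too short: {len(row)} < fixed region "
            f"{layout.fixed_region_size}"
        )
    if columns is None:
        specs = schema.columns
    else:
        specs = tuple(schema.spec(name) for name in columns)
    return tuple(_decode_cell(spec, layout, row) for spec in specs)
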