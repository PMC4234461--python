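# On-disk format, bit-exact

This document is normative for the format this package reads and writes.
All multi-byte integers are big-endian everywhere, so table directories
are byte-identical across operating systems and hardware architectures.

## Table directory

| file             | contents                                                      |
|------------------|---------------------------------------------------------------|
| `schema.xml`     | column definitions (dialect below)                            |
| `rows.dat`       | encoded rows stored back to back, in insertion order          |
| `rowindex.db`    | ordered KV store: row position → row pointer                  |
| `metadata.xml`   | format version, `num_rows`, registered indexes and bin widths |
| `index_<name>.db`| one ordered KV store per secondary index                      |

Row-index entries: key = 8-byte row position (0-based, dense), value =
8-byte data-file offset ++ 4-byte row length (12 bytes total).

The KV stores are SQLite files (table `kv(k BLOB, v BLOB)` ordered by
`(k, v)`); any engine that iterates byte-string keys in ascending
lexicographic order with duplicate keys would serve.

## Schema XML dialect

```xml
<schema version="1.0">
  <columns>
    <column name="POS" ctype="uint" element_size="4" num_elements="1"/>
    <column name="ALT" ctype="char" element_size="1" num_elements="var"/>
  </columns>
</schema>
```

`ctype` ∈ {`uint`, `int`, `float`, `char`}; `element_size` in bytes
(uint/int 1–8, float 2/4/8 = IEEE 754 half/single/double, char 1);
`num_elements` a positive integer or `var`. Document order is column
order. Attribute order and indentation are fixed: equal schemas
serialise to identical bytes.

## Row encoding

A row is a **fixed region** followed by a **variable region** and may not
exceed 65,535 bytes.

Fixed region, in schema order:

* fixed-count column: `element_size × num_elements` bytes of element
  encodings;
* variable-count column: a 4-byte pointer — 2-byte offset from the start
  of the row, 2-byte element count. The empty/missing value is the
  pointer `(0, 0)`.

Variable-region payloads follow in schema order, unpadded, at the
offsets the pointers name. A pointer must satisfy
`offset ≥ fixed_region_size` and `offset + count·element_size ≤ row length`.

### Element encodings (size `s` bytes)

| type  | valid values                      | stored as                     | MISSING            |
|-------|-----------------------------------|-------------------------------|--------------------|
| uint  | `[0, 2^(8s) − 2]`                 | value + 1                     | all-zero bytes     |
| int   | `[−2^(8s−1) + 1, 2^(8s−1) − 1]`   | value + `2^(8s−1)` (excess-K) | all-zero bytes     |
| float | finite IEEE half/single/double    | raw big-endian bit pattern    | canonical quiet NaN: `0x7E00` / `0x7FC00000` / `0x7FF8000000000000` |
| char  | any byte                          | raw byte                      | (see below)        |

The integer bias costs one value of range per size and makes the stored
bytes sort as unsigned with MISSING first — the same bytes double as
index-key material. A fixed-length char cell that is entirely `0x00`
bytes decodes as MISSING (NUL bytes are rejected inside fixed char
values). For variable-length columns the `(0, 0)` pointer means MISSING;
an empty string or empty tuple is therefore indistinguishable from
MISSING and decodes as MISSING.

### Worked example

Schema `[a: uint2×1, b: char var, c: float4×2]`, values
`(5, "AC", (1.0, MISSING))`:

```
00 06 | 00 0E 00 02 | 3F 80 00 00  7F C0 00 00 | 41 43
 a=6    b→(14,2)      c = 1.0f     c = qNaN      "AC"
```

16 bytes: fixed region 14, payload `"AC"` at offset 14.

## Index keys

An index entry's key is the concatenation of per-column encodings; the
value is the 8-byte row position. Byte order of keys equals value order
of the key tuples (MISSING first):

* uint/int: the element encodings above, unchanged;
* float: the IEEE bits with the sign bit set if non-negative, otherwise
  all bits inverted; MISSING is all-zero;
* fixed-length char: raw bytes;
* variable-length char: raw bytes plus a `0x00` terminator (embedded
  NULs are rejected for indexed columns), which preserves prefix order
  (`"2" < "2L"`) under concatenation;
* binned column (`width w`): `floor(value / w)` encoded as an 8-byte
  signed integer whatever the source type;
* multi-element cells: element encodings concatenated. A variable-count
  numeric column is only permitted as the last key column (its extent is
  otherwise not recoverable from the key).

`metadata.xml` records each index's key columns and bin widths; the
store lives in `index_<name>.db` with `<name>` = key columns joined by
`+`.
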