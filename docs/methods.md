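# Methods and design notes

## The storage model

The package implements a write-once read-many (WORM) store for tabular
data: a table is built exactly once, sealed, and thereafter only read.
This discipline matches how genomic datasets are actually used — a VCF
or GTF is produced by a pipeline and then analysed, never edited in
place — and it buys immutability, trivially safe concurrent readers and
full portability: a table directory can be copied anywhere and opened.

A row is encoded as a fixed region and a variable region
(docs/FORMAT.md gives the bit-exact layout). Fixed-count columns live
entirely in the fixed region at schema-determined offsets, so a reader
can decode any single column of any row without touching the rest of the
row — this is what makes projected cursors cheap. Variable-count columns
put a 4-byte (offset, count) pointer in the fixed region and their
payload in the variable region. The 2-byte pointer fields cap a row at
65,535 bytes and a cell at 65,535 elements; realistic VCF/GTF rows are
two orders of magnitude below this, and the builder fails loudly on
overflow rather than truncating.

All integer encodings are biased (unsigned: value+1; signed: excess-K)
so that the all-zero byte pattern is free to mean MISSING and the stored
bytes sort as unsigned with MISSING first. The same bytes therefore
serve unchanged as index-key material. Floats are raw IEEE 754
half/single/double bits with a canonical quiet NaN as MISSING. Choosing
big-endian everywhere makes encode deterministic and table files
byte-identical across architectures; a golden-byte test pins the format.

One representational consequence is documented rather than worked
around: for variable-length columns the empty value and MISSING share
the (0, 0) pointer and both decode as MISSING. VCF's own missing marker
("." ) maps onto this cleanly.

## Storage engine

Row pointers and index entries need only an ordered byte-string
key-value map with duplicate keys, point lookups and range scans. That
contract — not any particular engine — is what the design depends on,
and it is stated executably as the in-memory reference backend
(`MemoryKVStore`, a sorted list). The on-disk backend is SQLite: a
`(k BLOB, v BLOB)` table with a composite index, since SQLite compares
BLOBs by memcmp, which is exactly the required order, and it ships with
the standard library. Ordering by `(k, v)` makes duplicate keys come
back in ascending row-position order with no extra bookkeeping.

## Indexes

An index key is the concatenation of per-column order-preserving
encodings; correctness rests on the invariant that byte order of keys
equals value order of key tuples. The non-obvious cases:

* **floats** use the standard bit trick (invert all bits when negative,
  else set the sign bit);
* **variable-length strings** are NUL-terminated so that `"2" < "2L"`
  survives concatenation with following columns; embedded NUL bytes in
  indexed strings are rejected at build time (with the offending row
  position) rather than silently mis-sorting;
* **bins** map a value to `floor(value / width)` — bin `b` covers
  `[b·w, (b+1)·w)`, which keeps negative values and negative bins exact
  — and encode the bin id as an 8-byte signed integer regardless of
  source type, so partial-key arithmetic is uniform;
* **MISSING sorts before every present value** (the all-zero pattern),
  consistently between the row codec and the key codec;
* a **variable-count numeric column** has no delimiter inside the key,
  so it is only accepted as the last key column; variable strings are
  fine anywhere (the terminator delimits them).

Range cursors realise partial keys by encoding the value prefix and
comparing bytes: `key ≥ enc(start)` and `key < enc(stop)`, a half-open
interval. On a (CHROM, POS) index the common "all rows within 1 kb of a
locus" query is then a single contiguous scan. Keys of a binned index
*are* bin ids: `keys()`, `histogram()` and `key_count()` speak bin ids,
while cursor bounds take raw values and are binned before encoding.

Index ordering, range queries and histograms are tested against a
brute-force oracle that sorts and filters decoded values directly and
knows nothing about the byte encodings.

## Converters and type inference

`vcf2wt` runs two passes: the first accumulates per-column statistics
(integer extrema, string lengths, element counts, undeclared INFO keys),
the second builds the table with the smallest legal type per column —
an integer column whose observed minimum is non-negative becomes
unsigned, and the size is minimal given that one value of range is
reserved for MISSING (observed max 200 fits one unsigned byte because
uint1 covers [0, 254]). Float columns default to IEEE single rather
than half: VCF quality scores routinely exceed 2048, the largest integer
half represents exactly; half is available per column for data known to
be coarse. A `--single-pass` mode trades storage (8-byte integers) for
one less scan. INFO keys present in the data but absent from the header
are added as variable char columns rather than rejected.

Flat dot-separated column naming (`INFO.DP`, `NA0001.GT`) keeps the
schema one-level and unambiguous. Multi-valued string fields — ALT above
all — are stored as the comma-joined source text (a char element is one
byte), while multi-valued numeric fields (`Number=A` and friends) are
stored as variable-count element tuples; genotypes stay strings, since
column access rather than genotype semantics is the point of the store.
VCF positions remain 1-based; GTF coordinates remain 1-based inclusive;
no coordinate convention is ever shifted.

The transition/transversion counter classifies each alternate allele of
each row: single-base A/C/G/T pairs only, {A,G} and {C,T} transitions,
every other base pair a transversion; indels and symbolic alleles are
skipped. The same classification is computed two independent ways — a
(REF, ALT) column scan, and a REF+ALT index histogram weighting each
distinct key by its count — and the two must agree, which the tests and
the acceptance script both check.

## Synthetic data

The generators in `wormtable.fixtures` produce format-level toy data,
deterministically from a seed. The toy VCF has 100 rows over three
chromosome arms with three samples and five INFO fields by default
(depth, mapping quality, per-allele frequency and count, a flag):
positions strictly increasing per chromosome, ~85% SNPs with occasional
indels and multi-allelic sites, sporadic missing values in QUAL/ID/
FILTER/FORMAT fields. The toy GTF nests gene → transcript → exon/CDS
blocks. `random_table` draws schemas across every type, size and element
count and deliberately oversamples the codec's edges (range extrema,
MISSING, variable-length payloads), since uniform sampling almost never
hits the reserved patterns.

What the toys do not emulate: linkage structure, realistic allele
frequencies, genotype consistency, header pathologies of real-world VCF
emitters, or multi-gigabyte scale. Passing tests therefore demonstrate
format-level correctness (parsing, encoding, ordering, querying), not
population-genetic realism or out-of-core performance.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so the
whole suite completes in seconds while still exercising every code path:
10³ random tables for codec round-trips, 100 tables (up to ~120 rows
each) for the index order/range oracles, 10⁴ (value, width) pairs for
bin containment, and 100 random 1 kb windows against a 10,000-row
converted VCF. Floating-point fixture values are quarter-integers, which
are exactly representable at half, single and double precision, so
round-trip comparisons are exact rather than tolerance-based; conversion
fidelity for floats parsed from decimal text is compared at relative
1e-6 (single precision carries ~7 significant digits). Binning uses
Python's `math.floor` on the quotient; for integer values and widths the
division is exact integer floor division.

## Known limitations

* No interval/overlap search: a (CHROM, POS) index answers point-anchored
  windows, not "all features overlapping [a, b]" for spanning features.
* No compression of the data file, and no checksums beyond the format
  version in the metadata.
* Single writer, no concurrent build; tables are immutable after
  `finalise`, and only index registration may change afterwards
  (via `wtadmin add`/`rm`).
* Empty string vs MISSING is not distinguishable in variable-length
  columns (see above).
* The converters cover VCF 4.x and GTF; BCF and other formats are out of
  scope.
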