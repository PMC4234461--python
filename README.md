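# wormtable

A write-once read-many (WORM) binary table store for genome-scale tabular
data, with converters for VCF and GTF.

Most genomic data lives in tab-delimited text (a VCF of variant calls, a
GTF of gene annotations). Text is portable but every analysis pays the
full cost of parsing it, line by line, and there is no general way to
jump to the rows with a particular value in a particular column. This
package converts such files once into a compact, portable binary table —
values stored in native machine form, each column given the smallest
type that covers its observed values — and then provides:

* **random access to rows** through an ordered key-value row index
  (tables implement the Python sequence protocol);
* **projected cursors**: iterate only the columns you need over a
  half-open row range, decoding nothing else;
* **secondary indexes over arbitrary column combinations**, built from
  order-preserving byte encodings so that range queries, key iteration,
  exact-key counting and histograms are plain prefix scans of a B-tree
  style store;
* **binned indexes**: a column may be indexed by `floor(value / w)`, so
  a histogram of, say, quality scores at resolution `w` costs one scan
  of the distinct keys.

A table is an ordinary directory (data file + key-value databases + XML
schema) that can be copied between machines; every multi-byte quantity
is big-endian, so the bytes are identical on any architecture. The full
bit-level format is in [docs/FORMAT.md](docs/FORMAT.md) and the design
notes in [docs/methods.md](docs/methods.md).

## Worked example

```sh
$ make-fixtures demo --seed 1 --rows 100     # writes demo/toy.vcf, demo/toy.gtf
$ vcf2wt demo/toy.vcf demo/toy.wt
wrote 100 rows to demo/toy.wt
$ wtadmin add demo/toy.wt CHROM+POS
$ wtadmin ls demo/toy.wt
table: demo/toy.wt  rows: 100
CHROM+POS	(CHROM, POS)	100 entries
```

Count transitions and transversions by scanning just the REF and ALT
columns, then seek into a 200 kb window on chromosome arm 2L:

```python
import wormtable as wt

t = wt.open_table("demo/toy.wt")
print(wt.count_transitions_transversions(t))
# (30, 69)

idx = t.open_index("CHROM+POS")
for chrom, pos, ref, alt in idx.cursor(
    ["CHROM", "POS", "REF", "ALT"],
    start=("2L", 100_000), stop=("2L", 300_000),
):
    print(chrom, pos, ref, alt)
# 2L 125398 C A
# 2L 158476 G A
# ...
# 2L 297199 G C
```

The first result is the (transitions, transversions) pair over all 100
sites — each alternate allele of a multi-allelic site classified on its
own, indels skipped. The cursor then returns exactly the rows with
`CHROM == "2L"` and `100000 <= POS < 300000`, in ascending position,
without touching the rest of the table: the index key for (CHROM, POS)
is an order-preserving byte string, so the window is one contiguous key
range. The same counts can be had without any scan at all from a
`REF+ALT` index histogram (`wt.count_ts_tv_from_index`).

`wtadmin` also offers `show` (schema), `dump` (rows as TSV, `.` for
missing), `hist` (key histogram of an index) and `rm` (drop an index).

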