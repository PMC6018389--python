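# bon-format

**Biological Object Notation (BON)** — a block-structured container for
biological data built on JSON syntax, with *selective* per-attribute
compression and a streaming reader.

Biological data still travels mostly as flat files (FASTA, FASTQ, Newick)
whose metadata conventions are ad hoc and whose parsers are therefore
fragile — the classic example being FASTQ, where a quality line may begin
with `@`, the very character that marks a new record. XML alternatives
(TinySeq, NeXML) are unambiguous but drown the data in markup. BON keeps
the data/metadata separation of structured formats while staying as easy
to parse as JSON, and lets you compress exactly the values that are large
(sequences, quality strings, whole trees) while the names and metadata
remain readable mid-stream — so a pipeline can filter a data set while
receiving it, without temporary files.

## The format

A BON stream is a concatenation of **blocks**. Each block is a JSON
*header* object followed immediately by a JSON *payload* array of
records:

```
{"size":2,"data":{"readid":0,"sequence":1,...}}[{...},{...}]
```

* `size` — number of top-level payload objects (nested objects excluded).
* `data` — one entry per attribute occurring in the payload; the value is
  `1` when that attribute's values are stored compressed, `0` otherwise.
* Further header attributes are free-form metadata.

The header/payload junction reads `}[` and consecutive blocks abut as
`]{`; neither is valid JSON, which makes them cheap block signals. The
stream as a whole is deliberately *not* valid JSON, but each header and
each payload is, and BON never stores a newline. Compressed values are
zlib streams (RFC 1950, level 6 by default) encoded as standard base64
(RFC 3548) — a 33% size tax on the compressed bytes in exchange for a
plain-text container.

The package converts to and from TinySeq-style XML, FASTQ and FASTA for
sequence records, and Newick/NeXML for phylogenetic trees, which are
encoded as explicit vertex/edge graphs (edge: `id`, `source`, `target`
plus free metadata; vertex: `id`, `name`, `branch_length` on the child
vertex of each branch). A deterministic synthetic-fixture generator and a
file-size accounting module (data-to-file ratio, whole-file gzip
comparison) round out the toolkit.

## Worked example

```python
from bon import serialize_block
from bon.seq import fastq_to_bon
from bon.stream import peek_headers, iter_objects

fastq = "@r1 spot=1\nACGT\n+\n@AAA\n@r2 spot=2\nGGGGCCCC\n+\nIIIIIIII\n"
text = serialize_block(fastq_to_bon(fastq))
print(text)
```

prints (one line, no newlines anywhere):

```
{"size":2,"data":{"readid":0,"spotid":0,"sequence":1,"quality":1,"length":0}}[{"readid":"r1","spotid":"1","sequence":"eJxzdHYPAQACswEg","quality":"eJxzcHR0BAACigEE","length":4},{"readid":"r2","spotid":"2","sequence":"eJxzd3d3dwYCAAncAik=","quality":"eJzz9IQAAApMAkk=","length":8}]
```

Note the first read's quality string `@AAA`: in FASTQ that leading `@` is
a parsing trap; in BON it is just a value. The header says two records
follow and that `sequence` and `quality` are compressed (`1`), the rest
verbatim (`0`). Reading it back:

```python
(header,) = peek_headers(text)          # header only, nothing decompressed
for block_idx, obj in iter_objects(text, decode=True):
    print(block_idx, obj)
# 0 {'readid': 'r1', 'spotid': '1', 'sequence': 'ACGT', 'quality': '@AAA', 'length': 4}
# 0 {'readid': 'r2', 'spotid': '2', 'sequence': 'GGGGCCCC', 'quality': 'IIIIIIII', 'length': 8}
```

The same works from the shell, streaming through pipes:

```sh
bon fixtures --kind fastq --n 1000 - \
    | bon convert --from fastq --to bon --compress sequence,quality - - \
    | bon validate -
# OK: 1 block(s), 1000 object(s)
```

`bon inspect` prints headers without touching payloads, `bon stats`
reports file bytes, data bytes, data-to-file ratio and the `gzip -6` size
of any supported file.

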