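# Methods

## The container model

A BON stream is a sequence of blocks; a block is a JSON header object
abutting a JSON payload array with no separator. Two consequences drive
the whole design:

* the junctions `}[` (header→payload) and `]{` (payload→next header) are
  not valid JSON, so they double as block signals;
* each part *is* valid JSON on its own, so any JSON parser can read a
  header or a payload once the stream is split.

The header is self-describing: `size` counts the top-level payload
objects (nested objects — e.g. a tree stored under a `tree` attribute —
are not counted), and `data` enumerates **every** attribute occurring in
the payload with a 0/1 compression flag, not only the compressed ones.
We chose "list all" because it makes the header a complete vocabulary of
the payload: a reader can decide from the header alone whether a stream
is worth decoding. Payload objects may have heterogeneous key sets; the
header takes the union in first-seen order.

Serialization is deterministic and compact: no whitespace, header keys
in canonical order (`size`, `data`, extras in insertion order), JSON
strings with ASCII escaping. No serialized byte is ever a newline; the
no-newline rule also applies to the *values* themselves (converters strip
line breaks from wrapped sources), and `validate_block` enforces it.

## Selective compression codec

A flagged value is compressed as a zlib stream (RFC 1950) and wrapped in
standard base64 (RFC 3548, with padding). The zlib level defaults to 6
and is exposed on `CompressionSpec` (1–9). Text is UTF-8 encoded before
compression; nested structures (the tree graph) are serialized as compact
JSON first, so decoding can re-parse them. base64 output length is
exactly `4·⌈n/3⌉` for an `n`-byte zlib stream — a 33% overhead, the price
of keeping the container plain text.

Decoding distinguishes failure modes: `Base64DecodeError` (bad alphabet
or padding — transport corruption) vs `ZlibDecodeError` (valid base64,
corrupt stream), both carrying attribute name and object/block indices.

Two pragmatic choices, both consequences of the format carrying no type
marker for compressed values:

* **Double-compression refusal** is heuristic: a string that decodes as
  base64 *and* inflates as zlib is treated as already compressed and
  refused. A natural value passing both tests is astronomically unlikely.
* **Re-parsing after decompression** happens only when the decompressed
  text starts with `{` or `[`. A compressed *plain string* that is itself
  JSON text would therefore come back as a structure, not a string. Known
  limitation; none of the converters produce such values.

## Streaming scanner

Block boundaries are found by an incremental JSON-aware scanner, not by
splitting on the `}[` / `]{` substrings: the signal characters are only
guaranteed unique outside string values (they cannot occur in base64),
but a defline or other metadata string may legally contain them. The
scanner decodes one JSON value at a time (header object, then payload
objects one by one inside the array) with the standard library's
incremental decoder, carrying state across chunk edges; input is read in
configurable chunks (default 64 KiB) from a path, pipe or in-memory
text, and memory is bounded by one payload object plus the buffer. On
streams whose values are free of the signals, the scanner's boundaries
coincide with plain substring search — the property the shell one-liner
recipe relies on, and a tested invariant.

Strictness: nothing may appear between blocks; a single trailing newline
(text-editor artifact) is tolerated by default and rejectable. Truncated
input reports the last complete block index and the byte offset where
scanning stopped. A header whose `size` disagrees with the payload length
is a validation error naming the block. Blocks and stream-level
documents use the same `]{` junction and are treated uniformly.

`peek_headers` skims payloads by parsing their JSON tokens without ever
base64/zlib-decoding a value; it does not byte-skip without parsing.

## Sequence converters

**TinySeq.** One payload object per entry, keys `seqtype`, `accver`,
`taxid`, `orgname`, `defline`, `length`, `sequence` — the XML naming
scheme minus the `TSeq_` prefix, with the sequence type promoted from an
XML tag attribute to an ordinary key. `taxid` and `length` are JSON
numbers. Line breaks inside XML sequence text are stripped. Default
compression: `{sequence}`.

**FASTQ.** Keys `readid`, `spotid`, `sequence`, `quality`, `length`;
default compression `{sequence, quality}`. Parsing is length-guarded:
sequence lines are accumulated until the `+` separator, then quality
characters until their count equals the sequence length — so a quality
line starting with `@` is never misread as a record start, and wrapped
records parse identically to unwrapped ones. Quality characters outside
ASCII 33–126 and length mismatches are format errors naming the read.
The description line is split as: token up to the first space → `readid`;
a `spot=`/`spot:` token in the remainder → `spotid`, else the whole
remainder. The writer emits `@readid spot=spotid`, so round-trips are
lossless for whitespace-free spot ids (the generator's case); a spot id
containing spaces survives BON→FASTQ→BON only as the full-remainder
fallback.

## Tree graph encoding

A tree is two sets: vertices (`id`, optional `name`, optional
`branch_length`) and edges (`id`, `source`, `target`, free metadata).
Ids are assigned by preorder traversal (`v0…`, `e0…`) so output is
byte-stable. Branch lengths sit on the **child vertex** of each branch;
`PhyloGraph.to_dict(lengths_on="edges")` emits the edge-centric
convention instead (NeXML's), and the reader accepts either, as well as
the spaced spelling `"branch length"`. Validation enforces tree-ness
(unique ids, `|E| = |V|−1`, one root, single parents, connectivity, no
cycles); `arg=True` relaxes to a rooted connected DAG so ancestral
recombination graphs — recombination vertices with two parents, edges
carrying e.g. breakpoint positions — are representable. No ARG inference
is performed.

In a BON payload each object is one tree: `tree` holds the graph (the
default compression target) and sibling keys are tree-level metadata
that stays readable while the tree is compressed. Newick and NeXML
parsing/writing are delegated to dendropy; round-trip fidelity is
checked in the tests by Robinson–Foulds distance (must be 0) and total
branch length (conserved to 1e−9), which exercises our graph encoding
against dendropy's independent bipartition machinery.

## Synthetic fixtures

Generators for FASTQ, TinySeq XML and random trees are deterministic in
`(seed, config)`. Defaults: 100 records of 50–150 nt, uniform residues,
quality uniform over ASCII 33–126, 10% of reads with a quality string
forced to start with `@`, 10% line-wrapped; trees by successive random
joins with branch lengths uniform on [0.001, 1] rounded to 6 decimals
(so text round-trips are exact). `repeat_rich=True` switches to tandem
`ACGT` repeats, the regime where per-value zlib pays off clearly.

What the fixtures do *not* emulate: realistic base composition, quality
profiles correlated with position or instrument, long-read length
distributions, taxon-name conventions, or tree shapes from real
inference. Passing tests therefore demonstrate format correctness and
the *direction* of size effects, not the compression percentages one
would measure on full-size public-archive corpora.

## Size accounting

`measure` reports file bytes, data bytes and their ratio. Data bytes are
the on-disk characters of the designated data attributes (default
`sequence`, `quality`, `tree`): residues for FASTQ/FASTA, element text
with whitespace stripped for XML (the wrapping newlines are clutter, not
data), and for BON the value as stored — base64 length for compressed
values, so the ratio reflects the true on-disk trade-off. XML attribute
values inside tags are not counted as data.

`gzip_whole` reproduces `gzip -c -6 FILE | wc -c` with the zlib library:
same deflate parameters, gzip container with the stored file name, mtime
and Unix OS byte. The two implementations emit identical bytes while the
compressed stream stays within their common block-split regime (our
default-size fixtures, up to roughly tens of kilobytes of compressed
output; several hundred kilobytes for repetitive input); past that their
deflate block decisions diverge and sizes differ by well under 0.1%.
Both behaviours are pinned by tests.

On repeat-rich corpora the expected ordering holds and is asserted:
whole-file gzip < selectively compressed BON < uncompressed BON — the
per-value base64 tax and the smaller compression window are exactly what
whole-file compression does not pay, while only BON remains parseable
mid-stream.

## Problem sizes and numerical choices

The acceptance computations use: 3,000 random bytes (base64 overhead),
1,000 random byte strings ≤512 B (codec round-trip), 200 random blocks
with signal-character values (stream round-trip), 10,000 FASTQ reads
with 10% adversarial quality lines, 100 random trees of 10–500 leaves
(RF = 0, branch-length error < 1e−9), and a 50,000-record repeat-rich
nucleotide corpus of 120–240 nt (size ordering). All randomness is
seeded; the acceptance script derives sub-seeds from a single `--seed`.

Other numerical choices: zlib level fixed at 6 unless overridden;
branch-length comparisons at 1e−9 (well above float64 noise for sums of
hundreds of terms, well below the 6-decimal fixture resolution); header
flag values restricted to exactly 0/1; UTF-8 everywhere.

## Known limitations

* No random access or block index; streams are read forward only.
* No checksums; corruption is detected only where it breaks JSON, base64
  or zlib framing.
* `peek_headers` is O(stream) — it parses payload tokens even though it
  decodes nothing.
* The FASTQ spot-id split is a convention, not a standard; see above.
* Binary payloads are supported only via the base64 text path; there is
  no binary container variant.
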