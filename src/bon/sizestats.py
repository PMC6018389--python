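"""File-size accounting: byte counts, data-to-file ratio, gzip comparison.

The data-to-file ratio separates *data* — the characters of the
designated biological values (sequence, quality, tree) as they appear on
disk — from *clutter*: syntax, tags, keys, line breaks.  The higher the
ratio, the leaner the format.  For compressed BON the data bytes are the
base64 characters actually stored, so the ratio reflects the on-disk
trade-off (zlib shrinks the value, base64 adds a third back).

``gzip_whole`` reproduces the byte count of the shell pipeline
``gzip -c -6 FILE | wc -c`` exactly: same deflate stream, same header
fields (stored file name, mtime, OS byte).
"""

from __future__ import annotations

import gzip
import io
import json
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from . import seq as _seq
from . import stream as _stream
from .errors import FormatError

#: Attribute names whose values count as biological data by default.
DEFAULT_DATA_KEYS = frozenset({"sequence", "quality", "tree"})

VARIANTS = ("source", "bon_uncompressed", "bon_compressed", "gzip_whole")


@dataclass(frozen=True)
class SizeReport:
    """Byte accounting for one file in one variant."""

    file_bytes: int
    data_bytes: int
    ratio: float
    variant: str

    def __post_init__(self) -> None:
        if not 0 <= self.data_bytes <= self.file_bytes:
            raise ValueError(
                f"data_bytes {self.data_bytes} outside [0, file_bytes={self.file_bytes}]")


def _read(source: str | Path) -> tuple[bytes, str]:
    if isinstance(source, Path):
        data = source.read_bytes()
    else:
        data = source.encode("utf-8")
    return data, data.decode("utf-8")


def sniff_format(text: str) -> str:
    """Guess the format from the first non-blank character."""
    head = text.lstrip()[:1]
    if head == "@":
        return "fastq"
    if head == "<":
        return "tinyseq"
    if head == "{":
        return "bon"
    if head == ">":
        return "fasta"
    raise FormatError("cannot sniff format: unrecognized leading character")


def _json_value_len(value: Any) -> int:
    if isinstance(value, str):
        return len(value)
    return len(json.dumps(value, separators=(",", ":"), ensure_ascii=True))


def _data_bytes(text: str, fmt: str, data_keys: frozenset[str]) -> int:
    if fmt == "fastq":
        total = 0
        for rec in _seq.parse_fastq(text):
            if "sequence" in data_keys:
                total += len(rec.sequence)
            if "quality" in data_keys:
                total += len(rec.quality)
        return total
    if fmt == "tinyseq":
        # Element text of the data fields, whitespace stripped: the
        # residues themselves, not the line breaks Entrez inserts.
        total = 0
        if "sequence" in data_keys:
            for m in re.finditer(r"<TSeq_sequence>(.*?)</TSeq_sequence>", text, re.DOTALL):
                total += len(re.sub(r"\s+", "", m.group(1)))
        return total
    if fmt == "bon":
        total = 0
        for _, obj in _stream.iter_objects(text, decode=False):
            for key in data_keys:
                if key in obj:
                    total += _json_value_len(obj[key])
        return total
    if fmt == "fasta":
        total = 0
        for line in text.splitlines():
            if not line.startswith(">"):
                total += len(line.strip())
        return total
    raise FormatError(f"unknown format {fmt!r}")


def gzip_whole(source: str | Path, level: int = 6) -> int:
    """Byte size of the gzip stream of the whole file at the given level.

    Matches ``gzip -c -<level> FILE | wc -c`` byte-for-byte: the header
    stores the file's base name and mtime and the Unix OS marker, and the
    deflate payload is the same zlib stream the command produces.
    """
    if isinstance(source, Path):
        data = source.read_bytes()
        name = source.name
        mtime = int(os.stat(source).st_mtime)
    else:
        data = source.encode("utf-8")
        name, mtime = None, 0
    buf = io.BytesIO()
    with gzip.GzipFile(filename=name or "", fileobj=buf, mode="wb",
                       compresslevel=level, mtime=mtime) as fh:
        fh.write(data)
    out = bytearray(buf.getvalue())
    out[9] = 0x03  # OS byte: Unix, as the command-line tool writes it
    return len(out)


def measure(source: str | Path, variant: str, *, fmt: str | None = None,
            data_keys: Iterable[str] = DEFAULT_DATA_KEYS) -> SizeReport:
    """Byte-exact size report for one file (or in-memory text).

    ``variant`` labels what the file is (``source``, ``bon_uncompressed``,
    ``bon_compressed``, or ``gzip_whole``); for ``gzip_whole`` the size of
    the gzipped stream is reported and the data ratio is not meaningful
    (reported as 0).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    keys = frozenset(data_keys)
    if variant == "gzip_whole":
        return SizeReport(file_bytes=gzip_whole(source), data_bytes=0,
                          ratio=0.0, variant=variant)
    raw, text = _read(source)
    fmt = fmt or sniff_format(text)
    data = _data_bytes(text, fmt, keys)
    file_bytes = len(raw)
    ratio = data / file_bytes if file_bytes else 0.0
    return SizeReport(file_bytes=file_bytes, data_bytes=data, ratio=ratio, variant=variant)


def compare_report(reports: Sequence[SizeReport]) -> list[dict[str, Any]]:
    """Tabulate reports with percent size change relative to the first.

    Returns plain rows (dicts) ready for TSV rendering.
    """
    if not reports:
        return []
    base = reports[0].file_bytes
    rows = []
    for rep in reports:
        pct = 100.0 * (rep.file_bytes - base) / base if base else 0.0
        rows.append({"variant": rep.variant, "file_bytes": rep.file_bytes,
                     "data_bytes": rep.data_bytes, "ratio": round(rep.ratio, 4),
                     "pct_vs_first": round(pct, 2)})
    return rows


def render_tsv(rows: Sequence[dict[str, Any]]) -> str:
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r[c]) for c in cols) for r in rows]
    return "\n".join(lines) + "\n"
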