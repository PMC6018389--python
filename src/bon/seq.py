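"""Converters between BON and sequence-record formats.

TinySeq (NCBI's minimal XML sequence record) maps to one payload object
per ``<TSeq>`` entry with the same naming scheme minus the ``TSeq_``
prefix: ``seqtype``, ``accver``, ``taxid``, ``orgname``, ``defline``,
``length``, ``sequence`` (``taxid`` and ``length`` as numbers, the rest
strings).  The sequence type, which TinySeq buries in an XML tag
attribute, becomes an ordinary key.  By default only the sequence value
is compressed.

FASTQ maps to one object per read with ``readid``, ``spotid``,
``sequence``, ``quality`` and ``length`` keys; the default compresses
sequence and quality.  FASTQ's classic ambiguity — a quality line may
begin with ``@``, the record-start character — is handled by
length-guarded parsing: after the ``+`` line, quality characters are
accumulated until their count equals the sequence length, so a leading
``@`` can never be misread as a new record.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Iterator
from xml.etree import ElementTree
from xml.sax.saxutils import escape as _xml_escape

from .core import BonBlock, BonObject, CompressionSpec, decode_object, encode_block
from .errors import FormatError

#: Attributes compressed by default for each source format.
TINYSEQ_DEFAULT_SPEC = CompressionSpec({"sequence"})
FASTQ_DEFAULT_SPEC = CompressionSpec({"sequence", "quality"})

_TINYSEQ_FIELDS = ("seqtype", "accver", "taxid", "orgname", "defline", "length", "sequence")
_QUALITY_RANGE = (33, 126)
_SPOT_RE = re.compile(r"\bspot(?:id)?[=:](\S+)", re.IGNORECASE)


@dataclass(frozen=True)
class TinySeqRecord:
    """One TinySeq entry with line breaks stripped from the sequence."""

    seqtype: str  # "nucleotide" | "protein"
    accver: str
    taxid: int
    orgname: str
    defline: str
    length: int
    sequence: str

    def to_object(self) -> BonObject:
        return {"seqtype": self.seqtype, "accver": self.accver, "taxid": self.taxid,
                "orgname": self.orgname, "defline": self.defline,
                "length": self.length, "sequence": self.sequence}


@dataclass(frozen=True)
class FastqRecord:
    """One FASTQ read; quality characters are printable ASCII 33-126."""

    readid: str
    spotid: str
    sequence: str
    quality: str
    length: int

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.quality) == self.length):
            raise FormatError(
                f"read {self.readid!r}: sequence ({len(self.sequence)}), quality "
                f"({len(self.quality)}) and length ({self.length}) disagree")
        for ch in self.quality:
            if not _QUALITY_RANGE[0] <= ord(ch) <= _QUALITY_RANGE[1]:
                raise FormatError(
                    f"read {self.readid!r}: quality character {ch!r} outside ASCII 33-126")

    def to_object(self) -> BonObject:
        return {"readid": self.readid, "spotid": self.spotid,
                "sequence": self.sequence, "quality": self.quality,
                "length": self.length}


# ---------------------------------------------------------------------------
# TinySeq XML

def _tseq_text(elem: ElementTree.Element, tag: str, accver: str) -> str:
    child = elem.find(f"TSeq_{tag}")
    if child is None or child.text is None:
        raise FormatError(f"TinySeq entry {accver!r}: missing element TSeq_{tag}")
    return child.text


def parse_tinyseq(xml: str) -> Iterator[TinySeqRecord]:
    """Parse a TinySeqSet (or bare TSeq) document into records.

    Line breaks inside sequence text (Entrez wraps them) are removed.
    """
    try:
        root = ElementTree.fromstring(xml)
    except ElementTree.ParseError as exc:
        line, col = exc.position
        raise FormatError(f"malformed TinySeq XML at line {line}, column {col}: {exc}") from exc
    entries = [root] if root.tag == "TSeq" else root.findall("TSeq")
    for elem in entries:
        accver_el = elem.find("TSeq_accver")
        accver = (accver_el.text or "") if accver_el is not None else "<unknown>"
        seqtype_el = elem.find("TSeq_seqtype")
        if seqtype_el is None:
            raise FormatError(f"TinySeq entry {accver!r}: missing element TSeq_seqtype")
        seqtype = seqtype_el.get("value") or (seqtype_el.text or "")
        sequence = re.sub(r"\s+", "", _tseq_text(elem, "sequence", accver))
        yield TinySeqRecord(
            seqtype=seqtype,
            accver=_tseq_text(elem, "accver", accver),
            taxid=int(_tseq_text(elem, "taxid", accver)),
            orgname=_tseq_text(elem, "orgname", accver),
            defline=_tseq_text(elem, "defline", accver),
            length=int(_tseq_text(elem, "length", accver)),
            sequence=sequence,
        )


def tinyseq_to_bon(xml: str, spec: CompressionSpec = TINYSEQ_DEFAULT_SPEC) -> BonBlock:
    """Convert a TinySeq document into one BON block (sequence compressed by default)."""
    payload = [rec.to_object() for rec in parse_tinyseq(xml)]
    return encode_block(payload, spec)


def bon_to_tinyseq(block: BonBlock, wrap: int = 70) -> str:
    """Render a block of sequence objects back to TinySeq XML.

    Sequences are wrapped at ``wrap`` columns (0 = single line), matching
    the line-broken XML Entrez emits.
    """
    out = io.StringIO()
    out.write("<?xml version=\"1.0\"?>\n<TSeqSet>\n")
    for i, obj in enumerate(block.payload):
        rec = decode_object(obj, block.header, object_index=i)
        missing = [f for f in _TINYSEQ_FIELDS if f not in rec]
        if missing:
            raise FormatError(f"object {i} lacks TinySeq fields: {', '.join(missing)}")
        seq = str(rec["sequence"])
        body = "\n".join(seq[j:j + wrap] for j in range(0, len(seq), wrap)) if wrap else seq
        out.write("<TSeq>\n")
        out.write(f"  <TSeq_seqtype value=\"{_xml_escape(str(rec['seqtype']))}\"/>\n")
        for tag in ("accver", "taxid", "orgname", "defline", "length"):
            out.write(f"  <TSeq_{tag}>{_xml_escape(str(rec[tag]))}</TSeq_{tag}>\n")
        out.write(f"  <TSeq_sequence>{body}</TSeq_sequence>\n</TSeq>\n")
    out.write("</TSeqSet>\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTQ

def parse_fastq(text: str) -> Iterator[FastqRecord]:
    """Length-guarded FASTQ parser.

    Handles line-wrapped sequence and quality; a quality line starting
    with ``@`` is never mistaken for a new record because quality is read
    until its length matches the sequence.
    """
    lines = text.splitlines()
    i, n = 0, len(lines)
    while i < n:
        if not lines[i]:
            i += 1
            continue
        if not lines[i].startswith("@"):
            raise FormatError(f"line {i + 1}: expected '@' record start, got {lines[i][:20]!r}")
        desc = lines[i][1:]
        readid, _, remainder = desc.partition(" ")
        m = _SPOT_RE.search(remainder)
        spotid = m.group(1) if m else remainder.strip()
        i += 1
        seq_parts = []
        while i < n and not lines[i].startswith("+"):
            seq_parts.append(lines[i].strip())
            i += 1
        if i >= n:
            raise FormatError(f"read {readid!r}: truncated record (no '+' separator)")
        sequence = "".join(seq_parts)
        i += 1  # skip the '+' line
        qual_parts: list[str] = []
        qlen = 0
        while qlen < len(sequence):
            if i >= n:
                raise FormatError(
                    f"read {readid!r}: quality ({qlen}) shorter than sequence "
                    f"({len(sequence)}) at end of input")
            part = lines[i].strip()
            qual_parts.append(part)
            qlen += len(part)
            i += 1
        quality = "".join(qual_parts)
        if len(quality) != len(sequence):
            raise FormatError(
                f"read {readid!r}: quality length {len(quality)} != "
                f"sequence length {len(sequence)}")
        yield FastqRecord(readid=readid, spotid=spotid, sequence=sequence,
                          quality=quality, length=len(sequence))


def fastq_to_bon(fastq: str, spec: CompressionSpec = FASTQ_DEFAULT_SPEC) -> BonBlock:
    """Convert FASTQ text into one BON block (sequence and quality compressed)."""
    payload = [rec.to_object() for rec in parse_fastq(fastq)]
    return encode_block(payload, spec)


def bon_to_fastq(block: BonBlock) -> str:
    """Render a block of read objects as canonical 4-line FASTQ.

    The description line is ``@<readid> spot=<spotid>`` (bare ``@<readid>``
    when the spot id is empty); the ``+`` line is bare; no line wrapping.
    """
    out = io.StringIO()
    for i, obj in enumerate(block.payload):
        rec = decode_object(obj, block.header, object_index=i)
        fq = FastqRecord(readid=str(rec["readid"]), spotid=str(rec.get("spotid", "")),
                         sequence=str(rec["sequence"]), quality=str(rec["quality"]),
                         length=int(rec["length"]))
        head = f"@{fq.readid} spot={fq.spotid}" if fq.spotid else f"@{fq.readid}"
        out.write(f"{head}\n{fq.sequence}\n+\n{fq.quality}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTA export

def bon_to_fasta(block: BonBlock, wrap: int = 70) -> tuple[str, int]:
    """Export sequence objects as FASTA.

    Header line is ``><accver> <defline>`` (falling back to ``readid`` for
    FASTQ-derived blocks).  Objects without a sequence are skipped; the
    second return value counts them.
    """
    out = io.StringIO()
    skipped = 0
    for i, obj in enumerate(block.payload):
        rec = decode_object(obj, block.header, object_index=i)
        if "sequence" not in rec:
            skipped += 1
            continue
        ident = rec.get("accver") or rec.get("readid") or f"record{i}"
        defline = rec.get("defline", "")
        header = f">{ident} {defline}".rstrip()
        seq = str(rec["sequence"])
        if wrap:
            body = "\n".join(seq[j:j + wrap] for j in range(0, len(seq), wrap))
        else:
            body = seq
        out.write(f"{header}\n{body}\n")
    return out.getvalue(), skipped


def records_to_block(records: Iterable[TinySeqRecord] | Iterable[FastqRecord],
                     spec: CompressionSpec) -> BonBlock:
    """Build a BON block straight from typed records."""
    return encode_block([rec.to_object() for rec in records], spec)
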