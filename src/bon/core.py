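"""BON data model, selective compression codec and block serialization.

A BON stream is a concatenation of *blocks*.  Each block is a JSON header
object immediately followed by a JSON payload array; the two abut with no
separator, so the junction reads ``}[`` — deliberately invalid JSON, which
makes it a cheap block signal.  The header carries two mandatory
attributes:

``size``
    number of top-level objects in the payload (nested objects excluded),
``data``
    a map from attribute name to a compression flag, ``1`` when the values
    of that attribute are stored zlib-compressed and base64-encoded, ``0``
    when stored verbatim.

Any further header attributes are free-form metadata and travel verbatim.
Selective compression keeps attribute *names* and unflagged metadata
readable mid-stream while large values (sequences, quality strings, whole
trees) are compressed individually.
"""

from __future__ import annotations

import base64
import binascii
import json
import re
import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .errors import (
    Base64DecodeError,
    CodecError,
    DoubleCompressionError,
    ValidationError,
    ZlibDecodeError,
)

#: One biological record: a flat-or-nested JSON-compatible mapping.
BonObject = dict[str, Any]

DEFAULT_ZLIB_LEVEL = 6

_BASE64_RE = re.compile(r"^[A-Za-z0-9+/]+={0,2}$")


@dataclass(frozen=True)
class CompressionSpec:
    """Which attributes to compress, and how hard.

    ``compress`` names the attributes whose *values* are stored as
    base64-wrapped zlib streams; an empty set yields fully uncompressed
    BON.  ``level`` is the zlib compression level (1-9, default 6).
    """

    compress: frozenset[str] = frozenset()
    level: int = DEFAULT_ZLIB_LEVEL

    def __init__(self, compress: Iterable[str] = (), level: int = DEFAULT_ZLIB_LEVEL):
        names = frozenset(compress)
        for name in names:
            if not name:
                raise ValueError("attribute names in a CompressionSpec must be non-empty")
        if not 1 <= level <= 9:
            raise ValueError(f"zlib level must be in 1..9, got {level}")
        object.__setattr__(self, "compress", names)
        object.__setattr__(self, "level", level)


@dataclass
class BonHeader:
    """Per-block metadata: payload object count plus per-attribute flags."""

    size: int
    data: dict[str, int] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValidationError(f"header size must be >= 0, got {self.size}")
        for name, flag in self.data.items():
            if not isinstance(name, str) or not name:
                raise ValidationError(f"attribute name must be a non-empty string, got {name!r}")
            if flag not in (0, 1):
                raise ValidationError(f"compression flag for {name!r} must be 0 or 1, got {flag!r}")

    def compressed_attributes(self) -> frozenset[str]:
        return frozenset(name for name, flag in self.data.items() if flag == 1)

    def to_dict(self) -> dict[str, Any]:
        """Header as a plain mapping in canonical key order (size, data, extras)."""
        out: dict[str, Any] = {"size": self.size, "data": dict(self.data)}
        for key, value in self.extras.items():
            if key in ("size", "data"):
                raise ValidationError(f"extra header attribute shadows mandatory key {key!r}")
            out[key] = value
        return out

    @classmethod
    def from_dict(cls, obj: Mapping[str, Any]) -> "BonHeader":
        if "size" not in obj or "data" not in obj:
            raise ValidationError("header must carry mandatory attributes 'size' and 'data'")
        size = obj["size"]
        data = obj["data"]
        if not isinstance(size, int) or isinstance(size, bool):
            raise ValidationError(f"header 'size' must be an integer, got {size!r}")
        if not isinstance(data, dict):
            raise ValidationError(f"header 'data' must be an object, got {data!r}")
        extras = {k: v for k, v in obj.items() if k not in ("size", "data")}
        return cls(size=size, data=dict(data), extras=extras)


@dataclass
class BonBlock:
    """A header and the payload it describes."""

    header: BonHeader
    payload: list[BonObject] = field(default_factory=list)


def compress_value(plain: bytes | str, level: int = DEFAULT_ZLIB_LEVEL) -> str:
    """Compress a value to base64-wrapped zlib text.

    Text input is UTF-8 encoded first.  The result uses the standard
    base64 alphabet with ``=`` padding and contains no newline, so it can
    be embedded in a JSON string verbatim.
    """
    if isinstance(plain, str):
        plain = plain.encode("utf-8")
    return base64.b64encode(zlib.compress(plain, level)).decode("ascii")


def decompress_value(encoded: str, *, attribute: str | None = None,
                     object_index: int | None = None,
                     block_index: int | None = None) -> bytes:
    """Inverse of :func:`compress_value`.

    Raises :class:`Base64DecodeError` when the text is not base64 and
    :class:`ZlibDecodeError` when the decoded bytes are not a zlib stream,
    so callers can tell transport corruption from codec corruption.
    """
    ctx = dict(attribute=attribute, object_index=object_index, block_index=block_index)
    try:
        raw = base64.b64decode(encoded.encode("ascii"), validate=True)
    except (binascii.Error, UnicodeEncodeError, ValueError) as exc:
        raise Base64DecodeError(f"invalid base64 value: {exc}", **ctx) from exc
    try:
        return zlib.decompress(raw)
    except zlib.error as exc:
        raise ZlibDecodeError(f"invalid zlib stream: {exc}", **ctx) from exc


def _looks_compressed(value: Any) -> bool:
    """Heuristic: is this string already a base64-wrapped zlib stream?"""
    if not isinstance(value, str) or not value or len(value) % 4:
        return False
    if not _BASE64_RE.match(value):
        return False
    try:
        zlib.decompress(base64.b64decode(value, validate=True))
    except (binascii.Error, ValueError, zlib.error):
        return False
    return True


def _value_to_bytes(value: Any, attribute: str) -> bytes:
    if isinstance(value, str):
        return value.encode("utf-8")
    if isinstance(value, (dict, list)):
        # Compact JSON so decoding can re-parse the nested structure.
        return json.dumps(value, separators=(",", ":"), ensure_ascii=True).encode("utf-8")
    raise CodecError(
        f"cannot compress value of type {type(value).__name__}; "
        "only strings and nested structures are compressible",
        attribute=attribute,
    )


def encode_object(record: BonObject, spec: CompressionSpec) -> BonObject:
    """Return a copy of *record* with the spec'd attribute values compressed.

    Attribute names and unflagged values are untouched; an attribute named
    in the spec but absent from the record is ignored (payload objects may
    have heterogeneous key sets).  Compressing a value that already looks
    like a compressed one is refused rather than silently re-wrapped.
    """
    out: BonObject = {}
    for name, value in record.items():
        if name in spec.compress:
            if _looks_compressed(value):
                raise DoubleCompressionError(
                    "value already appears to be base64-wrapped zlib; "
                    "refusing to compress twice", attribute=name)
            out[name] = compress_value(_value_to_bytes(value, name), spec.level)
        else:
            out[name] = value
    return out


def decode_object(record: BonObject, header: BonHeader, *,
                  object_index: int | None = None,
                  block_index: int | None = None) -> BonObject:
    """Decompress every attribute flagged ``1`` in the governing header.

    Decompressed text that parses as a JSON object or array is re-parsed
    (that is how nested structures such as trees are stored); anything
    else stays a plain string.  Exact inverse of :func:`encode_object`.
    """
    flagged = header.compressed_attributes()
    out: BonObject = {}
    for name, value in record.items():
        if name in flagged:
            if not isinstance(value, str):
                raise CodecError(
                    f"attribute flagged compressed but value is {type(value).__name__}, "
                    "expected a base64 string",
                    attribute=name, object_index=object_index, block_index=block_index)
            raw = decompress_value(value, attribute=name,
                                   object_index=object_index, block_index=block_index)
            text = raw.decode("utf-8")
            if text[:1] in ("{", "["):
                try:
                    out[name] = json.loads(text)
                    continue
                except json.JSONDecodeError:
                    pass
            out[name] = text
        else:
            out[name] = value
    return out


def build_header(payload: Sequence[BonObject], spec: CompressionSpec | None = None,
                 extras: Mapping[str, Any] | None = None) -> BonHeader:
    """Build the self-describing header for a payload.

    ``size`` counts top-level objects only.  ``data`` enumerates every
    attribute name occurring in any payload object (first-seen order),
    flagged 1 when the spec compresses it and 0 otherwise, so a reader can
    discover the payload's vocabulary from the header alone.
    """
    spec = spec or CompressionSpec()
    data: dict[str, int] = {}
    for obj in payload:
        for name in obj:
            if name not in data:
                data[name] = 1 if name in spec.compress else 0
    return BonHeader(size=len(payload), data=data, extras=dict(extras or {}))


def encode_block(payload: Sequence[BonObject], spec: CompressionSpec | None = None,
                 extras: Mapping[str, Any] | None = None) -> BonBlock:
    """Compress a payload of plain records into a ready-to-serialize block."""
    spec = spec or CompressionSpec()
    encoded = [encode_object(obj, spec) for obj in payload]
    return BonBlock(header=build_header(payload, spec, extras), payload=encoded)


def decode_block(block: BonBlock) -> list[BonObject]:
    """Decompress every object of a block according to its header."""
    return [decode_object(obj, block.header, object_index=i)
            for i, obj in enumerate(block.payload)]


def validate_block(block: BonBlock, *, block_index: int | None = None) -> None:
    """Check the block invariants; raise :class:`ValidationError` on failure.

    Checks: header size matches payload length; flags are 0/1 (enforced by
    the header type); flagged values are base64-alphabet strings; no
    string value contains a newline.
    """
    where = "" if block_index is None else f" in block {block_index}"
    if block.header.size != len(block.payload):
        raise ValidationError(
            f"header size {block.header.size} != payload length {len(block.payload)}{where}")
    flagged = block.header.compressed_attributes()
    for i, obj in enumerate(block.payload):
        for name, value in obj.items():
            if name in flagged:
                if not isinstance(value, str) or (value and not _BASE64_RE.match(value)):
                    raise ValidationError(
                        f"attribute {name!r} flagged compressed but value is not "
                        f"base64 text{where} (object {i})")
            if isinstance(value, str) and "\n" in value:
                raise ValidationError(
                    f"string value of {name!r} contains a newline{where} (object {i})")


def serialize_block(block: BonBlock) -> str:
    """Render a block as compact text: header JSON abutting payload JSON.

    No whitespace, no newlines; the header/payload junction is exactly
    ``}[``.  Header keys are emitted in canonical order (``size``,
    ``data``, then extras in insertion order) so output is byte-stable.
    """
    if block.header.size != len(block.payload):
        raise ValidationError(
            f"refusing to serialize: header size {block.header.size} "
            f"!= payload length {len(block.payload)}")
    header_text = json.dumps(block.header.to_dict(), separators=(",", ":"), ensure_ascii=True)
    payload_text = json.dumps(block.payload, separators=(",", ":"), ensure_ascii=True)
    return header_text + payload_text


def serialize_stream(blocks: Iterable[BonBlock]) -> str:
    """Concatenate serialized blocks; the inter-block junction is ``]{``."""
    return "".join(serialize_block(b) for b in blocks)
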