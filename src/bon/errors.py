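"""Exception hierarchy for BON encoding, decoding and streaming."""

from __future__ import annotations


class BonError(Exception):
    """Base class for every error raised by this package."""


class CodecError(BonError):
    """A per-attribute compression or decompression failure.

    Carries enough context (attribute name, object index, block index) to
    locate the offending value in a stream; any of these may be ``None``
    when the failure occurs outside a block context.
    """

    def __init__(self, message: str, *, attribute: str | None = None,
                 object_index: int | None = None, block_index: int | None = None):
        self.attribute = attribute
        self.object_index = object_index
        self.block_index = block_index
        where = []
        if block_index is not None:
            where.append(f"block {block_index}")
        if object_index is not None:
            where.append(f"object {object_index}")
        if attribute is not None:
            where.append(f"attribute {attribute!r}")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)


class Base64DecodeError(CodecError):
    """The value is not valid base64 text (bad alphabet or padding)."""


class ZlibDecodeError(CodecError):
    """The base64 layer decoded, but the bytes are not a valid zlib stream."""


class DoubleCompressionError(CodecError):
    """Refusal to compress a value that already looks like a compressed one."""


class FormatError(BonError):
    """Malformed input in one of the source formats (FASTQ, TinySeq XML, ...)."""


class StreamError(BonError):
    """A structural problem in a BON stream (truncation, junk between blocks).

    ``last_block`` is the index of the last block that parsed completely
    (-1 when none did) and ``offset`` the byte offset where scanning stopped.
    """

    def __init__(self, message: str, *, last_block: int = -1, offset: int | None = None):
        self.last_block = last_block
        self.offset = offset
        detail = f" (last complete block: {last_block}"
        if offset is not None:
            detail += f", byte offset {offset}"
        detail += ")"
        super().__init__(message + detail)


class ValidationError(BonError):
    """A block violates a BON invariant (e.g. header size != payload length)."""


class GraphError(BonError):
    """A vertex/edge set does not form a valid tree (or DAG in ARG mode)."""
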