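"""Stream-safe BON reading: block boundary detection and object iteration.

A BON stream is not valid JSON as a whole — blocks abut at ``}[`` and
``]{`` junctions — but each header and each payload is valid JSON on its
own.  The scanner here parses the stream incrementally with a real JSON
decoder rather than splitting on the junction substrings: a ``}[`` inside
a string value (a defline, say) can never cause a mis-split, which the
naive ``sed 's/}\\[/\\n/g'`` recipe cannot guarantee for arbitrary
metadata.  On benign data (no junction characters inside values) both
approaches find the same boundaries.

Input may be an in-memory string, a ``pathlib.Path``, an open text or
binary file (including pipes), or any iterable of text chunks.  Files are
read in chunks (default 64 KiB); block boundaries may straddle chunk
edges.  Memory use is bounded by one payload object plus scanner state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, IO, Iterable, Iterator, Union

from .core import BonBlock, BonHeader, BonObject, decode_object
from .errors import StreamError, ValidationError

DEFAULT_BUFFER_SIZE = 64 * 1024

Source = Union[str, Path, IO[str], IO[bytes], Iterable[str]]


@dataclass(frozen=True)
class BlockBoundary:
    """Byte offsets of one block: [header_start, header_end) is the header
    JSON, [header_end, payload_end) the payload JSON array."""

    header_start: int
    header_end: int
    payload_end: int


def _chunk_source(source: Source, buffer_size: int) -> Iterator[str]:
    if isinstance(source, str):
        yield source
        return
    if isinstance(source, Path):
        with open(source, "r", encoding="utf-8") as fh:
            while chunk := fh.read(buffer_size):
                yield chunk
        return
    read = getattr(source, "read", None)
    if callable(read):
        while chunk := read(buffer_size):
            if isinstance(chunk, bytes):
                chunk = chunk.decode("utf-8")
            yield chunk
        return
    for chunk in source:
        if isinstance(chunk, bytes):
            chunk = chunk.decode("utf-8")
        yield chunk


class _Cursor:
    """Buffered view over a chunk source with incremental JSON decoding."""

    def __init__(self, chunks: Iterator[str]):
        self._chunks = chunks
        self._buf = ""
        self._base = 0  # absolute offset of _buf[0]
        self._pos = 0
        self._eof = False
        self._decoder = json.JSONDecoder()

    @property
    def offset(self) -> int:
        return self._base + self._pos

    def _fill(self) -> bool:
        if self._eof:
            return False
        for chunk in self._chunks:
            if chunk:
                self._buf += chunk
                return True
        self._eof = True
        return False

    def trim(self) -> None:
        """Drop the consumed prefix so memory stays bounded."""
        if self._pos:
            self._base += self._pos
            self._buf = self._buf[self._pos:]
            self._pos = 0

    def peek(self) -> str | None:
        while self._pos >= len(self._buf):
            if not self._fill():
                return None
        return self._buf[self._pos]

    def advance(self) -> None:
        self._pos += 1

    def decode_value(self) -> Any:
        """Decode one JSON value starting exactly at the cursor.

        Refills the buffer and retries while the value is incomplete; at
        end of input the JSON error propagates to the caller.
        """
        while True:
            try:
                value, end = self._decoder.raw_decode(self._buf, self._pos)
            except json.JSONDecodeError:
                if self._fill():
                    continue
                raise
            self._pos = end
            return value


def _parse_blocks(source: Source, *, buffer_size: int = DEFAULT_BUFFER_SIZE,
                  allow_trailing_newline: bool = True):
    """Yield ``(block_index, header, boundary, objects_iter)`` per block.

    ``objects_iter`` must be exhausted before requesting the next block.
    """
    cursor = _Cursor(_chunk_source(source, buffer_size))
    block_index = 0
    while True:
        cursor.trim()
        ch = cursor.peek()
        if ch is None:
            return
        if ch == "\n" and allow_trailing_newline:
            cursor.advance()
            if cursor.peek() is None:
                return
            raise StreamError("content after trailing newline",
                              last_block=block_index - 1, offset=cursor.offset)
        if ch != "{":
            raise StreamError(f"expected block header, found {ch!r}",
                              last_block=block_index - 1, offset=cursor.offset)
        header_start = cursor.offset
        try:
            raw_header = cursor.decode_value()
        except json.JSONDecodeError as exc:
            raise StreamError(f"unreadable block header: {exc.msg}",
                              last_block=block_index - 1, offset=header_start) from exc
        try:
            header = BonHeader.from_dict(raw_header)
        except ValidationError as exc:
            raise ValidationError(f"block {block_index}: {exc}") from exc
        header_end = cursor.offset
        if cursor.peek() != "[":
            raise StreamError(
                "payload array must follow the header directly ('}[' junction)",
                last_block=block_index - 1, offset=cursor.offset)

        state = {"payload_end": None}

        def _objects(idx: int = block_index) -> Iterator[BonObject]:
            cursor.advance()  # consume '['
            count = 0
            ch = cursor.peek()
            while True:
                if ch is None:
                    raise StreamError("truncated payload",
                                      last_block=idx - 1, offset=cursor.offset)
                if ch == "]":
                    cursor.advance()
                    break
                if count:
                    if ch != ",":
                        raise StreamError(f"expected ',' or ']' in payload, found {ch!r}",
                                          last_block=idx - 1, offset=cursor.offset)
                    cursor.advance()
                try:
                    obj = cursor.decode_value()
                except json.JSONDecodeError as exc:
                    raise StreamError(f"unreadable payload object: {exc.msg}",
                                      last_block=idx - 1, offset=cursor.offset) from exc
                if not isinstance(obj, dict):
                    raise ValidationError(
                        f"block {idx}: payload element {count} is not a JSON object")
                count += 1
                yield obj
                cursor.trim()
                ch = cursor.peek()
            if count != header.size:
                raise ValidationError(
                    f"block {idx}: header size {header.size} != payload length {count}")
            state["payload_end"] = cursor.offset

        boundary = (header_start, header_end, state)
        yield block_index, header, boundary, _objects()
        if state["payload_end"] is None:
            raise RuntimeError("payload iterator must be exhausted before the next block")
        block_index += 1


def scan_blocks(source: Source, *, buffer_size: int = DEFAULT_BUFFER_SIZE,
                allow_trailing_newline: bool = True) -> Iterator[BonBlock]:
    """Yield every block of a stream, validated, payload values verbatim."""
    for _, header, _, objects in _parse_blocks(
            source, buffer_size=buffer_size,
            allow_trailing_newline=allow_trailing_newline):
        yield BonBlock(header=header, payload=list(objects))


def scan_boundaries(source: Source, *, buffer_size: int = DEFAULT_BUFFER_SIZE,
                    allow_trailing_newline: bool = True) -> list[BlockBoundary]:
    """Byte offsets of every block in the stream."""
    out = []
    for _, _, (hs, he, state), objects in _parse_blocks(
            source, buffer_size=buffer_size,
            allow_trailing_newline=allow_trailing_newline):
        for _ in objects:
            pass
        out.append(BlockBoundary(hs, he, state["payload_end"]))
    return out


def iter_objects(source: Source, *, decode: bool = False,
                 buffer_size: int = DEFAULT_BUFFER_SIZE,
                 allow_trailing_newline: bool = True) -> Iterator[tuple[int, BonObject]]:
    """Yield ``(block_index, object)`` pairs one object at a time.

    With ``decode=True`` flagged attributes are decompressed through the
    governing header; otherwise base64 strings are yielded verbatim.
    Suitable for filtering a stream while receiving it — the whole stream
    is never held in memory.
    """
    for block_index, header, _, objects in _parse_blocks(
            source, buffer_size=buffer_size,
            allow_trailing_newline=allow_trailing_newline):
        for object_index, obj in enumerate(objects):
            if decode:
                obj = decode_object(obj, header, object_index=object_index,
                                    block_index=block_index)
            yield block_index, obj


def peek_headers(source: Source, *, buffer_size: int = DEFAULT_BUFFER_SIZE,
                 allow_trailing_newline: bool = True) -> list[BonHeader]:
    """Read only the headers of a stream; payload values are never decompressed."""
    headers = []
    for _, header, _, objects in _parse_blocks(
            source, buffer_size=buffer_size,
            allow_trailing_newline=allow_trailing_newline):
        headers.append(header)
        for _ in objects:  # skim past the payload
            pass
    return headers
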