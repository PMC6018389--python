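"""Codec, header and block serialization behaviour."""

import json
import math
import zlib

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bon import (
    Base64DecodeError,
    BonBlock,
    BonHeader,
    CompressionSpec,
    DoubleCompressionError,
    ValidationError,
    ZlibDecodeError,
    build_header,
    compress_value,
    decode_object,
    decompress_value,
    encode_block,
    encode_object,
    serialize_block,
    serialize_stream,
    validate_block,
)
from bon.stream import scan_blocks

# zlib (RFC 1950, level 6) of the empty byte string, base64-encoded;
# frozen from an independent run of the reference zlib implementation.
EMPTY_ZLIB_B64 = "eJwDAAAAAAE="


class TestCodec:
    def test_empty_input_frozen_value(self):
        assert compress_value(b"") == EMPTY_ZLIB_B64
        assert decompress_value(EMPTY_ZLIB_B64) == b""

    @pytest.mark.parametrize("payload", [
        b"",
        b"ACGT",
        "ACGT" .encode() * 2500,                       # 10 kb of repeats
        bytes(range(256)) * 7,
        "μ-ορganism\n∂ata".encode("utf-8"),
    ])
    def test_round_trip_identity(self, payload):
        assert decompress_value(compress_value(payload)) == payload

    def test_text_input_utf8(self):
        assert decompress_value(compress_value("ACGT")) == b"ACGT"

    def test_output_is_newline_free_base64(self):
        out = compress_value(bytes(range(256)) * 400)
        assert "\n" not in out
        assert set(out) <= set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                               "abcdefghijklmnopqrstuvwxyz0123456789+/=")

    def test_invalid_base64_raises_base64_error(self):
        with pytest.raises(Base64DecodeError):
            decompress_value("not-base64!!")

    def test_valid_base64_invalid_zlib_raises_zlib_error(self):
        with pytest.raises(ZlibDecodeError):
            decompress_value("AAAA")

    def test_error_carries_attribute_name(self):
        with pytest.raises(ZlibDecodeError, match="quality"):
            decompress_value("AAAA", attribute="quality", object_index=3)

    @given(st.binary(max_size=2000))
    def test_codec_round_trip_property(self, payload):
        assert decompress_value(compress_value(payload)) == payload

    @given(st.binary(max_size=2000))
    def test_base64_length_law(self, payload):
        z = len(zlib.compress(payload, 6))
        assert len(compress_value(payload)) == 4 * math.ceil(z / 3)


class TestEncodeDecode:
    def test_encode_compresses_only_named_attributes(self):
        obj = {"defline": "d", "sequence": "ACGT"}
        out = encode_object(obj, CompressionSpec({"sequence"}))
        assert out["defline"] == "d"
        assert out["sequence"] == compress_value("ACGT")
        assert set(out) == set(obj)

    def test_empty_spec_is_identity(self):
        obj = {"defline": "d", "sequence": "ACGT"}
        assert encode_object(obj, CompressionSpec()) == obj

    def test_absent_attribute_in_spec_is_ignored(self):
        obj = {"defline": "d"}
        assert encode_object(obj, CompressionSpec({"sequence"})) == obj

    def test_double_compression_refused(self):
        spec = CompressionSpec({"sequence"})
        once = encode_object({"sequence": "ACGTACGT"}, spec)
        with pytest.raises(DoubleCompressionError):
            encode_object(once, spec)

    def test_nested_structure_round_trips(self):
        tree = {"vertices": [{"id": "v0"}, {"id": "v1"}],
                "edges": [{"id": "e0", "source": "v0", "target": "v1"}]}
        spec = CompressionSpec({"tree"})
        enc = encode_object({"tree": tree, "name": "t"}, spec)
        assert isinstance(enc["tree"], str)
        header = build_header([{"tree": tree, "name": "t"}], spec)
        assert decode_object(enc, header) == {"tree": tree, "name": "t"}

    def test_decode_respects_zero_flag(self):
        obj = {"sequence": "ACGT"}
        header = BonHeader(size=1, data={"sequence": 0})
        assert decode_object(obj, header) == obj

    def test_decode_flags_zlib_failure_with_context(self):
        header = BonHeader(size=1, data={"sequence": 1})
        with pytest.raises(ZlibDecodeError, match="sequence"):
            decode_object({"sequence": "AAAA"}, header, object_index=0)

    def test_decode_inverts_encode(self):
        spec = CompressionSpec({"sequence", "quality"})
        obj = {"readid": "r1", "sequence": "ACGT", "quality": "!!!!", "length": 4}
        header = build_header([obj], spec)
        assert decode_object(encode_object(obj, spec), header) == obj


class TestHeader:
    def test_flags_follow_spec(self):
        payload = [{"defline": "a", "sequence": "AC"},
                   {"defline": "b", "sequence": "GT"}]
        header = build_header(payload, CompressionSpec({"sequence"}))
        assert header.size == 2
        assert header.data == {"defline": 0, "sequence": 1}

    def test_empty_payload(self):
        header = build_header([])
        assert (header.size, header.data) == (0, {})

    def test_size_excludes_nested_objects(self):
        payload = [{"tree": {"vertices": [], "edges": []}, "name": "t"}]
        assert build_header(payload).size == 1

    def test_heterogeneous_key_union(self):
        payload = [{"a": 1}, {"b": 2}, {"a": 3, "c": 4}]
        assert build_header(payload).data == {"a": 0, "b": 0, "c": 0}

    def test_extras_survive(self):
        header = build_header([], extras={"source": "synthetic"})
        assert header.to_dict() == {"size": 0, "data": {}, "source": "synthetic"}

    @pytest.mark.parametrize("kwargs", [
        {"size": -1, "data": {}},
        {"size": 0, "data": {"x": 2}},
        {"size": 0, "data": {"": 0}},
    ])
    def test_invalid_headers_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            BonHeader(**kwargs)

    def test_mandatory_attributes_enforced_on_read(self):
        with pytest.raises(ValidationError):
            BonHeader.from_dict({"size": 0})


class TestSerialization:
    def test_empty_block_literal(self):
        assert serialize_block(encode_block([])) == '{"size":0,"data":{}}[]'

    def test_no_newline_anywhere(self):
        block = encode_block([{"defline": "a b", "sequence": "ACGT" * 100}],
                             CompressionSpec({"sequence"}))
        assert "\n" not in serialize_block(block)

    def test_junction_split_yields_two_valid_json_parts(self):
        block = encode_block([{"defline": "d", "sequence": "ACGT"}],
                             CompressionSpec({"sequence"}))
        text = serialize_block(block)
        head, _, tail = text.partition("}[")
        header = json.loads(head + "}")
        payload = json.loads("[" + tail)
        assert header["size"] == len(payload) == 1

    def test_size_mismatch_refused(self):
        block = BonBlock(header=BonHeader(size=2, data={}), payload=[{}])
        with pytest.raises(ValidationError):
            serialize_block(block)

    def test_single_block_stream_identical(self):
        block = encode_block([{"a": 1}])
        assert serialize_stream([block]) == serialize_block(block)

    def test_two_empty_blocks_literal(self):
        stream = serialize_stream([encode_block([]), encode_block([])])
        assert stream == '{"size":0,"data":{}}[]{"size":0,"data":{}}[]'

    def test_validate_block_catches_newline_value(self):
        block = BonBlock(header=BonHeader(size=1, data={"defline": 0}),
                         payload=[{"defline": "a\nb"}])
        with pytest.raises(ValidationError):
            validate_block(block)

    def test_validate_block_catches_nonbase64_flagged_value(self):
        block = BonBlock(header=BonHeader(size=1, data={"sequence": 1}),
                         payload=[{"sequence": "not base64 !!"}])
        with pytest.raises(ValidationError):
            validate_block(block)


_values = st.one_of(
    st.text(alphabet=st.characters(blacklist_characters="\n", codec="utf-8"),
            max_size=30),
    st.integers(-10**6, 10**6),
    st.floats(allow_nan=False, allow_infinity=False, width=32),
)
_objects = st.dictionaries(
    st.text(alphabet="abcdefgh}{[]", min_size=1, max_size=8), _values, max_size=5)


class TestBlockProperties:
    @given(st.lists(_objects, max_size=6))
    def test_block_round_trip(self, payload):
        block = encode_block(payload)
        blocks = list(scan_blocks(serialize_block(block)))
        assert len(blocks) == 1
        assert blocks[0].header == block.header
        assert blocks[0].payload == block.payload

    @given(st.lists(_objects, max_size=6))
    def test_header_size_matches_payload(self, payload):
        assert build_header(payload).size == len(payload)

    @given(st.lists(st.lists(_objects, max_size=4), max_size=4))
    def test_stream_never_contains_newline(self, payloads):
        text = serialize_stream([encode_block(p) for p in payloads])
        assert "\n" not in text
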