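"""LEB128 varints and a tiny binary record reader/writer.

All multi-byte fixed-width integers in the archive are little-endian.
"""

from __future__ import annotations

import struct


def varint_size(value: int) -> int:
    """Byte length of the LEB128 encoding of ``value`` (>= 0)."""
    if value < 0:
        raise ValueError("varint is unsigned")
    size = 1
    while value >= 0x80:
        value >>= 7
        size += 1
    return size


def encode_varint(value: int) -> bytes:
    if value < 0:
        raise ValueError("varint is unsigned")
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def decode_varint(buf: bytes, pos: int) -> tuple[int, int]:
    """Decode a varint at ``pos``; return (value, new_pos)."""
    result = 0
    shift = 0
    while True:
        byte = buf[pos]
        pos += 1
        result |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return result, pos
        shift += 7


class Writer:
    """Accumulates a binary blob of varints, fixed ints, bytes and strings."""

    def __init__(self) -> None:
        self._parts: list[bytes] = []

    def varint(self, value: int) -> None:
        self._parts.append(encode_varint(value))

    def u8(self, value: int) -> None:
        self._parts.append(struct.pack("<B", value))

    def u32(self, value: int) -> None:
        self._parts.append(struct.pack("<I", value))

    def u64(self, value: int) -> None:
        self._parts.append(struct.pack("<Q", value))

    def raw(self, data: bytes) -> None:
        self._parts.append(data)

    def blob(self, data: bytes) -> None:
        self.varint(len(data))
        self.raw(data)

    def string(self, text: str) -> None:
        self.blob(text.encode("utf-8"))

    def getvalue(self) -> bytes:
        return b"".join(self._parts)


class Reader:
    """Sequential reader mirroring :class:`Writer`."""

    def __init__(self, buf: bytes, pos: int = 0) -> None:
        self.buf = buf
        self.pos = pos

    def varint(self) -> int:
        value, self.pos = decode_varint(self.buf, self.pos)
        return value

    def u8(self) -> int:
        value = self.buf[self.pos]
        self.pos += 1
        return value

    def u32(self) -> int:
        (value,) = struct.unpack_from("<I", self.buf, self.pos)
        self.pos += 4
        return value

    def u64(self) -> int:
        (value,) = struct.unpack_from("<Q", self.buf, self.pos)
        self.pos += 8
        return value

    def raw(self, n: int) -> bytes:
        data = self.buf[self.pos : self.pos + n]
        if len(data) != n:
            raise ValueError("truncated stream")
        self.pos += n
        return data

    def blob(self) -> bytes:
        return self.raw(self.varint())

    def string(self) -> str:
        return self.blob().decode("utf-8")
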