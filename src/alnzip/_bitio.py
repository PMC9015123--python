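"""Bit-granular writer/reader used by the archive codec.

Records are concatenated without byte alignment so that the serialized
size of each record, in bits, is exactly the quantity the arborescence
minimized.  Bits are packed MSB-first within each byte.  Varints are
LEB128 (7 payload bits per byte, LSB group first) written as whole 8-bit
chunks into the bit stream.
"""

from __future__ import annotations

from .errors import CorruptArchiveError


def varint_bit_length(value: int) -> int:
    """Exact number of bits a varint occupies in the stream (multiple of 8)."""
    if value < 0:
        raise ValueError("varints are unsigned")
    nbytes = 1
    while value >= 0x80:
        value >>= 7
        nbytes += 1
    return 8 * nbytes


class BitWriter:
    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0  # partial byte accumulator
        self._nacc = 0  # bits currently in the accumulator

    @property
    def bit_position(self) -> int:
        return 8 * len(self._buf) + self._nacc

    def write_bits(self, value: int, nbits: int) -> None:
        if nbits < 0 or value < 0 or nbits < value.bit_length():
            raise ValueError(f"value {value} does not fit in {nbits} bits")
        acc = (self._acc << nbits) | value
        total = self._nacc + nbits
        while total >= 8:
            total -= 8
            self._buf.append((acc >> total) & 0xFF)
        self._acc = acc & ((1 << total) - 1)
        self._nacc = total

    def write_varint(self, value: int) -> None:
        if value < 0:
            raise ValueError("varints are unsigned")
        while True:
            group = value & 0x7F
            value >>= 7
            self.write_bits(group | (0x80 if value else 0), 8)
            if not value:
                break

    def write_bytes(self, data: bytes) -> None:
        for b in data:
            self.write_bits(b, 8)

    def getvalue(self) -> bytes:
        """Zero-pad the trailing partial byte and return the stream."""
        out = bytes(self._buf)
        if self._nacc:
            out += bytes([self._acc << (8 - self._nacc)])
        return out


class BitReader:
    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0  # in bits

    @property
    def bit_position(self) -> int:
        return self._pos

    def read_bits(self, nbits: int) -> int:
        end = self._pos + nbits
        if end > 8 * len(self._data):
            raise CorruptArchiveError("corrupt archive: truncated bit stream")
        first = self._pos >> 3
        last = (end + 7) >> 3
        chunk = int.from_bytes(self._data[first:last], "big")
        value = (chunk >> (8 * last - end)) & ((1 << nbits) - 1)
        self._pos = end
        return value

    def read_varint(self) -> int:
        value = 0
        shift = 0
        while True:
            group = self.read_bits(8)
            value |= (group & 0x7F) << shift
            if not group & 0x80:
                return value
            shift += 7
            if shift > 63:
                raise CorruptArchiveError("corrupt archive: runaway varint")

    def read_bytes(self, nbytes: int) -> bytes:
        return bytes(self.read_bits(8) for _ in range(nbytes))
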