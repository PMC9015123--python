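"""Archive codec: records, bit-level serialization, entropy backend.

An archive stores, for every row of the alignment, either a
*reference record* (the row verbatim, packed at N bits per character) or a
*delta record* (mismatch runs against the row's parent in the referencing
hierarchy).  Records appear in a topological order of the arborescence —
parents before children, siblings by ascending original index — so
decoding is a single forward pass.  Original row indices stored in each
record restore the file order exactly.

Wire layout (inner payload, bit-packed, then fed to the entropy backend):

    varint n | varint l | varint |Σ| + alphabet UTF-8 | varint N | varint I
    | n × (varint header byte-length + header UTF-8)
    | n records:
        flag=0 | row id (I bits) | l chars (N bits)                 reference
        flag=1 | row id (I) | parent id (I) | varint #runs
              | per run: start (I) | varint len | chars (N each)    delta

Outer envelope (bytes): magic "MSAZ" | version | backend id
    | varint inner byte length | CRC32 of inner | backend(inner).

Per-record bit lengths on the wire equal the encodability-graph edge
weights exactly; their sum equals the arborescence's total weight.
"""

from __future__ import annotations

import bz2
import gzip
import lzma
import zlib
from dataclasses import dataclass
from typing import Union

from ._bitio import BitReader, BitWriter, varint_bit_length
from .arborescence import Arborescence, minimum_spanning_arborescence
from .errors import (
    CorruptArchiveError,
    UnrecognizedArchiveError,
    UnsupportedBackendError,
)
from .graph import ROOT, CostModel, MismatchRun, build_encodability_graph, mismatch_runs
from .likelihood import WindowConfig, rank_by_likelihood, sliding_windows
from .msa_io import Msa

MAGIC = b"MSAZ"
VERSION = 1

_BACKENDS = {"none": 0, "bzip2": 1, "gzip": 2, "lzma": 3}
_BACKEND_NAMES = {v: k for k, v in _BACKENDS.items()}
DEFAULT_BACKEND = "bzip2"


@dataclass(frozen=True)
class ReferenceRecord:
    original_index: int
    row: str


@dataclass(frozen=True)
class DeltaRecord:
    original_index: int
    parent_original_index: int
    runs: tuple[MismatchRun, ...]


Record = Union[ReferenceRecord, DeltaRecord]


@dataclass
class EncodedArchive:
    """In-memory form of an archive, before/after byte serialization."""

    n: int
    l: int  # noqa: E741
    alphabet: tuple[str, ...]
    cost_model: CostModel
    headers: list[str]
    records: list[Record]
    backend: str = DEFAULT_BACKEND


def topological_record_order(ma: Arborescence) -> list[int]:
    """Rows in decode order: parents first, siblings by original index."""
    children = ma.children()
    order: list[int] = []
    stack = list(reversed(children.get(ROOT, [])))
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children.get(v, [])))
    return order


def encode_archive(
    msa: Msa, ma: Arborescence, backend: str = DEFAULT_BACKEND
) -> EncodedArchive:
    """Turn an alignment plus its arborescence into archive records.

    Children of the dummy root become reference records; every other row
    becomes a delta record against its parent's row.
    """
    records: list[Record] = []
    for i in topological_record_order(ma):
        p = ma.parent[i]
        if p == ROOT:
            records.append(ReferenceRecord(original_index=i, row=msa.rows[i]))
        else:
            runs = tuple(mismatch_runs(msa.rows[p], msa.rows[i]))
            records.append(
                DeltaRecord(original_index=i, parent_original_index=p, runs=runs)
            )
    return EncodedArchive(
        n=msa.n,
        l=msa.l,
        alphabet=msa.alphabet,
        cost_model=CostModel.from_msa(msa),
        headers=list(msa.headers),
        records=records,
        backend=backend,
    )


def apply_runs(ref_row: str, runs: list[MismatchRun] | tuple[MismatchRun, ...]) -> str:
    """Replay mismatch runs onto a reference row (inverse of mismatch_runs)."""
    out = list(ref_row)
    for r in runs:
        end = r.start + len(r.chars)
        if end > len(ref_row):
            raise CorruptArchiveError(
                f"corrupt delta: run [{r.start}, {end}) exceeds row length {len(ref_row)}"
            )
        out[r.start : end] = r.chars
    return "".join(out)


def _record_bits(rec: Record, cm: CostModel, l: int) -> int:
    """Exact wire size of one record — must equal the graph edge weight."""
    I, N = cm.bits_per_index, cm.bits_per_char
    if isinstance(rec, ReferenceRecord):
        return 1 + I + l * N
    bits = 1 + 2 * I + varint_bit_length(len(rec.runs))
    for r in rec.runs:
        bits += I + varint_bit_length(len(r.chars)) + N * len(r.chars)
    return bits


def serialize_archive(a: EncodedArchive) -> bytes:
    """Canonical byte layout; equal archives serialize to equal bytes."""
    w = BitWriter()
    w.write_varint(a.n)
    w.write_varint(a.l)
    alpha_bytes = "".join(a.alphabet).encode("utf-8")
    w.write_varint(len(alpha_bytes))
    w.write_bytes(alpha_bytes)
    w.write_varint(a.cost_model.bits_per_char)
    w.write_varint(a.cost_model.bits_per_index)
    for h in a.headers:
        hb = h.encode("utf-8")
        w.write_varint(len(hb))
        w.write_bytes(hb)

    char_code = {c: k for k, c in enumerate(a.alphabet)}
    I, N = a.cost_model.bits_per_index, a.cost_model.bits_per_char
    for rec in a.records:
        start_bit = w.bit_position
        if isinstance(rec, ReferenceRecord):
            w.write_bits(0, 1)
            w.write_bits(rec.original_index, I)
            packed = 0
            for c in rec.row:
                packed = (packed << N) | char_code[c]
            w.write_bits(packed, a.l * N)
        else:
            w.write_bits(1, 1)
            w.write_bits(rec.original_index, I)
            w.write_bits(rec.parent_original_index, I)
            w.write_varint(len(rec.runs))
            for r in rec.runs:
                w.write_bits(r.start, I)
                w.write_varint(len(r.chars))
                packed = 0
                for c in r.chars:
                    packed = (packed << N) | char_code[c]
                w.write_bits(packed, len(r.chars) * N)
        assert w.bit_position - start_bit == _record_bits(rec, a.cost_model, a.l)
    return w.getvalue()


def deserialize_archive(b: bytes) -> EncodedArchive:
    """Exact inverse of :func:`serialize_archive` (backend already undone)."""
    r = BitReader(b)
    n = r.read_varint()
    l = r.read_varint()  # noqa: E741
    if n < 1 or l < 1:
        raise CorruptArchiveError(f"corrupt archive: invalid dimensions n={n}, l={l}")
    alpha_len = r.read_varint()
    alphabet = tuple(r.read_bytes(alpha_len).decode("utf-8"))
    N = r.read_varint()
    I = r.read_varint()
    cm = CostModel(bits_per_char=N, bits_per_index=I)
    headers = []
    for _ in range(n):
        hlen = r.read_varint()
        headers.append(r.read_bytes(hlen).decode("utf-8"))

    records: list[Record] = []
    for _ in range(n):
        flag = r.read_bits(1)
        original_index = r.read_bits(I)
        if not 0 <= original_index < n:
            raise CorruptArchiveError(f"corrupt archive: row id {original_index}")
        if flag == 0:
            packed = r.read_bits(l * N)
            chars = []
            for k in range(l - 1, -1, -1):
                code = (packed >> (k * N)) & ((1 << N) - 1)
                if code >= len(alphabet):
                    raise CorruptArchiveError("corrupt archive: character code out of range")
                chars.append(alphabet[code])
            records.append(
                ReferenceRecord(original_index=original_index, row="".join(chars))
            )
        else:
            parent = r.read_bits(I)
            n_runs = r.read_varint()
            runs = []
            for _ in range(n_runs):
                start = r.read_bits(I)
                rlen = r.read_varint()
                if rlen < 1 or start + rlen > l:
                    raise CorruptArchiveError("corrupt archive: run out of bounds")
                packed = r.read_bits(rlen * N)
                chars = []
                for k in range(rlen - 1, -1, -1):
                    code = (packed >> (k * N)) & ((1 << N) - 1)
                    if code >= len(alphabet):
                        raise CorruptArchiveError(
                            "corrupt archive: character code out of range"
                        )
                    chars.append(alphabet[code])
                runs.append(MismatchRun(start=start, chars="".join(chars)))
            records.append(
                DeltaRecord(
                    original_index=original_index,
                    parent_original_index=parent,
                    runs=tuple(runs),
                )
            )
    return EncodedArchive(
        n=n, l=l, alphabet=alphabet, cost_model=cm, headers=headers, records=records
    )


def backend_compress(b: bytes, backend: str = DEFAULT_BACKEND) -> bytes:
    if backend == "none":
        return b
    if backend == "bzip2":
        return bz2.compress(b, 9)
    if backend == "gzip":
        # mtime pinned so archive bytes are reproducible across runs
        return gzip.compress(b, 9, mtime=0)
    if backend == "lzma":
        return lzma.compress(b, preset=6)
    raise UnsupportedBackendError(f"unsupported backend: {backend!r}")


def backend_decompress(b: bytes, backend: str = DEFAULT_BACKEND) -> bytes:
    try:
        if backend == "none":
            return b
        if backend == "bzip2":
            return bz2.decompress(b)
        if backend == "gzip":
            return gzip.decompress(b)
        if backend == "lzma":
            return lzma.decompress(b)
    except (OSError, lzma.LZMAError, ValueError) as exc:
        raise CorruptArchiveError(f"corrupt archive: backend failed ({exc})") from exc
    raise UnsupportedBackendError(f"unsupported backend: {backend!r}")


def _encode_varint_bytes(value: int) -> bytes:
    w = BitWriter()
    w.write_varint(value)
    return w.getvalue()


def compress(
    msa: Msa,
    cfg: WindowConfig | None = None,
    backend: str = DEFAULT_BACKEND,
) -> bytes:
    """Full pipeline: rank rows, build the sparse graph, solve the
    arborescence, serialize records, run the entropy backend, wrap in the
    envelope.  Deterministic for fixed (msa, cfg, backend)."""
    if backend not in _BACKENDS:
        raise UnsupportedBackendError(f"unsupported backend: {backend!r}")
    if cfg is None:
        cfg = WindowConfig()
    order = rank_by_likelihood(msa)
    windows = sliding_windows(order, cfg)
    eg = build_encodability_graph(msa, windows)
    ma = minimum_spanning_arborescence(eg)
    archive = encode_archive(msa, ma, backend=backend)
    inner = serialize_archive(archive)
    return envelope(inner, backend)


def envelope(inner: bytes, backend: str = DEFAULT_BACKEND) -> bytes:
    """Wrap a serialized archive in the self-describing outer envelope."""
    if backend not in _BACKENDS:
        raise UnsupportedBackendError(f"unsupported backend: {backend!r}")
    payload = backend_compress(inner, backend)
    crc = zlib.crc32(inner) & 0xFFFFFFFF
    return (
        MAGIC
        + bytes([VERSION, _BACKENDS[backend]])
        + _encode_varint_bytes(len(inner))
        + crc.to_bytes(4, "big")
        + payload
    )


def decompress(data: bytes) -> Msa:
    """Exact inverse of :func:`compress`: reconstructs rows hierarchically
    in record order, then restores original row order and headers."""
    if len(data) < 6 or data[:4] != MAGIC:
        raise UnrecognizedArchiveError("unrecognized archive: bad magic")
    if data[4] != VERSION:
        raise UnrecognizedArchiveError(f"unrecognized archive: version {data[4]}")
    backend_id = data[5]
    if backend_id not in _BACKEND_NAMES:
        raise UnsupportedBackendError(f"unsupported backend id: {backend_id}")
    backend = _BACKEND_NAMES[backend_id]
    r = BitReader(data[6:])
    inner_len = r.read_varint()
    pos = 6 + r.bit_position // 8
    if len(data) < pos + 4:
        raise CorruptArchiveError("corrupt archive: truncated envelope")
    crc_stored = int.from_bytes(data[pos : pos + 4], "big")
    inner = backend_decompress(data[pos + 4 :], backend)
    if len(inner) != inner_len:
        raise CorruptArchiveError(
            f"corrupt archive: payload length {len(inner)} != declared {inner_len}"
        )
    if zlib.crc32(inner) & 0xFFFFFFFF != crc_stored:
        raise CorruptArchiveError("corrupt archive: checksum mismatch")
    archive = deserialize_archive(inner)
    archive.backend = backend

    rows_by_index: dict[int, str] = {}
    for rec in archive.records:
        if isinstance(rec, ReferenceRecord):
            rows_by_index[rec.original_index] = rec.row
        else:
            parent_row = rows_by_index.get(rec.parent_original_index)
            if parent_row is None:
                raise CorruptArchiveError(
                    f"corrupt archive: record {rec.original_index} references "
                    f"undecoded parent {rec.parent_original_index}"
                )
            rows_by_index[rec.original_index] = apply_runs(parent_row, rec.runs)
    if len(rows_by_index) != archive.n:
        raise CorruptArchiveError("corrupt archive: duplicate or missing row records")
    return Msa(
        headers=archive.headers,
        rows=[rows_by_index[i] for i in range(archive.n)],
    )
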