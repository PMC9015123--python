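"""Reading, validating and writing aligned FASTA.

The container type :class:`Msa` is deliberately strict: every row has the
same length, headers are kept verbatim (the full description line without
the leading ``>``), record order is preserved, and character case is never
normalized.  Upper- and lower-case forms of the same letter are distinct
alphabet symbols — compression must be lossless at the byte level, so the
reader takes no view on biological equivalence.

Coordinates are 0-based everywhere in this codebase.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO

from .errors import FastaFormatError, NotAnAlignmentError

Source = Union[str, Path, IO[str], IO[bytes]]


@dataclass
class Msa:
    """A multiple sequence alignment: ``n`` rows of identical length ``l``.

    Attributes
    ----------
    headers:
        Verbatim FASTA description lines (no ``>``), one per row, in file
        order.
    rows:
        The aligned character strings.  Gaps (``-``) are ordinary
        characters.
    """

    headers: list[str]
    rows: list[str]
    _codes_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise NotAnAlignmentError("no records: an alignment needs at least one sequence")
        if len(self.headers) != len(self.rows):
            raise NotAnAlignmentError(
                f"{len(self.headers)} headers for {len(self.rows)} rows"
            )
        l = len(self.rows[0])
        if l == 0:
            raise NotAnAlignmentError("not an alignment: record 1 has length 0")
        for k, row in enumerate(self.rows):
            if len(row) != l:
                raise NotAnAlignmentError(
                    "not an alignment: record {} has length {}, expected {} "
                    "(record 1)".format(k + 1, len(row), l)
                )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def l(self) -> int:  # noqa: E743 - matches field convention for alignment length
        return len(self.rows[0])

    @property
    def alphabet(self) -> tuple[str, ...]:
        """Sorted tuple of the distinct characters actually observed."""
        return self.codes()[1]

    def codes(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Integer-coded matrix view plus the sorted alphabet behind it.

        Returns an ``(n, l)`` array of indices into the sorted alphabet.
        Cached — the Msa is treated as immutable after construction.
        """
        if self._codes_cache is None:
            mat = np.frombuffer(
                "".join(self.rows).encode("utf-32-le"), dtype=np.uint32
            ).reshape(self.n, self.l)
            alpha_points = np.unique(mat)
            alphabet = tuple(chr(c) for c in alpha_points)
            codes = np.searchsorted(alpha_points, mat).astype(np.int32)
            object.__setattr__(self, "_codes_cache", (codes, alphabet))
        return self._codes_cache


def _text_stream(source: Source, mode: str) -> tuple[IO[str], bool]:
    """Return a text handle and whether the caller owns (must close) it."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream
    return io.TextIOWrapper(source, encoding="utf-8", newline=""), False


def read_fasta_msa(source: Source) -> Msa:
    """Parse FASTA text into an :class:`Msa`.

    Line-wrapped records are joined; headers are kept verbatim; both Unix
    and Windows line endings are accepted.  Raises
    :class:`FastaFormatError` for empty or malformed input and
    :class:`NotAnAlignmentError` when record lengths differ.
    """
    handle, owned = _text_stream(source, "r")
    try:
        text = handle.read()
    finally:
        if owned:
            handle.close()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError("format error: sequence data before first '>' header")
    headers: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        headers.append(rec.description)
        rows.append(str(rec.seq))
    if not headers:
        raise FastaFormatError("no records found in FASTA input")
    return Msa(headers=headers, rows=rows)


def write_fasta_msa(msa: Msa, sink: Source, line_width: int = 60) -> None:
    """Write ``msa`` as FASTA, wrapping sequence lines at ``line_width``.

    The output re-parses to an Msa equal to the input (headers, rows,
    order, case).  A handwritten writer is used instead of SeqIO so that
    degenerate headers (including the empty header) round-trip verbatim.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    handle, owned = _text_stream(sink, "w")
    try:
        for header, row in zip(msa.headers, msa.rows):
            handle.write(">" + header + "\n")
            for start in range(0, len(row), line_width):
                handle.write(row[start : start + line_width] + "\n")
    finally:
        if owned:
            handle.close()


def msa_from_rows(rows: Iterable[str], headers: Iterable[str] | None = None) -> Msa:
    """Convenience constructor used heavily by tests and the generator."""
    rows = list(rows)
    if headers is None:
        headers = [f"seq{i}" for i in range(len(rows))]
    return Msa(headers=list(headers), rows=rows)
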