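"""Bit-cost model, mismatch-run deltas, and the encodability graph.

The central object is a directed weighted graph on the alignment's rows
plus one dummy root vertex.  The weight of edge (i, j) is the *exact*
serialized size, in bits, of the delta record that reconstructs row j from
row i; the weight of the root edge into i is the exact size of storing row
i verbatim as a reference.  Because edge weights equal true record sizes,
the minimum spanning arborescence of this graph minimizes the actual
pre-backend archive size (cost-fidelity).

Costs are parameterized by two integers derived from the alignment:

* ``N`` — bits per character, ``ceil(log2(alphabet size))``;
* ``I`` — bits per index, ``ceil(log2(max(n, l)))``,

both clamped to at least 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._bitio import varint_bit_length
from .errors import NotAnAlignmentError
from .msa_io import Msa

#: Vertex id of the dummy root (lower than any row index by convention).
ROOT = -1

#: One bit per record distinguishes reference from delta on the wire.
RECORD_FLAG_BITS = 1


@dataclass(frozen=True)
class CostModel:
    """Fixed-width bit costs for one alignment.

    ``bits_per_char`` (N) is the width of one packed character;
    ``bits_per_index`` (I) the width of a row or column index.  Both are
    file-level constants so every record is decodable from (n, l, alphabet)
    alone.
    """

    bits_per_char: int
    bits_per_index: int

    def __post_init__(self) -> None:
        if self.bits_per_char < 1 or self.bits_per_index < 1:
            raise ValueError("bit widths must be positive")

    @classmethod
    def from_msa(cls, msa: Msa) -> "CostModel":
        n_chars = len(msa.alphabet)
        N = max(1, math.ceil(math.log2(n_chars))) if n_chars > 1 else 1
        span = max(msa.n, msa.l)
        I = max(1, math.ceil(math.log2(span))) if span > 1 else 1
        return cls(bits_per_char=N, bits_per_index=I)


@dataclass(frozen=True)
class MismatchRun:
    """A maximal block of consecutive columns where target differs from
    reference: ``chars`` replaces the reference at columns
    ``start .. start + len(chars) - 1``."""

    start: int
    chars: str

    def __post_init__(self) -> None:
        if self.start < 0 or not self.chars:
            raise ValueError("run needs a non-negative start and non-empty chars")


def mismatch_runs(ref_row: str, target_row: str) -> list[MismatchRun]:
    """Maximal substitution runs turning ``ref_row`` into ``target_row``.

    Rows are aligned, so column-wise substitution suffices — gaps are
    ordinary characters.  Raises for unequal lengths.
    """
    if len(ref_row) != len(target_row):
        raise NotAnAlignmentError(
            f"not comparable: rows of length {len(ref_row)} and {len(target_row)}"
        )
    a = np.frombuffer(ref_row.encode("utf-32-le"), dtype=np.uint32)
    b = np.frombuffer(target_row.encode("utf-32-le"), dtype=np.uint32)
    diff = np.nonzero(a != b)[0]
    if diff.size == 0:
        return []
    breaks = np.nonzero(np.diff(diff) > 1)[0] + 1
    runs = []
    for seg in np.split(diff, breaks):
        start = int(seg[0])
        runs.append(MismatchRun(start=start, chars=target_row[start : start + len(seg)]))
    return runs


def run_payload_bits(runs: list[MismatchRun], cm: CostModel) -> int:
    """Index-plus-characters cost of the runs: Σ (I + N·len(chars)).

    This is the classic representational cost of a delta — one index per
    run plus one packed character per mismatched column — excluding the
    record's structural fields (type flag, row ids, counts, lengths).
    """
    I, N = cm.bits_per_index, cm.bits_per_char
    return sum(I + N * len(r.chars) for r in runs)


def delta_record_bits(runs: list[MismatchRun], cm: CostModel) -> int:
    """Exact wire size of a delta record carrying ``runs``.

    Layout: type flag, target row id (I bits), parent row id (I bits),
    varint run count, then per run: start column (I bits), varint length,
    characters at N bits each.
    """
    I, N = cm.bits_per_index, cm.bits_per_char
    bits = RECORD_FLAG_BITS + 2 * I + varint_bit_length(len(runs))
    for r in runs:
        bits += I + varint_bit_length(len(r.chars)) + N * len(r.chars)
    return bits


def reference_record_bits(l: int, cm: CostModel) -> int:
    """Exact wire size of a reference record: flag + row id + l characters."""
    return RECORD_FLAG_BITS + cm.bits_per_index + l * cm.bits_per_char


def pair_cost(ref_index: int, target_index: int, msa: Msa, cm: CostModel) -> int:
    """Bits needed to store row ``target_index`` as a delta against
    ``ref_index`` — exactly what the codec will emit for that record."""
    if ref_index == target_index:
        raise ValueError("reference and target must be distinct rows")
    runs = mismatch_runs(msa.rows[ref_index], msa.rows[target_index])
    return delta_record_bits(runs, cm)


def reference_cost(seq_index: int, msa: Msa, cm: CostModel) -> int:
    """Bits needed to store row ``seq_index`` verbatim: I + l·N plus the
    record's fixed overhead.  Identical for every row of one alignment."""
    if not 0 <= seq_index < msa.n:
        raise IndexError(seq_index)
    return reference_record_bits(msa.l, cm)


@dataclass
class EncodabilityGraph:
    """Dummy-rooted directed graph whose edge weights are record sizes.

    ``graph`` is a networkx DiGraph on vertices {ROOT, 0..n-1}; every row
    has a root in-edge (reference storage cost), and rows sharing a sliding
    window form a bidirected clique of delta costs.  Root-connectivity is
    therefore structural: a spanning arborescence always exists.
    """

    graph: nx.DiGraph
    cost_model: CostModel
    n: int

    def weight(self, u: int, v: int) -> int:
        return self.graph.edges[u, v]["weight"]


def build_encodability_graph(
    msa: Msa, windows: list[list[int]], cm: CostModel | None = None
) -> EncodabilityGraph:
    """Assemble the graph from sliding-window cliques plus root edges.

    A pair appearing in several overlapping windows gets a single edge —
    the cost is deterministic, duplicates are redundant.  Pairwise delta
    costs are computed column-wise on the integer-coded matrix.
    """
    if cm is None:
        cm = CostModel.from_msa(msa)
    covered = set()
    for w in windows:
        covered.update(w)
    if covered != set(range(msa.n)):
        raise ValueError("windows must cover every row index exactly once or more")

    g = nx.DiGraph()
    g.add_node(ROOT)
    ref_bits = reference_record_bits(msa.l, cm)
    for i in range(msa.n):
        g.add_edge(ROOT, i, weight=ref_bits)

    codes, _ = msa.codes()
    I, N = cm.bits_per_index, cm.bits_per_char
    for w in windows:
        for ai, i in enumerate(w):
            row_i = codes[i]
            for j in w[ai + 1 :]:
                if g.has_edge(i, j):
                    continue
                neq = row_i != codes[j]
                diff = np.nonzero(neq)[0]
                if diff.size == 0:
                    bits = RECORD_FLAG_BITS + 2 * I + varint_bit_length(0)
                    g.add_edge(i, j, weight=bits)
                    g.add_edge(j, i, weight=bits)
                    continue
                # run structure is direction-independent for substitutions;
                # only char case differs, and len(chars) is shared, so the
                # two directed weights coincide under this wire format.
                breaks = np.nonzero(np.diff(diff) > 1)[0]
                n_runs = breaks.size + 1
                seg_lengths = np.diff(
                    np.concatenate(([0], breaks + 1, [diff.size]))
                )
                bits = RECORD_FLAG_BITS + 2 * I + varint_bit_length(n_runs)
                bits += n_runs * I + N * diff.size
                bits += sum(varint_bit_length(int(s)) for s in seg_lengths)
                g.add_edge(i, j, weight=int(bits))
                g.add_edge(j, i, weight=int(bits))
    return EncodabilityGraph(graph=g, cost_model=cm, n=msa.n)
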