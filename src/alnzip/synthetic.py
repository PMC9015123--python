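"""Reproducible synthetic alignments with controlled redundancy.

The generator emulates the one property the compressor exploits — graded
similarity between rows — without pretending to be an evolutionary
simulator.  A root row is drawn uniformly over the non-gap alphabet and
copied down a tree (star, random binary, or k clusters around divergent
centres); along each branch every site is independently redrawn uniformly
over the alphabet with probability ``substitution_prob``.  Redrawing (which
may re-pick the same character) makes ``substitution_prob = 1`` the
saturation point where rows are i.i.d. uniform and the expected pairwise
mismatch fraction is (|Σ|−1)/|Σ|.

Gaps are overlaid afterwards: short gap runs are written into randomly
chosen column ranges of random row subsets, keeping all rows the same
length — the generator produces alignments, never raw sequences, so gaps
replace characters rather than shifting them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Msa

DNA_GAP_ALPHABET = ("a", "c", "g", "t", "-")
PROTEIN_GAP_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + ("-",)


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the generator.

    substitution_prob — per-site probability, per tree branch, that the
        site is redrawn uniformly over the non-gap alphabet (0 = clones,
        1 = saturation).
    gap_run_prob — per-column probability that a gap run *starts* there;
        each run covers a geometric-ish short span (1–8 columns) in a
        random subset of rows, emulating shared indel columns.
    tree — "star" (all rows one branch from the root), "binary" (random
        bifurcating topology, one branch per edge), or "clustered" with
        ``k_clusters`` centres far from each other and tight members.
    """

    n: int = 50
    l: int = 500  # noqa: E741
    substitution_prob: float = 0.02
    gap_run_prob: float = 0.01
    tree: str = "clustered"
    k_clusters: int = 4
    alphabet: tuple[str, ...] = DNA_GAP_ALPHABET
    gap_char: str = "-"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.l < 1:
            raise ValueError("n and l must be positive")
        if not 0.0 <= self.substitution_prob <= 1.0:
            raise ValueError("substitution_prob must be in [0, 1]")
        if not 0.0 <= self.gap_run_prob <= 1.0:
            raise ValueError("gap_run_prob must be in [0, 1]")
        if self.tree not in ("star", "binary", "clustered"):
            raise ValueError(f"unknown tree shape: {self.tree!r}")
        if self.tree == "clustered" and self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")


def _mutate(row: np.ndarray, prob: float, n_sym: int, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(row.size) < prob
    out = row.copy()
    out[mask] = rng.integers(0, n_sym, mask.sum())
    return out


def _binary_topology(
    n: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], list[int]]:
    """Random bifurcating tree as (parent, child) edges over node ids.

    Node 0 is the root; leaves are the last n ids.  Built by random
    sequential attachment: each new leaf splits a uniformly chosen branch.
    """
    # grow a leaf set by splitting; represent as parent pointers
    parents = {1: 0, 2: 0}
    leaves = [1, 2]
    next_id = 3
    while len(leaves) < n:
        split = leaves[rng.integers(0, len(leaves))]
        parents[next_id] = split
        parents[next_id + 1] = split
        leaves.remove(split)
        leaves.extend([next_id, next_id + 1])
        next_id += 2
    return [(p, c) for c, p in parents.items()], leaves


def generate_msa(p: EvolutionParams) -> Msa:
    """Draw a seeded synthetic alignment under ``p``."""
    rng = np.random.default_rng(p.seed)
    core = [c for c in p.alphabet if c != p.gap_char]
    n_sym = len(core)
    root = rng.integers(0, n_sym, p.l)

    if p.n == 1:
        rows_codes = [root]
    elif p.tree == "star":
        rows_codes = [_mutate(root, p.substitution_prob, n_sym, rng) for _ in range(p.n)]
    elif p.tree == "binary":
        if p.n == 2:
            rows_codes = [_mutate(root, p.substitution_prob, n_sym, rng) for _ in range(2)]
        else:
            edges, leaves = _binary_topology(p.n, rng)
            node_rows = {0: root}
            for parent, child in sorted(edges, key=lambda e: e[1]):
                node_rows[child] = _mutate(
                    node_rows[parent], p.substitution_prob, n_sym, rng
                )
            rows_codes = [node_rows[leaf] for leaf in sorted(leaves)]
    else:  # clustered
        centre_prob = min(1.0, 10.0 * p.substitution_prob) or 0.3
        centres = [
            _mutate(root, centre_prob, n_sym, rng) for _ in range(p.k_clusters)
        ]
        rows_codes = [
            _mutate(centres[i % p.k_clusters], p.substitution_prob, n_sym, rng)
            for i in range(p.n)
        ]

    mat = np.stack(rows_codes)
    chars = np.array(core, dtype="<U1")[mat]

    # shared gap-run overlay
    if p.gap_run_prob > 0 and p.n >= 1:
        starts = np.nonzero(rng.random(p.l) < p.gap_run_prob)[0]
        for s in starts:
            span = int(rng.integers(1, 9))
            member = rng.random(p.n) < rng.uniform(0.2, 0.9)
            if not member.any():
                member[rng.integers(0, p.n)] = True
            chars[member, s : s + span] = p.gap_char

    rows = ["".join(r) for r in chars]
    headers = [f"synthetic_{p.tree}_{p.seed}_{i}" for i in range(p.n)]
    return Msa(headers=headers, rows=rows)
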