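"""Column-profile likelihood ranking and sliding-window clique layout.

Each row of an alignment is scored by how "typical" it is of the alignment
as a whole: treating columns as independent, the probability of character
``x`` at column ``j`` is its relative frequency in that column, and a row's
log-likelihood is the sum of the log column probabilities of its own
characters.  Rows with similar scores tend to be similar to each other, so
sorting by score and connecting only rows that share a sliding window gives
a sparse candidate-reference graph at O(n·l) cost instead of the O(n²·l)
all-pairs cost matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Msa


@dataclass
class ColumnProfiles:
    """Per-column character occurrence counts for an alignment.

    ``counts`` has shape ``(l, A)`` where ``A`` is the alphabet size; entry
    ``counts[j, a]`` is the number of rows carrying alphabet character ``a``
    at column ``j``.  Every column's counts sum to ``n``.
    """

    counts: np.ndarray
    alphabet: tuple[str, ...]
    n: int
    l: int  # noqa: E741
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {c: a for a, c in enumerate(self.alphabet)}

    def count(self, char: str, column: int) -> int:
        """Occurrence count of ``char`` at ``column`` (0 if absent)."""
        a = self._index.get(char)
        return 0 if a is None else int(self.counts[column, a])

    def p(self, char: str, column: int) -> float:
        """Empirical probability of ``char`` at ``column``."""
        return self.count(char, column) / self.n


def column_profiles(msa: Msa) -> ColumnProfiles:
    """Count character occurrences per column."""
    codes, alphabet = msa.codes()
    A = len(alphabet)
    flat = codes + np.arange(msa.l, dtype=np.int64) * A
    counts = np.bincount(flat.ravel(), minlength=msa.l * A).reshape(msa.l, A)
    return ColumnProfiles(counts=counts, alphabet=alphabet, n=msa.n, l=msa.l)


def all_log_likelihoods(msa: Msa, profiles: ColumnProfiles | None = None) -> np.ndarray:
    """Log-likelihood of every row under the column profiles, in nats.

    Scores are always finite (each row's own character contributes at least
    a count of 1, so every probability is >= 1/n) and always <= 0.
    """
    if profiles is None:
        profiles = column_profiles(msa)
    codes, _ = msa.codes()
    picked = np.take_along_axis(profiles.counts.T, codes, axis=0)  # (n, l)
    return np.log(picked).sum(axis=1) - msa.l * np.log(msa.n)


def sequence_log_likelihood(
    row_index: int, msa: Msa, profiles: ColumnProfiles
) -> float:
    """Sum over columns of log p(character | column profile) for one row."""
    codes, _ = msa.codes()
    picked = profiles.counts[np.arange(msa.l), codes[row_index]]
    return float(np.log(picked).sum() - msa.l * np.log(msa.n))


def rank_by_likelihood(msa: Msa) -> list[int]:
    """Row indices sorted by descending log-likelihood.

    Ties break by ascending original row index, so the permutation (and
    everything downstream of it, including archive bytes) is deterministic.
    """
    lls = all_log_likelihoods(msa)
    return sorted(range(msa.n), key=lambda i: (-lls[i], i))


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry over the likelihood-sorted row list.

    ``window_length`` rows form a clique in the encodability graph; windows
    advance by ``step = window_length - overlap`` rows.  The defaults (30
    with overlap 20) are the densest setting of the standard grid — larger
    windows buy better compression for more cost-matrix work.
    """

    window_length: int = 30
    overlap: int = 20

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2 (a window of 1 creates no edges)")
        if not 0 <= self.overlap < self.window_length:
            raise ValueError("overlap must satisfy 0 <= overlap < window_length")

    @property
    def step(self) -> int:
        return self.window_length - self.overlap


def sliding_windows(order: list[int], cfg: WindowConfig) -> list[list[int]]:
    """Cut the sorted order into overlapping windows (the graph's cliques).

    Windows start at 0, step, 2·step, …; the last window is clipped to end
    exactly at position n so the tail rows still sit in a full-size clique.
    With n > window_length the window count is
    ``ceil((n - window_length) / step) + 1``; otherwise there is a single
    window holding every index.
    """
    n = len(order)
    lw, ls = cfg.window_length, cfg.step
    if n <= lw:
        return [list(order)]
    starts = list(range(0, n - lw, ls))
    starts.append(n - lw)
    return [list(order[s : s + lw]) for s in starts]
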