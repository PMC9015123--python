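"""Diagnostics and benchmark harnesses.

Two divergence diagnostics are provided:

* :func:`average_hamming_distance` — the sum of pairwise Hamming
  distances divided by ``L·N`` (alignment length times sequence count),
  exactly as defined; note the normalization is *not* by pair count, so
  the value grows with ``N`` and can exceed 1 for divergent alignments.
* :func:`average_p_distance` — mean over unordered pairs of the fraction
  of mismatching columns among columns where neither row has a gap.

The sweep harnesses run the full compression pipeline over window-config
grids and divergence grids and return tidy DataFrames, one row per run.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd

from . import codec
from .arborescence import minimum_spanning_arborescence
from .graph import build_encodability_graph
from .likelihood import WindowConfig, rank_by_likelihood, sliding_windows
from .msa_io import Msa, write_fasta_msa
from .synthetic import EvolutionParams, generate_msa
import io


def average_hamming_distance(msa: Msa) -> float:
    """(Σ_{i<j} Hamming(S_i, S_j)) / (L·N) with N = rows, L = columns.

    Computed from column character counts: a column with counts
    {c_x} contributes (N² − Σ c_x²)/2 mismatching pairs.
    """
    if msa.n < 2:
        raise ValueError("average Hamming distance needs at least 2 sequences")
    codes, alphabet = msa.codes()
    A = len(alphabet)
    flat = codes + np.arange(msa.l, dtype=np.int64) * A
    counts = np.bincount(flat.ravel(), minlength=msa.l * A).reshape(msa.l, A)
    total_mismatch_pairs = (
        msa.l * msa.n**2 - (counts.astype(np.int64) ** 2).sum()
    ) // 2
    return float(total_mismatch_pairs) / (msa.l * msa.n)


def average_p_distance(msa: Msa, gap_char: str = "-") -> float:
    """Mean pairwise p-distance, excluding gap-containing columns pairwise.

    For each unordered row pair, columns where either row carries a gap
    are dropped from numerator and denominator.  Pairs with no comparable
    columns are skipped with a warning.
    """
    if msa.n < 2:
        raise ValueError("average p-distance needs at least 2 sequences")
    codes, alphabet = msa.codes()
    try:
        gap_code = alphabet.index(gap_char)
        not_gap = codes != gap_code
    except ValueError:
        not_gap = np.ones_like(codes, dtype=bool)
    vals = []
    skipped = 0
    for i in range(msa.n):
        for j in range(i + 1, msa.n):
            comparable = not_gap[i] & not_gap[j]
            m = int(comparable.sum())
            if m == 0:
                skipped += 1
                continue
            mism = int((codes[i][comparable] != codes[j][comparable]).sum())
            vals.append(mism / m)
    if skipped:
        warnings.warn(
            f"{skipped} gap-saturated pair(s) had no comparable columns and were skipped",
            stacklevel=2,
        )
    if not vals:
        raise ValueError("no pair had comparable columns")
    return float(np.mean(vals))


def _fasta_bytes(msa: Msa) -> bytes:
    buf = io.StringIO()
    write_fasta_msa(msa, buf)
    return buf.getvalue().encode("utf-8")


def compression_stats(
    msa: Msa, cfg: WindowConfig | None = None, backend: str = codec.DEFAULT_BACKEND
) -> dict:
    """Run the pipeline once and measure every size along the way."""
    if cfg is None:
        cfg = WindowConfig()
    t0 = time.perf_counter()
    order = rank_by_likelihood(msa)
    windows = sliding_windows(order, cfg)
    eg = build_encodability_graph(msa, windows)
    ma = minimum_spanning_arborescence(eg)
    archive = codec.encode_archive(msa, ma, backend=backend)
    inner = codec.serialize_archive(archive)
    blob = codec.envelope(inner, backend)
    elapsed = time.perf_counter() - t0
    raw = _fasta_bytes(msa)
    return {
        "n": msa.n,
        "l": msa.l,
        "window_length": cfg.window_length,
        "overlap": cfg.overlap,
        "backend": backend,
        "raw_bytes": len(raw),
        "pre_backend_bytes": len(inner),
        "compressed_bytes": len(blob),
        "compression_ratio": len(raw) / len(blob),
        "n_references": len(ma.references),
        "arborescence_weight_bits": ma.total_weight,
        "wall_time_s": elapsed,
    }


def sweep_windows(
    msa: Msa,
    configs: list[WindowConfig] | None = None,
    backend: str = codec.DEFAULT_BACKEND,
    input_id: str = "msa",
) -> pd.DataFrame:
    """Benchmark one alignment across window configurations.

    Default grid: the standard (window, overlap) ladder 5/3, 10/7, 20/15,
    30/20 plus the single-full-window densification bound (window = n).
    """
    if configs is None:
        configs = [
            WindowConfig(5, 3),
            WindowConfig(10, 7),
            WindowConfig(20, 15),
            WindowConfig(30, 20),
        ]
        if msa.n >= 2:
            configs.append(WindowConfig(max(msa.n, 2), 0))
    rows = []
    for cfg in configs:
        stats = compression_stats(msa, cfg, backend)
        stats["input_id"] = input_id
        stats["average_hamming_distance"] = (
            average_hamming_distance(msa) if msa.n >= 2 else 0.0
        )
        rows.append(stats)
    return pd.DataFrame(rows)


def divergence_sweep(
    params_grid: list[EvolutionParams], backend: str = codec.DEFAULT_BACKEND
) -> pd.DataFrame:
    """Compression ratio versus divergence over a generator-parameter grid.

    One pipeline run per EvolutionParams (each carries its own seed);
    correlate ``average_hamming_distance`` against ``compression_ratio``
    downstream — more divergence should mean less compression.
    """
    rows = []
    for p in params_grid:
        msa = generate_msa(p)
        stats = compression_stats(msa, None, backend)
        stats["input_id"] = f"synth_s{p.seed}"
        stats["substitution_prob"] = p.substitution_prob
        stats["seed"] = p.seed
        stats["average_hamming_distance"] = (
            average_hamming_distance(msa) if msa.n >= 2 else 0.0
        )
        rows.append(stats)
    return pd.DataFrame(rows)
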