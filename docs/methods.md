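# Methods

## Model

An alignment is `n` rows of length `l` over an observed alphabet Σ
(gap `-` is an ordinary symbol; upper- and lower-case letters are
distinct, because the tool promises byte-exact reconstruction and takes
no view on biological equivalence). The compressor chooses, for every
row, either verbatim storage or delta storage against one parent row,
subject to the parent relation forming a forest whose roots are the
verbatim rows. With all candidate costs expressed in bits, that choice
is exactly a minimum spanning arborescence in a directed graph with a
dummy root: root edges price verbatim storage, row-to-row edges price
delta storage, and any spanning arborescence is a feasible archive whose
total weight is its payload size. Minimizing total weight therefore
minimizes the real pre-backend archive, which is why edge weights here
are defined as *serialized record sizes*, not abstract distances
(cost-fidelity; asserted exactly in the test suite).

## Likelihood heuristic and sparsification

The full cost matrix needs `O(n²·l)` work. To avoid it, rows are ranked
by `Σ_j log(F_{S_ij,j} / n)` — the log-probability of the row under its
own alignment's column profiles, assuming column independence. The score
is a similarity-to-consensus measure: rows with close scores tend to be
similar. A sliding window (length `l_w`, step `l_s = l_w − overlap`)
over the ranked list yields `⌈(n−l_w)/l_s⌉ + 1` cliques (for
`n > l_w`), giving `O(n)` edges and `O(n·l)` cost-matrix work. The last
window is clipped to end exactly at position `n`, so tail rows still
get a full-size candidate set. Sorting direction (descending) and the
tie rule (ascending original index) are fixed so archives are
bit-reproducible. Natural log is used; only the ordering matters.

Defaults `l_w = 30`, `overlap = 20` are the densest point of the
standard benchmark ladder (5/3, 10/7, 20/15, 30/20); larger windows
monotonically improve the achievable total weight (edge-set growth can
only help the optimum, which the tests assert at the total-weight
level) at quadratic-in-`l_w` cost-matrix expense.

## Wire format and cost model

`N = max(1, ⌈log₂|Σ|⌉)` bits per character, `I = max(1, ⌈log₂ max(n,
l)⌉)` bits per index; both stored in the archive header. Records are
bit-packed back to back:

* reference: 1 flag bit, row id (`I`), `l` characters (`N` each) —
  i.e. the classic `I + l·N` reference cost plus the 1-bit flag;
* delta: 1 flag bit, row id (`I`), parent id (`I`), varint run count,
  then per run a start column (`I`), a varint length, and the
  replacement characters (`N` each). The index-plus-characters part is
  the classic per-run cost `I + N·len`; a two-run, four-character delta
  carries exactly `2I + 4N` bits of run payload.

Varints are LEB128. The inner stream (dimensions, alphabet, cost
parameters, verbatim headers, records in parents-first topological
order with siblings by ascending original index) is compressed by the
chosen backend (bzip2 default; gzip pins `mtime=0` for reproducible
bytes) and wrapped in an envelope with magic, version, backend id,
declared payload length and a CRC32 that is verified on decode.
Truncation, checksum failure and unknown magic raise distinguishable
errors.

Because deltas are column-wise substitution runs on equal-length rows,
the mismatch-position set — and hence the run structure and both
directed edge weights — is symmetric between any two rows; only the
stored characters differ by direction. The directed-graph machinery is
kept because the arborescence needs directions, not because the weights
differ under this wire format.

## Arborescence solver

The solver wraps networkx's Edmonds/Chu-Liu implementation. Ties are
resolved by a lexicographic objective folded into integer weights
(primary: total bits; secondary: sum of parent vertex ids with the root
lowest), so equal-cost optima cannot make archive bytes drift between
runs. An exhaustive oracle enumerates every parent map (vectorised,
`n ≤ 8`), keeps the acyclic root-connected ones, and certifies the
solver's optimality on hundreds of random graphs in the test suite —
this is the testable content of the claim that the arborescence defines
an optimal reference set.

## Synthetic data

The generator emulates graded redundancy, the one property the
compressor exploits. A uniform random root row evolves down a tree;
along each branch every site is redrawn uniformly over the non-gap
alphabet with probability `substitution_prob`, so `1.0` is saturation
(i.i.d. uniform rows, expected pairwise mismatch `(|Σ|−1)/|Σ|`). Tree
shapes: `star`, random `binary`, and `clustered` (k centres drawn at
10× the member divergence, members tight around centres). Short gap
runs (1–8 columns) overwrite random column ranges in random row
subsets, emulating shared indel columns while keeping rows equal
length — the tool consumes alignments, so gaps replace characters and
no true indels are simulated.

`clustered` (k = 4) is the default topology: collections of homologous
sequences have phylogenetic group structure, which is what makes
reference-based storage profitable; a star of independently noised rows
is the least favourable realistic case and is retained in the test
grids. Default sizes (n = 50, l = 500, 2% substitution, 1% gap-run
probability) are a mid-sized, mid-divergence gene alignment.

What passing tests on this data do *not* show: performance on real
alignments with rate heterogeneity, alignment-error artifacts, long
indel blocks, or protein substitution structure — the generator draws
substitutions uniformly, so real archives may contain more (or less)
entropy per mismatch than synthetic ones.

## Numerical and degenerate-input choices

* All weights are integer bit counts — no floating point in the solver.
* One-symbol alphabets and `n = 1` or `l = 1` alignments are valid
  (`N` and `I` clamp to 1 bit).
* Identical rows produce empty-run deltas; an all-identical alignment
  stores one reference plus `n − 1` empty deltas.
* A pair with zero comparable (non-gap) columns is skipped with a
  warning in `average_p_distance`; the average Hamming distance follows
  the `Σ pairwise Hamming / (L·N)` normalization verbatim, so it is not
  bounded by 1.
* Problem sizes in the test and acceptance harnesses (e.g. 100 × 500
  window sweeps, 40 × 300 divergence grids, 100 × 2000 backend
  comparisons, fuzz sizes log-uniform over n ≤ 200, l ≤ 5000) are the
  package's chosen study scale for desk-side certification of trends
  and exact invariants.

## Known limitations

* No random access or streaming decode; archives decode whole.
* No protein-specific modelling; protein alphabets work but are packed
  at `⌈log₂|Σ|⌉` bits like any other symbol set.
* The entropy backend sees one concatenated stream (references +
  metadata + headers); no per-block backend selection.
* `O(V·E)` Edmonds; dense full-window graphs on large `n` are slow by
  construction and only used as the densification bound.
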