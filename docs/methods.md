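# Methods

## Model and definitions

The collection *G* is an ordered list of genes, each a string over
{A,C,G,T}; order defines `gene_index`, the identity used everywhere. For a
threshold *n* and seat length *N* (*n* < *N*), two *N*-strings from
*different* genes are duplicates iff they share any length-*n* substring;
repeats within one gene never disqualify anything. A seat is an *N*-string
(boundary-truncated to as short as *n*) all of whose length-*n* windows
occur in exactly one gene. The kernel scale *n* is the stringency dial: it
is the shortest stretch of perfect complementarity the design guards
against, so smaller *n* is stricter and yields fewer seats.

## Data structure

Kernels live in a depth-*n* 4-ary trie. Each internal node holds four
child slots (A,C,G,T), allocated on demand; depth-*n* leaves hold the
ordered occurrence list and a boolean duplicate flag. The flag, not a
counter: it is only ever set once a second distinct gene contributes an
occurrence, and nothing downstream needs duplication multiplicity. The
structure has no horizontal links between same-depth nodes and no suffix
links — insertion is per k-mer, O(n) per occurrence, which also makes
incremental addition of genes trivial: inserting a new gene's kernels
updates flags in place, and the result is observationally identical to a
fresh build (a tested contract).

The complete tree over levels 0..*n* has (4^(n+1) − 1)/3 vertices
(`full_tree_nodes`); this is the node-count bound and the denominator of
the fill-in statistic. The byte figures in `trie_stats` are a storage
model, not process measurements: 24 bytes per tree node, plus
G·(13·ΔL + 16) bytes for gene and occurrence records for G genes of mean
length ΔL (12 bytes per indexed position plus one sequence byte, and a
16-byte per-gene record). They estimate what a compact C layout of this
index would occupy.

## Seat emission: two modes

`per-leaf` (default): one candidate per distinct unique kernel, anchored
at its first recorded occurrence in scan order, extended rightward by the
available ≤ *N − n* characters; candidates passing the all-windows-unique
test are seats, with no containment filtering. This is the reading under
which the three-gene demonstration yields 13 leaves → 11 unique kernels →
7 seats, boundary-truncated seats (GGC, CCC) included.

`per-occurrence`: one candidate per occurrence of each unique kernel; the
passing set then equals, provably and by test, the exhaustive enumeration
of every window whose *n*-windows are all unique. A maximality filter then
drops any seat whose interval is wholly contained in another seat's
interval of the same gene (identical intervals keep the first generated).
This is the literal "all maximal unique substrings" reading. Both modes
extend rightward only; seats shorter than *N* can therefore occur only at
a gene's right boundary.

`min_output_length` is an output-time filter (the public seat databases
list seats ≥ 19 nt); pipeline counts are always reported before it.

## Input handling

FASTA is read via Biopython; file order is preserved. Sequences are
uppercased and U→T mapped so mRNA-style input works on the DNA alphabet.
Ambiguous characters default to `mask`: the character stays in place but
every k-mer window overlapping it is excluded from indexing, so masking
can neither create nor destroy uniqueness of unaffected kernels (a
property test). `reject` raises at the first offending position (1-based
in the message). Internal coordinates are 0-based; all user-facing output
is 1-based inclusive. Genes shorter than *n* are accepted and skipped with
a warning.

## Synthetic data

`synth_transcriptome` draws i.i.d. bases from a configurable composition
(uniform by default) at lengths uniform in a range, then overwrites
planted motifs at fixed (gene, position) slots — planting after the fill
guarantees the cross-gene duplicates exist; overlapping plants resolve
later-wins. This emulates only what the uniqueness machinery is sensitive
to: sequence length, composition, and exact shared substrings. It does not
emulate codon bias, GC heterogeneity, repeat families or paralogy, so
passing tests certify algorithmic correctness, not seat yields on real
transcriptomes (real mRNA has far more kernel sharing than an i.i.d.
model at the same composition).

## Verification strategy and problem sizes

Correctness rests on dual routes: a flat-dictionary brute-force oracle
(string → set of owning genes; exhaustive window enumeration for seats)
that shares no code with the trie. The cross-validation harness draws
seeded random cases — up to 20 genes of length up to 200, *n* in 2..6,
*N* up to *n*+10 — sizes at which the exhaustive oracle is instant while
still exercising boundary truncation, same-gene repeats and cross-gene
sharing; the acceptance suite runs 100 such cases for set equality and 50
for incremental-vs-rebuild equality. Hypothesis property tests
(derandomized) cover the structural invariants: node-count bound,
occurrence conservation Σ(L−n+1), gene-order invariance, monotonicity of
duplication under gene addition, seat soundness by direct substring search.

## Design choices

- The full-tree size is counted as vertices including the root,
  (4^(n+1) − 1)/3 — the convention consistent with the reported tabulated
  sizes — not as edges.
- `build_trie` is repeated `add_gene`: one code path for batch and
  incremental indexing; equivalence evidence comes from the independent
  oracle rather than from comparing a path with itself.
- The index persistence format (CLI `add`) is versioned JSON of genes plus
  per-leaf occurrence lists, reloaded by replaying insertions. It is an
  internal format, not for interchange.
- CLI defaults n=13, N=21, min-len 19: 21 nt is the standard siRNA target
  length, stretches of ~11–15 nt of identity suffice for off-target
  silencing (so 13 sits mid-range), and 19 is the customary minimum
  listed seat length.

## Limitations

- Uniqueness is exact-match only: no mismatch tolerance, no G:U wobble,
  no miRNA-like seed matches. A seat guarantees absence of perfect
  ≥ *n*-mer sharing, nothing weaker.
- Seats are placement windows only; no efficacy scoring (GC content,
  thermodynamic asymmetry, secondary structure) is applied — seats are
  intended as input to such tools.
- Pure-Python node objects make transcriptome-scale runs at n ≥ 13
  memory-hungry relative to a packed C layout; the storage-model estimate
  quantifies the compact layout, not this implementation.
- Removing a gene from an index is not supported; rebuild instead.
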