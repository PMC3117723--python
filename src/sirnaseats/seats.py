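"""Seat extraction: unique kernels, rightward extension, uniqueness test.

A *seat* is a substring of length N within one gene, every length-n
substring of which occurs in no other gene — a placement window for an
siRNA with minimized off-target hybridization. The pipeline: build the
depth-n trie, list the unique kernels, extend each rightward by the N-n
characters available in its gene (truncating at the right boundary, so a
seat is never shorter than n), and keep a candidate iff all of its
length-n windows are unique.

Two emission modes exist because "one candidate per unique kernel" and
"all maximal unique windows" are different readings of the same problem:

* ``per-leaf`` (default): one candidate per distinct unique kernel,
  anchored at its first recorded occurrence; no containment filtering.
  This reproduces the worked-example tally of 7 seats on the three demo
  genes with n=3, N=5.
* ``per-occurrence``: one candidate per occurrence of each unique kernel;
  passing candidates whose interval is wholly contained in another passing
  candidate's interval of the same gene are then dropped (maximality);
  identical intervals keep the first-generated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .sequence_io import GeneRecord
from .trie import Trie, UniqueEntry, build_trie, unique_leaves

EMIT_MODES = ("per-leaf", "per-occurrence")

__all__ = [
    "EMIT_MODES",
    "SeatParams",
    "Seat",
    "SeatCounts",
    "extend_candidate",
    "is_unique_nstring",
    "passing_candidates",
    "find_seats",
    "count_report",
]


@dataclass(frozen=True)
class SeatParams:
    """Search parameters: kernel length n < seat length N."""

    n: int
    N: int
    emit_mode: str = "per-leaf"
    min_output_length: int | None = None  # defaults to n (no filtering)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.n < self.N:
            raise ValueError(f"need n < N, got n={self.n}, N={self.N}")
        if self.emit_mode not in EMIT_MODES:
            raise ValueError(f"emit_mode must be one of {EMIT_MODES}")
        mol = self.min_output_length
        if mol is not None and not (self.n <= mol <= self.N):
            raise ValueError(
                f"min_output_length must lie in [{self.n}, {self.N}], got {mol}"
            )

    @property
    def effective_min_length(self) -> int:
        return self.n if self.min_output_length is None else self.min_output_length


class Seat(NamedTuple):
    """A unique N-string anchored in one gene (0-based start)."""

    gene_index: int
    start: int
    length: int
    sequence: str


class SeatCounts(NamedTuple):
    """Pipeline tally: trie leaves, unique kernels, candidates, seats."""

    leaf_count: int
    n_unique: int
    candidate_count: int
    seat_count: int


def extend_candidate(entry: UniqueEntry, gene: GeneRecord, N: int, at: int) -> str:
    """Extend a unique kernel rightward into an N-string candidate.

    Takes the N-n characters to the right of the kernel within the same
    gene; near the right boundary only the available characters are taken,
    so the result has length min(N, gene.length - at) >= n.
    """
    if at not in entry.all_positions:
        raise ValueError(
            f"{at} is not a recorded occurrence of kernel {entry.kernel!r}"
        )
    return gene.sequence[at:at + N]


def is_unique_nstring(candidate: str, unique_set: frozenset[str] | set[str], n: int) -> bool:
    """True iff every length-n window of the candidate is a unique kernel."""
    if len(candidate) < n:
        raise ValueError(f"candidate shorter than n={n}: {candidate!r}")
    return all(
        candidate[i:i + n] in unique_set for i in range(len(candidate) - n + 1)
    )


def _generate_candidates(
    entries: Sequence[UniqueEntry], genes: Sequence[GeneRecord], params: SeatParams
) -> list[Seat]:
    """All candidates for the chosen mode, in generation order."""
    cands: list[Seat] = []
    for entry in entries:
        gene = genes[entry.gene_index]
        positions = (
            (entry.anchor_position,)
            if params.emit_mode == "per-leaf"
            else entry.all_positions
        )
        for at in positions:
            seq = extend_candidate(entry, gene, params.N, at)
            cands.append(Seat(entry.gene_index, at, len(seq), seq))
    return cands


def _drop_contained(seats: list[Seat]) -> list[Seat]:
    """Maximality filter: drop seats wholly contained in another seat.

    Identical intervals keep the first-generated seat. Quadratic per gene;
    seat lists per gene are short in practice.
    """
    seen: set[tuple[int, int, int]] = set()
    deduped: list[Seat] = []
    for s in seats:
        key = (s.gene_index, s.start, s.length)
        if key not in seen:
            seen.add(key)
            deduped.append(s)
    kept = []
    for s in deduped:
        contained = any(
            o.gene_index == s.gene_index
            and o.start <= s.start
            and s.start + s.length <= o.start + o.length
            and (o.start, o.length) != (s.start, s.length)
            for o in deduped
        )
        if not contained:
            kept.append(s)
    return kept


def passing_candidates(
    genes: Sequence[GeneRecord], params: SeatParams, trie: Trie | None = None
) -> list[Seat]:
    """Candidates that pass the uniqueness test, before any maximality filter.

    In per-occurrence mode this is the full set of windows whose length-n
    subwindows are all unique — the quantity the brute-force oracle
    enumerates directly.
    """
    if trie is None:
        trie = build_trie(genes, params.n)
    entries = unique_leaves(trie)
    unique_set = frozenset(e.kernel for e in entries)
    return [
        s
        for s in _generate_candidates(entries, genes, params)
        if is_unique_nstring(s.sequence, unique_set, params.n)
    ]


def find_seats(
    genes: Sequence[GeneRecord],
    params: SeatParams,
    trie: Trie | None = None,
) -> list[Seat]:
    """Run the full seat search; returns seats ordered by gene then start.

    All seats of length >= n are returned; the ``min_output_length``
    threshold is applied only when writing the output table, so reported
    counts refer to the unfiltered result. A prebuilt trie over the same
    genes may be passed to skip the indexing step.
    """
    seats, _ = _find_seats_counted(genes, params, trie)
    return seats


def _find_seats_counted(
    genes: Sequence[GeneRecord],
    params: SeatParams,
    trie: Trie | None = None,
) -> tuple[list[Seat], SeatCounts]:
    if trie is None:
        trie = build_trie(genes, params.n)
    entries = unique_leaves(trie)
    unique_set = frozenset(e.kernel for e in entries)
    candidates = _generate_candidates(entries, genes, params)
    passing = [
        s for s in candidates if is_unique_nstring(s.sequence, unique_set, params.n)
    ]
    if params.emit_mode == "per-occurrence":
        passing = _drop_contained(passing)
    passing.sort(key=lambda s: (s.gene_index, s.start))
    counts = SeatCounts(
        leaf_count=trie.leaf_count,
        n_unique=len(entries),
        candidate_count=len(candidates),
        seat_count=len(passing),
    )
    return passing, counts


def count_report(
    genes: Sequence[GeneRecord], params: SeatParams, trie: Trie | None = None
) -> SeatCounts:
    """Summary counts for the pipeline (seat count before output filtering)."""
    _, counts = _find_seats_counted(genes, params, trie)
    return counts
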