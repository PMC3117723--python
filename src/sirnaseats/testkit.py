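"""Brute-force oracles and a seeded synthetic transcriptome generator.

The oracles realize the uniqueness definition directly with a flat
dictionary keyed by substring — they share no code or data structure with
the trie, so agreement between the two routes is evidence, not tautology.
The generator produces small random transcript collections with optional
planted motifs, giving guaranteed cross-gene duplicates to exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import ALPHABET, GeneRecord

__all__ = [
    "SynthSpec",
    "oracle_unique_nstrings",
    "oracle_seats",
    "synth_transcriptome",
    "random_small_spec",
    "cross_validate",
]


def _clean(seq: str, start: int, k: int) -> bool:
    return all(c in ALPHABET for c in seq[start:start + k])


def oracle_unique_nstrings(
    genes: Sequence[GeneRecord], n: int
) -> tuple[set[str], set[str]]:
    """Partition observed n-strings into unique (one gene) vs duplicate (>=2).

    Direct dictionary of string -> set of gene indices; windows touching a
    masked (non-ACGT) character are not observed, matching the indexing
    policy.
    """
    owners: dict[str, set[int]] = {}
    for gidx, gene in enumerate(genes):
        seq = gene.sequence
        for pos in range(gene.length - n + 1):
            if _clean(seq, pos, n):
                owners.setdefault(seq[pos:pos + n], set()).add(gidx)
    unique = {s for s, gs in owners.items() if len(gs) == 1}
    dup = {s for s, gs in owners.items() if len(gs) >= 2}
    return unique, dup


def oracle_seats(
    genes: Sequence[GeneRecord], n: int, N: int
) -> set[tuple[int, int, str]]:
    """Exhaustively enumerate every window of length N (boundary-truncated,
    minimum n) and keep those whose n-subwindows all belong to one gene.

    Returns (gene_index, 0-based start, sequence) triples. Independent of
    the trie code path.
    """
    if not n < N:
        raise ValueError(f"need n < N, got n={n}, N={N}")
    unique, _ = oracle_unique_nstrings(genes, n)
    out: set[tuple[int, int, str]] = set()
    for gidx, gene in enumerate(genes):
        seq = gene.sequence
        for start in range(gene.length - n + 1):
            window = seq[start:start + N]
            ok = all(
                window[i:i + n] in unique for i in range(len(window) - n + 1)
            )
            if ok:
                out.add((gidx, start, window))
    return out


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a random transcript collection.

    ``planted_motifs`` is a list of (motif, [(gene_index, position), ...]);
    motifs are written over the random fill after generation, so planted
    cross-gene duplicates are guaranteed present. Overlapping plants are
    resolved later-wins.
    """

    num_genes: int
    length_range: tuple[int, int] = (50, 200)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motifs: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_genes < 0:
            raise ValueError("num_genes must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")
        if not math.isclose(sum(self.base_composition), 1.0, abs_tol=1e-9):
            raise ValueError("base_composition must sum to 1")


def synth_transcriptome(spec: SynthSpec) -> list[GeneRecord]:
    """Generate a deterministic random gene collection from a spec."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    bases = np.array(list("ACGT"))
    seqs: list[list[str]] = []
    for _ in range(spec.num_genes):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(list(rng.choice(bases, size=length, p=spec.base_composition)))
    for motif, placements in spec.planted_motifs:
        for gidx, pos in placements:
            if gidx >= spec.num_genes or pos < 0 or pos + len(motif) > len(seqs[gidx]):
                raise ValueError(
                    f"motif {motif!r} does not fit in gene {gidx} at {pos}"
                )
            seqs[gidx][pos:pos + len(motif)] = list(motif)
    return [
        GeneRecord(f"SYN{i + 1:06d}", "", "".join(s)) for i, s in enumerate(seqs)
    ]


def random_small_spec(rng: np.random.Generator) -> tuple[SynthSpec, int, int]:
    """Draw a small random study case: a SynthSpec plus (n, N).

    Cases stay small (<= 20 genes of length <= 200, n in 2..6,
    N in n+1..n+10) so exhaustive oracles remain instant.
    """
    n = int(rng.integers(2, 7))
    N = n + int(rng.integers(1, 11))
    num_genes = int(rng.integers(2, 21))
    lo = max(n, int(rng.integers(n, 40)))
    hi = int(rng.integers(lo, 201))
    spec = SynthSpec(
        num_genes=num_genes,
        length_range=(lo, hi),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return spec, n, N


def cross_validate(num_cases: int = 100, seed: int = 0) -> dict[str, int]:
    """Trie-vs-oracle equivalence over seeded random cases.

    For each case, checks that the trie's unique/duplicate kernel sets and
    the per-occurrence passing candidates equal the brute-force oracles
    exactly. Raises ``AssertionError`` naming the first divergence; returns
    counters on success.
    """
    from .seats import SeatParams, passing_candidates
    from .trie import build_trie, unique_leaves

    rng = np.random.default_rng(seed)
    kernels_checked = 0
    seats_checked = 0
    for case in range(num_cases):
        spec, n, N = random_small_spec(rng)
        genes = synth_transcriptome(spec)
        trie = build_trie(genes, n)
        entries = unique_leaves(trie)
        trie_unique = {e.kernel for e in entries}
        trie_dup = {k for k, p in trie.iter_leaves() if p.duplicate}
        o_unique, o_dup = oracle_unique_nstrings(genes, n)
        if trie_unique != o_unique:
            diff = trie_unique.symmetric_difference(o_unique)
            raise AssertionError(
                f"case {case}: unique-set mismatch, first divergent "
                f"string {sorted(diff)[0]!r}"
            )
        if trie_dup != o_dup:
            diff = trie_dup.symmetric_difference(o_dup)
            raise AssertionError(
                f"case {case}: duplicate-set mismatch, first divergent "
                f"string {sorted(diff)[0]!r}"
            )
        cands = passing_candidates(
            genes, SeatParams(n=n, N=N, emit_mode="per-occurrence"), trie
        )
        cand_set = {(s.gene_index, s.start, s.sequence) for s in cands}
        o_seats = oracle_seats(genes, n, N)
        if cand_set != o_seats:
            diff = cand_set.symmetric_difference(o_seats)
            raise AssertionError(
                f"case {case}: seat-candidate mismatch, first divergent "
                f"entry {sorted(diff)[0]!r}"
            )
        kernels_checked += len(o_unique) + len(o_dup)
        seats_checked += len(o_seats)
    return {
        "cases": num_cases,
        "kernels_checked": kernels_checked,
        "seat_candidates_checked": seats_checked,
    }
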