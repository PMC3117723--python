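"""FASTA input, sequence normalization and tab-delimited seat output.

A transcript collection is an ordered list of :class:`GeneRecord`; the
position of a record in that list (``gene_index``) is the identity used by
the cross-gene uniqueness test, so file order is always preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

__all__ = [
    "ALPHABET",
    "GeneRecord",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "write_seats_table",
]


@dataclass(frozen=True)
class GeneRecord:
    """One input transcript: the unit "gene" for cross-gene uniqueness.

    ``masked`` holds 0-based positions whose character is outside {A,C,G,T}
    after normalization; any k-mer window overlapping a masked position is
    never indexed and can never appear in a seat.
    """

    gene_id: str
    description: str
    sequence: str
    masked: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        bad = {i for i, c in enumerate(self.sequence) if c not in ALPHABET}
        if bad != set(self.masked):
            raise ValueError(
                f"masked positions {sorted(self.masked)} do not match "
                f"non-ACGT positions {sorted(bad)} in {self.gene_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def window_is_clean(self, start: int, k: int) -> bool:
        """True if the k-mer at ``start`` overlaps no masked position."""
        if start < 0 or start + k > self.length:
            return False
        if not self.masked:
            return True
        return not any(p in self.masked for p in range(start, start + k))


def normalize_sequence(raw: str, policy: str = "mask") -> tuple[str, frozenset[int]]:
    """Uppercase, map U->T, and handle ambiguous characters.

    policy "mask" (default): non-ACGT characters are kept in place but their
    positions are returned as masked, excluding every overlapping k-mer.
    policy "reject": the first non-ACGT(U) character raises ``ValueError``
    naming its 1-based position.
    """
    if policy not in ("mask", "reject"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    seq = raw.upper().replace("U", "T")
    masked = frozenset(i for i, c in enumerate(seq) if c not in ALPHABET)
    if policy == "reject" and masked:
        pos = min(masked)
        raise ValueError(
            f"non-ACGTU character {seq[pos]!r} at position {pos + 1}"
        )
    return seq, masked


def read_fasta(path: str | os.PathLike, policy: str = "mask") -> list[GeneRecord]:
    """Read a multi-FASTA file into an ordered gene collection.

    File order is preserved (it defines ``gene_index``). The id is the first
    whitespace-delimited header token; the remainder becomes the description.
    Duplicate ids raise ``ValueError``; an empty file yields an empty list.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, masked = normalize_sequence(str(rec.seq), policy=policy)
        desc = rec.description[len(rec.id):].strip()
        records.append(GeneRecord(rec.id, desc, seq, masked))
    return records


def write_fasta(genes: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    """Write a gene collection back to multi-FASTA (round-trip safe)."""
    seqrecs = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description=g.description)
        for g in genes
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_seats_table(
    seats: Sequence,
    destination: str | os.PathLike,
    min_output_length: int,
    genes: Sequence[GeneRecord],
) -> int:
    """Write seats as TSV: gene_id, start, end, length, sequence.

    Coordinates are 1-based inclusive. Only seats with
    ``length >= min_output_length`` are written (the public siRNA-seat
    database applies a >=19 nt cut; here the threshold is caller-chosen).
    Returns the number of data rows written.
    """
    rows = sorted(
        (s for s in seats if s.length >= min_output_length),
        key=lambda s: (s.gene_index, s.start),
    )
    with open(destination, "w") as fh:
        fh.write("gene_id\tstart\tend\tlength\tsequence\n")
        for s in rows:
            fh.write(
                f"{genes[s.gene_index].gene_id}\t{s.start + 1}\t"
                f"{s.start + s.length}\t{s.length}\t{s.sequence}\n"
            )
    return len(rows)
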