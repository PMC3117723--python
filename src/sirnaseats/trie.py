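"""The modified n-truncated suffix tree (a depth-n 4-ary trie).

Every length-n substring ("kernel") of every gene is stored once, on a
root-to-leaf path of exactly n edges, with nodes allocated on demand. Each
leaf carries the ordered list of occurrences (gene index, 0-based offset)
and a cross-gene duplicate flag that is set the moment the kernel is seen
in a second distinct gene. The tree has no horizontal/side links and no
suffix links: insertion is per k-mer, left to right, gene by gene.

Memory accounting mirrors the storage model of the original C layout:
24 bytes per tree node, plus G(13*dL + 16) bytes for gene/occurrence
structures for G genes of mean length dL. These constants feed only the
:class:`TrieStats` estimate, never the Python object layout.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

from .sequence_io import ALPHABET, GeneRecord, normalize_sequence

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

TREE_NODE_BYTES = 24      # four child pointers + payload pointer + counter
GENE_STRUCT_BYTES = 16    # per-gene record in the storage model
STORAGE_BYTES_PER_CHAR = 13  # 12-byte occurrence structure + 1 sequence byte

INDEX_FORMAT = "sirnaseats-index"
INDEX_VERSION = 1

__all__ = [
    "Occurrence",
    "LeafPayload",
    "Trie",
    "TrieStats",
    "UniqueEntry",
    "build_trie",
    "add_gene",
    "unique_leaves",
    "full_tree_nodes",
    "trie_stats",
    "save_index",
    "load_index",
]


class Occurrence(NamedTuple):
    gene_index: int
    position: int


@dataclass
class LeafPayload:
    """Per-kernel record: ordered occurrences and the duplicate flag."""

    occurrences: list[Occurrence] = field(default_factory=list)
    duplicate: bool = False

    @property
    def occurrence_count(self) -> int:
        return len(self.occurrences)

    @property
    def owner(self) -> int:
        """Gene index of the first occurrence (the owning gene if unique)."""
        return self.occurrences[0].gene_index


class _Node:
    __slots__ = ("children",)

    def __init__(self) -> None:
        self.children: list = [None, None, None, None]


class UniqueEntry(NamedTuple):
    """One element of the unique-kernel list: a kernel seen in one gene only."""

    kernel: str
    gene_index: int
    anchor_position: int
    all_positions: tuple[int, ...]


class Trie:
    """Depth-n trie over {A,C,G,T} with occurrence-bearing leaves."""

    def __init__(self, n: int) -> None:
        if n < 1:
            raise ValueError(f"kernel length n must be >= 1, got {n}")
        self.n = n
        self.root = _Node()
        self.node_count = 1  # includes the root
        self.leaf_count = 0
        self.gene_ids: list[str] = []

    @property
    def num_genes_indexed(self) -> int:
        return len(self.gene_ids)

    def insert(self, s: str, occ: Occurrence) -> LeafPayload:
        """Insert one kernel occurrence, creating nodes only as needed.

        Appends ``occ`` to the leaf's occurrence list and sets the duplicate
        flag if the kernel was already present from a different gene.
        """
        if len(s) != self.n:
            raise ValueError(f"expected a string of length {self.n}, got {len(s)}")
        node = self.root
        for depth, base in enumerate(s):
            try:
                i = _BASE_INDEX[base]
            except KeyError:
                raise ValueError(f"character {base!r} outside ACGT in {s!r}") from None
            child = node.children[i]
            if child is None:
                if depth == self.n - 1:
                    child = LeafPayload()
                    self.leaf_count += 1
                else:
                    child = _Node()
                self.node_count += 1
                node.children[i] = child
            node = child
        leaf: LeafPayload = node  # depth n reached
        if leaf.occurrences and leaf.occurrences[0].gene_index != occ.gene_index:
            leaf.duplicate = True
        leaf.occurrences.append(occ)
        return leaf

    def iter_leaves(self) -> Iterator[tuple[str, LeafPayload]]:
        """Yield (kernel, payload) in lexicographic kernel order."""
        stack: list[tuple[object, str]] = [(self.root, "")]
        while stack:
            node, prefix = stack.pop()
            if isinstance(node, LeafPayload):
                yield prefix, node
                continue
            for i in range(3, -1, -1):
                child = node.children[i]
                if child is not None:
                    stack.append((child, prefix + _BASES[i]))

    def lookup(self, s: str) -> LeafPayload | None:
        if len(s) != self.n:
            return None
        node = self.root
        for base in s:
            i = _BASE_INDEX.get(base)
            if i is None:
                return None
            node = node.children[i]
            if node is None:
                return None
        return node


# alias matching the operation-level name
def insert_nstring(trie: Trie, s: str, occ: Occurrence) -> Trie:
    trie.insert(s, occ)
    return trie


def add_gene(trie: Trie, gene: GeneRecord) -> Trie:
    """Index one more gene incrementally; no rebuild is needed.

    The resulting trie is observationally identical (same leaves,
    occurrence lists, duplicate flags) to a fresh build over the extended
    collection. Genes shorter than n contribute nothing (warned).
    """
    if gene.gene_id in trie.gene_ids:
        raise ValueError(f"gene id {gene.gene_id!r} already indexed")
    gidx = trie.num_genes_indexed
    trie.gene_ids.append(gene.gene_id)
    n = trie.n
    if gene.length < n:
        logger.warning(
            "gene %s (length %d) is shorter than n=%d; no kernels indexed",
            gene.gene_id, gene.length, n,
        )
        return trie
    seq = gene.sequence
    for pos in range(gene.length - n + 1):
        if gene.window_is_clean(pos, n):
            trie.insert(seq[pos:pos + n], Occurrence(gidx, pos))
    return trie


def build_trie(genes: Sequence[GeneRecord], n: int) -> Trie:
    """Index every unmasked kernel of every gene, left to right, in order."""
    trie = Trie(n)
    for gene in genes:
        add_gene(trie, gene)
    return trie


def unique_leaves(trie: Trie) -> list[UniqueEntry]:
    """The unique-kernel list: leaves whose occurrences are all in one gene.

    Ordered by (owning gene index, first occurrence position); the list's
    length is the number of unique kernels in the collection.
    """
    entries = [
        UniqueEntry(
            kernel,
            payload.owner,
            payload.occurrences[0].position,
            tuple(o.position for o in payload.occurrences),
        )
        for kernel, payload in trie.iter_leaves()
        if not payload.duplicate
    ]
    entries.sort(key=lambda e: (e.gene_index, e.anchor_position))
    return entries


def full_tree_nodes(n: int) -> int:
    """Vertex count of the complete 4-ary tree with levels 0..n: (4^(n+1)-1)/3.

    Level k holds 4^k vertices; the sum over levels 0..n (root included)
    bounds the node count of any depth-n trie.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (4 ** (n + 1) - 1) // 3


@dataclass(frozen=True)
class TrieStats:
    """Tree fill-in and storage-model memory estimate."""

    n: int
    nodes_used: int
    full_tree_nodes: int
    fill_fraction: float
    estimated_tree_bytes: int
    estimated_total_bytes: int
    num_genes: int
    avg_gene_length: float


def trie_stats(trie: Trie, genes: Sequence[GeneRecord]) -> TrieStats:
    """Report fill-in vs the full tree and the byte estimate.

    The byte figures are estimates under the 24-byte-node / G(13*dL+16)
    storage model, not measurements of the running process.
    """
    full = full_tree_nodes(trie.n)
    g = len(genes)
    avg_len = sum(rec.length for rec in genes) / g if g else 0.0
    tree_bytes = TREE_NODE_BYTES * trie.node_count
    struct_bytes = int(g * (STORAGE_BYTES_PER_CHAR * avg_len + GENE_STRUCT_BYTES))
    return TrieStats(
        n=trie.n,
        nodes_used=trie.node_count,
        full_tree_nodes=full,
        fill_fraction=trie.node_count / full,
        estimated_tree_bytes=tree_bytes,
        estimated_total_bytes=tree_bytes + struct_bytes,
        num_genes=g,
        avg_gene_length=avg_len,
    )


def save_index(trie: Trie, genes: Sequence[GeneRecord], path: str | os.PathLike) -> None:
    """Persist trie + genes as versioned JSON.

    Internal format, not an interchange format: the layout may change
    between versions and is only guaranteed to round-trip through
    :func:`load_index` of the same package version.
    """
    doc = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "n": trie.n,
        "genes": [
            {"id": g.gene_id, "description": g.description, "sequence": g.sequence}
            for g in genes
        ],
        "leaves": {
            kernel: [[o.gene_index, o.position] for o in payload.occurrences]
            for kernel, payload in trie.iter_leaves()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_index(path: str | os.PathLike) -> tuple[Trie, list[GeneRecord]]:
    """Load a saved index, replaying insertions to rebuild the tree."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != INDEX_FORMAT:
        raise ValueError(f"{path} is not a {INDEX_FORMAT} file")
    if doc.get("version") != INDEX_VERSION:
        raise ValueError(f"unsupported index version {doc.get('version')}")
    genes = []
    for g in doc["genes"]:
        seq, masked = normalize_sequence(g["sequence"])
        genes.append(GeneRecord(g["id"], g["description"], seq, masked))
    trie = Trie(doc["n"])
    trie.gene_ids = [g.gene_id for g in genes]
    for kernel, occs in doc["leaves"].items():
        for gene_index, position in occs:
            trie.insert(kernel, Occurrence(gene_index, position))
    return trie, genes
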