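"""Property-based checks of the trie and seat pipeline against the
brute-force oracles, plus the structural invariants the data structure
must satisfy on any input."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirnaseats import (
    GeneRecord,
    SeatParams,
    add_gene,
    build_trie,
    find_seats,
    full_tree_nodes,
    oracle_seats,
    oracle_unique_nstrings,
    passing_candidates,
    unique_leaves,
)

SETTINGS = settings(max_examples=60, derandomize=True, deadline=None)


def gene_collections(min_genes=0, max_genes=6, max_len=40):
    seqs = st.text(alphabet="ACGT", min_size=0, max_size=max_len)
    return st.lists(seqs, min_size=min_genes, max_size=max_genes).map(
        lambda xs: [GeneRecord(f"g{i}", "", s) for i, s in enumerate(xs)]
    )


@SETTINGS
@given(genes=gene_collections(), n=st.integers(2, 5))
def test_trie_matches_oracle_partition(genes, n):
    trie = build_trie(genes, n)
    trie_unique = {e.kernel for e in unique_leaves(trie)}
    trie_dup = {k for k, p in trie.iter_leaves() if p.duplicate}
    o_unique, o_dup = oracle_unique_nstrings(genes, n)
    assert trie_unique == o_unique
    assert trie_dup == o_dup


@SETTINGS
@given(genes=gene_collections(), n=st.integers(2, 5))
def test_node_bound_and_occurrence_conservation(genes, n):
    trie = build_trie(genes, n)
    assert trie.node_count <= full_tree_nodes(n)
    total_occ = sum(p.occurrence_count for _, p in trie.iter_leaves())
    assert total_occ == sum(max(0, g.length - n + 1) for g in genes)


@SETTINGS
@given(
    genes=gene_collections(min_genes=2, max_genes=5),
    n=st.integers(2, 4),
    perm_seed=st.integers(0, 1000),
)
def test_gene_order_invariance(genes, n, perm_seed):
    """Permuting input order relabels gene indices but changes neither the
    leaf-string set, nor per-string occurrence multisets (up to the
    relabeling), nor the duplicate flags."""
    perm = np.random.default_rng(perm_seed).permutation(len(genes))
    shuffled = [genes[i] for i in perm]

    def observable(trie, gene_list):
        out = {}
        for kernel, payload in trie.iter_leaves():
            occs = sorted(
                (gene_list[o.gene_index].gene_id, o.position)
                for o in payload.occurrences
            )
            out[kernel] = (tuple(occs), payload.duplicate)
        return out

    assert observable(build_trie(genes, n), genes) == observable(
        build_trie(shuffled, n), shuffled
    )


@SETTINGS
@given(genes=gene_collections(min_genes=1), n=st.integers(2, 4))
def test_incremental_build_equals_fresh_build(genes, n):
    fresh = build_trie(genes, n)
    grown = build_trie(genes[:-1], n)
    add_gene(grown, genes[-1])
    assert dict(grown.iter_leaves()).keys() == dict(fresh.iter_leaves()).keys()
    for k, p in fresh.iter_leaves():
        q = grown.lookup(k)
        assert q.occurrences == p.occurrences
        assert q.duplicate == p.duplicate


@SETTINGS
@given(genes=gene_collections(min_genes=1), n=st.integers(2, 4))
def test_adding_genes_never_restores_uniqueness(genes, n):
    trie = build_trie(genes, n)
    dup_before = {k for k, p in trie.iter_leaves() if p.duplicate}
    unique_before = {e.kernel for e in unique_leaves(trie)}
    add_gene(trie, GeneRecord("extra", "", genes[0].sequence))
    dup_after = {k for k, p in trie.iter_leaves() if p.duplicate}
    unique_after = {e.kernel for e in unique_leaves(trie)}
    assert dup_before <= dup_after
    assert unique_after <= unique_before


@SETTINGS
@given(
    genes=gene_collections(min_genes=1, max_genes=5, max_len=30),
    n=st.integers(2, 4),
    extra=st.integers(1, 6),
    mode=st.sampled_from(["per-leaf", "per-occurrence"]),
)
def test_emitted_seats_are_sound_and_well_formed(genes, n, extra, mode):
    """Every emitted seat is confirmed by brute force: none of its length-n
    windows occurs in any other gene; lengths lie in [n, N] with short
    seats only at the right gene boundary."""
    N = n + extra
    seats = find_seats(genes, SeatParams(n=n, N=N, emit_mode=mode))
    for s in seats:
        gene = genes[s.gene_index]
        assert gene.sequence[s.start:s.start + s.length] == s.sequence
        assert n <= s.length <= N
        if s.length < N:
            assert s.start + s.length == gene.length
        for i in range(s.length - n + 1):
            window = s.sequence[i:i + n]
            for gidx, other in enumerate(genes):
                if gidx != s.gene_index:
                    assert window not in other.sequence


@SETTINGS
@given(
    genes=gene_collections(min_genes=1, max_genes=5, max_len=30),
    n=st.integers(2, 4),
    extra=st.integers(1, 6),
)
def test_per_occurrence_candidates_complete_vs_oracle(genes, n, extra):
    N = n + extra
    cands = passing_candidates(
        genes, SeatParams(n=n, N=N, emit_mode="per-occurrence")
    )
    assert {(s.gene_index, s.start, s.sequence) for s in cands} == oracle_seats(
        genes, n, N
    )


@SETTINGS
@given(
    genes=gene_collections(min_genes=1, max_genes=5, max_len=30),
    n=st.integers(2, 4),
    extra=st.integers(1, 4),
)
def test_per_leaf_seats_subset_of_per_occurrence_candidates(genes, n, extra):
    N = n + extra
    pl = find_seats(genes, SeatParams(n=n, N=N, emit_mode="per-leaf"))
    po = passing_candidates(
        genes, SeatParams(n=n, N=N, emit_mode="per-occurrence")
    )
    assert {(s.gene_index, s.sequence) for s in pl} <= {
        (s.gene_index, s.sequence) for s in po
    }


@SETTINGS
@given(genes=gene_collections(max_genes=4, max_len=25), n=st.integers(2, 4))
def test_masking_excludes_only_overlapping_windows(genes, n):
    """Replacing one base with N removes exactly the windows that overlap
    it; uniqueness of unaffected kernels elsewhere cannot be created."""
    if not genes or genes[0].length == 0:
        return
    g0 = genes[0]
    pos = g0.length // 2
    masked_seq = g0.sequence[:pos] + "N" + g0.sequence[pos + 1:]
    masked_gene = GeneRecord(g0.gene_id, "", masked_seq, frozenset({pos}))
    trie = build_trie([masked_gene] + genes[1:], n)
    expected = sum(
        1
        for g_i, g in enumerate([masked_gene] + genes[1:])
        for p in range(max(0, g.length - n + 1))
        if g.window_is_clean(p, n)
    )
    assert sum(p.occurrence_count for _, p in trie.iter_leaves()) == expected
    o_unique, o_dup = oracle_unique_nstrings([masked_gene] + genes[1:], n)
    assert {e.kernel for e in unique_leaves(trie)} == o_unique
    assert {k for k, p in trie.iter_leaves() if p.duplicate} == o_dup
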