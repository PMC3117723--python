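"""Tree fill-in and the storage-model memory estimate.

Indexes a synthetic collection at several kernel lengths and prints, per n,
how many of the complete 4-ary tree's (4^(n+1)-1)/3 vertices are actually
allocated, with the 24-bytes-per-node + G(13*dL+16) byte estimate. As n
grows, the fraction of the full tree in use drops sharply: on-demand
allocation is what keeps long kernels affordable.
"""

from sirnaseats import SynthSpec, build_trie, synth_transcriptome, trie_stats

genes = synth_transcriptome(SynthSpec(num_genes=50, length_range=(500, 1500), seed=7))

print("n\tnodes_used\tfull_tree\t%used\ttree_bytes\ttotal_bytes")
for n in (5, 7, 9, 11):
    st = trie_stats(build_trie(genes, n), genes)
    print(f"{st.n}\t{st.nodes_used}\t{st.full_tree_nodes}\t"
          f"{100 * st.fill_fraction:.3f}\t{st.estimated_tree_bytes}\t"
          f"{st.estimated_total_bytes}")
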