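"""Seat screening on a synthetic transcriptome with a planted shared motif.

Generates 10 random transcripts, plants one 13-mer into three of them
(guaranteeing cross-gene duplicates), extracts seats with realistic
parameters (n=13, N=21), and confirms no seat overlaps the planted motif.
"""

from sirnaseats import SeatParams, SynthSpec, find_seats, synth_transcriptome

MOTIF = "ACGTGACTGGTCA"  # 13-mer shared by genes 0, 3 and 7
spec = SynthSpec(
    num_genes=10,
    length_range=(300, 600),
    planted_motifs=[(MOTIF, [(0, 50), (3, 120), (7, 10)])],
    seed=42,
)
genes = synth_transcriptome(spec)
seats = find_seats(genes, SeatParams(n=13, N=21, emit_mode="per-leaf"))

print(f"{len(genes)} genes, {len(seats)} seats (n=13, N=21)")
for s in seats[:5]:
    print(f"{genes[s.gene_index].gene_id}\t{s.start + 1}\t{s.sequence}")

overlapping = [
    s for s in seats
    for m_gene, m_pos in [(0, 50), (3, 120), (7, 10)]
    if s.gene_index == m_gene
    and s.start < m_pos + len(MOTIF) - 12 and m_pos < s.start + s.length - 12
]
print(f"seats whose 13-mers reach into the planted motif: {len(overlapping)}")
# Expect 0: every 13-mer inside the shared motif occurs in three genes, so
# no seat may contain one.
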