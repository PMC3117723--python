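"""Seat extraction on the three-gene demonstration collection.

With kernel length n=3 the index holds 13 distinct 3-mers, of which 11
occur in only one gene; extending each unique 3-mer rightward to a
5-string and re-testing uniqueness leaves 7 siRNA seats.
"""

from sirnaseats import GeneRecord, SeatParams, count_report, find_seats

genes = [
    GeneRecord("G1", "", "AGAGAGGC"),
    GeneRecord("G2", "", "TCAATCCC"),
    GeneRecord("G3", "", "AATAAATC"),
]

params = SeatParams(n=3, N=5, emit_mode="per-leaf")
counts = count_report(genes, params)
print(f"leaves={counts.leaf_count} unique_kernels={counts.n_unique} "
      f"candidates={counts.candidate_count} seats={counts.seat_count}")

for seat in find_seats(genes, params):
    gid = genes[seat.gene_index].gene_id
    print(f"{gid}\t{seat.start + 1}-{seat.start + seat.length}\t{seat.sequence}")

# Each printed row is a window in one gene none of whose 3-mers occurs in
# any other gene: an siRNA placed there cannot match another gene over
# 3 or more consecutive bases of the kernel scale.
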