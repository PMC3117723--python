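# sirnaseats

Find **siRNA seats**: substrings of length *N* within one transcript whose
every length-*n* substring occurs in no other transcript of the collection.
An siRNA placed inside a seat cannot pair with any other gene over *n* or
more consecutive nucleotides, which minimizes off-target silencing at the
design stage — before any efficacy scoring is applied. The same machinery
answers the broader question "which short strings are specific to exactly
one gene?", useful for microarray probes, molecular beacons and PCR primers.

## Method

Let *G* be a set of genes (strings over {A,C,G,T}) and fix two integers
*n* < *N*. Two *N*-strings from different genes are **duplicates** if they
share any common substring of length *n*; an *N*-string that duplicates no
string from another gene is **unique** and forms a seat. The pipeline:

1. **Index.** Every length-*n* substring ("kernel") of every gene is stored
   in a depth-*n* 4-ary trie (a modified *n*-truncated suffix tree): one
   root-to-leaf path of *n* edges per distinct kernel, nodes allocated on
   demand. Each leaf keeps the ordered occurrence list (gene, offset) and a
   flag that is set the moment the kernel appears in a second gene.
2. **UNIQUE_n.** Leaves whose occurrences all lie in one gene are the unique
   kernels.
3. **Extend and test.** Each unique kernel is extended rightward by the
   *N − n* characters available in its gene (truncated at the gene boundary,
   so a seat is never shorter than *n*). A candidate is a seat iff all of
   its length-*n* windows are unique kernels.

The complete tree over levels 0..*n* has (4^(n+1) − 1)/3 vertices; on-demand
allocation uses only the paths actually present, which is what makes
kernel lengths of 13–16 practical on a transcriptome. New genes can be
added to a built index incrementally with results identical to a fresh
rebuild.

## Worked example

```python
from sirnaseats import GeneRecord, SeatParams, count_report, find_seats

genes = [GeneRecord("G1", "", "AGAGAGGC"),
         GeneRecord("G2", "", "TCAATCCC"),
         GeneRecord("G3", "", "AATAAATC")]
params = SeatParams(n=3, N=5, emit_mode="per-leaf")
print(count_report(genes, params))
for s in find_seats(genes, params):
    print(genes[s.gene_index].gene_id, s.start + 1, s.sequence)
```

prints

```
SeatCounts(leaf_count=13, n_unique=11, candidate_count=11, seat_count=7)
G1 1 AGAGA
G1 2 GAGAG
G1 5 AGGC
G1 6 GGC
G2 5 TCCC
G2 6 CCC
G3 2 ATAAA
```

The three genes contain 13 distinct 3-mers; 11 of them occur in a single
gene (AAT and ATC are shared between G2 and G3). Extending each unique
3-mer to a 5-string and re-testing leaves 7 seats — e.g. TCAAT fails
because its window AAT also occurs in G3, while seats at the right gene
boundary (GGC, CCC) are kept at their truncated length.

More narrative scripts live in `examples/` (synthetic transcriptome
screening, incremental index updates, memory footprint). A thin CLI wraps
the same library calls:

```sh
sirnaseats seats --in genes.fasta --out seats.tsv --n 13 --N 21 --min-len 19
sirnaseats stats --in genes.fasta --n-range 9:16 --out stats.tsv
sirnaseats add   --index saved.idx --in new.fasta
sirnaseats synth --spec spec.yaml --out fixture.fasta
sirnaseats verify --seed 5
```

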