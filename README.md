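# idxblast

Database-indexed protein BLAST. Instead of indexing the query (as
classical BLASTP does), `idxblast` builds a compressed inverted index
over the **database**: the database is length-sorted, partitioned into
letter-capped blocks sized for CPU caches, and each block gets a lookup
table over all 20³ amino-acid words pointing into a sorted,
delta-compressed position stream. Neighbor words (words scoring ≥ T
against a query word under the substitution matrix) are not materialized
as positions — the lookup table carries per-word neighbor lists, and the
search walks those posting lists at query time, giving the same visited
positions at a fraction of the index size.

Search proceeds per block: word hits are binned first by diagonal
(subject offset − query offset), then re-binned per subject sequence
while a two-hit filter keeps only hits within `[overlap, threshold_A)`
of the previous hit on the same diagonal. Surviving seed pairs undergo
X-drop ungapped extension; HSPs above the gap trigger undergo two-sided
X-drop gapped extension with affine gaps and full traceback.
Significance uses Karlin–Altschul statistics, `E = K·m′·n′·e^{−λS}`,
with the published NCBI constants and the classical length adjustment
(composition-based adjustment is intentionally out of scope, so E-values
are standard-KA rather than digit-identical to NCBI defaults).

The package is aimed at people studying BLAST-style search algorithms
and index data structures: every stage (indexing, compression, binning,
extension) is exposed as a library function with a brute-force reference
implementation alongside it.

## Worked example

```python
import idxblast as ib
from idxblast.orchestrator import format_tabular
from idxblast.search_core import SearchParams
from idxblast.synth import SyntheticSpec, generate_database

seqs, truth = generate_database(SyntheticSpec(n_sequences=200, n_planted=10, seed=1))
db = ib.sort_database(seqs)
index = ib.build_database_index(ib.partition_blocks(db, 8192), block_cap=8192)
query = next(s for s in seqs if s.accession == truth.donor[0])
print(format_tabular(ib.run_batch([query], db, index, SearchParams())))
```

prints (12-column tabular: query, subject, %identity, length, mismatches,
gap opens, q.start, q.end, s.start, s.end, E-value, bit score):

```
syn00106  syn00106  100.000  154  0   0  1   154  1   154  4.15e-91  321.6
syn00106  syn00003  61.404   57   20  1  14  70   21  75   7.00e-14  65.1
syn00106  syn00088  34.426   61   38  2  51  109  227 287  0.179     23.9
...
```

The first line is the query's own database copy (a full-length self hit);
the second is the planted homolog `syn00003`, recovered at the planted
~61 % identity with one gap. The remaining lines are chance similarities
with E-values approaching the cutoff. The `examples/` directory has one
short script per capability (index construction, compression internals,
two-hit binning, search, statistics).

A command-line interface wraps the same stages:

```sh
idxblast gendb -o db.fa -n 500          # synthetic database + truth table
idxblast formatdb -i db.fa
idxblast sortdb -i db.fa.fdb -o db.sdb
idxblast indexdb -i db.sdb -s 128       # block size in K letters
idxblast search -i query.fa -d db.sdb --outfmt tabular
```

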