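"""Search a query against an indexed database and print the report.

The query is the donor sequence of a planted homolog pair, so the hit
list contains the query's own database copy (self hit, ~100% identity)
and the planted receiver at roughly the planted identity.
"""

import idxblast as ib
from idxblast.orchestrator import format_tabular
from idxblast.search_core import SearchParams
from idxblast.synth import SyntheticSpec, generate_database

seqs, truth = generate_database(SyntheticSpec(n_sequences=200, n_planted=10, seed=1))
db = ib.sort_database(seqs)
index = ib.build_database_index(ib.partition_blocks(db, 8192), block_cap=8192)

query = next(s for s in seqs if s.accession == truth.donor[0])
result = ib.run_batch([query], db, index, SearchParams())
print(format_tabular(result))
print(f"# planted receiver: {truth.receiver[0]} "
      f"(segment identity {truth.achieved_identity[0]:.1f}%)")
# Columns: query, subject, %identity, length, mismatches, gap opens,
# q.start, q.end, s.start, s.end, E-value, bit score (1-based inclusive).
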