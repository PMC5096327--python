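"""Karlin-Altschul statistics: raw score -> bit score -> E-value.

Shows how an alignment score is converted with the published BLOSUM62
gapped constants (gap open 11, extend 1): lambda = 0.267, K = 0.041.
"""

from idxblast import stats

kp = stats.karlin_params("BLOSUM62", 11, 1)
query_len, db_letters, db_seqs = 250, 10**6, 2000
print(f"lambda={kp.lam}  K={kp.K}  H={kp.H}")
print(f"length adjustment: {stats.length_adjustment(kp, query_len, db_letters, db_seqs)}"
      " residues trimmed from each sequence end-effect")
print(f"{'raw':>5} {'bits':>7} {'E-value':>10}")
for raw in (30, 50, 80, 120):
    print(f"{raw:>5} {stats.bit_score(raw, kp):>7.1f} "
          f"{stats.evalue(raw, query_len, db_letters, db_seqs, kp):>10.2e}")
# A raw score of ~50 is marginal (E near 1) in a 1M-letter database;
# scores above ~80 are essentially certain homologs.
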