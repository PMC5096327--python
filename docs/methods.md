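# Methods

## Database model and index

A protein database is a list of sequences over the 20 canonical amino
acids; ambiguity letters (X, B, Z, U, J, O, `*`) and any unrecognized
character map to a single mask code. Masked residues score like `X`
under the substitution matrix but never participate in an indexed word,
so no seed can start inside a masked region (standard seeding
behaviour). Only the 20 canonical residues are word-indexable; the
lookup table therefore has a^W = 20³ = 8000 entries at the default word
length W = 3.

**Sorting and blocking.** The database is sorted by length (ascending,
stable — reproducible builds; early blocks are small and uniform) and
partitioned greedily into blocks capped at `block_cap` letters (default
131 072 = 128 K). A sequence that would overflow the cap starts the
next block; a single sequence longer than the cap occupies its own
block; no sequence ever spans two blocks. Blocking bounds the per-block
sequence-id width at ⌈log₂ n_block⌉ bits and, because of the length
sort, lets short blocks use narrow subject offsets. Results are mapped
back to input accessions through the recorded sorted↔original bijection.

**Compressed position stream.** Per block, every fully indexable W-mer
contributes one (sequence id, subject offset) position. Positions are
sorted per word by (offset, id) and compressed: positions sharing an
offset merge into one entry holding the offset once plus all ids;
offsets are stored as 8-bit increments over the previous entry's
absolute offset, with the first entry's increment measured from 0 (a
0-base makes per-word decoding stateless). Increments over 255 are
absorbed by padding entries `(255, 0, [])`; counts over 255 are emitted
as maximal 255-id entries followed by the remainder. Decoding is exact;
losslessness is fuzz-tested.

**Neighbor indirection.** Word w′ is a neighbor of w when
Σᵢ M[wᵢ, w′ᵢ] ≥ T (default T = 11 with BLOSUM62, the protein-search
convention; neighbor lists exclude the word itself, and the exact word
is always visited through its own posting list regardless of its
self-score). Neighbor lists are a function of (matrix, T, W) only, so
one table is shared by all blocks and stored once per index file.

## Search

**Hit detection.** For each query position the engine walks the exact
word's posting list and then each neighbor's, appending hits into
first-level bins keyed by diagonal id (subject offset − query offset;
dense array addressing via diagonal + query_len − 1). Because posting
lists are offset-sorted, hits within one (sequence, diagonal) arrive in
ascending subject offset.

**Two-level binning and the two-hit filter.** First-level bins are
scanned in ascending diagonal order; hits are re-binned per subject
sequence (the last-hit state is an array over block-local sequence ids,
each record storing the anchor offset *and its diagonal*, which avoids
any reset between diagonals and keeps the array cache-sized). A hit on
the record's diagonal at distance d from the anchor triggers when
`overlap ≤ d < threshold_A` (defaults: overlap = W = 3,
threshold_A = 40). Any hit with d ≥ overlap — triggering or not — and
any hit on a new diagonal becomes the new anchor; a hit overlapping the
anchor (d < overlap) leaves it in place. The update policy matters:
were the anchor displaced by every hit, runs of adjacent hits (the
identity diagonal of near-duplicate sequences) would space the anchors
one residue apart and never trigger. With this policy the emitted pair
set is provably identical to the classical query-indexed per-diagonal
last-hit scan, which the suite checks exhaustively; the filtered,
triggering hit (offset + diagonal) is what enters the second-level bin.

**Ungapped extension.** Each trigger seeds an X-drop extension along
its diagonal: left then right from the triggering word (whose score is
always included), stopping when the running score falls more than X₁
below its maximum (X₁ = 7 bits converted through the ungapped λ). A
trigger whose word lies inside the subject span of the previous
extension on the same diagonal is skipped; this decision depends only on
same-diagonal history, so the indexed and the query-indexed pipelines
make identical skips. HSPs scoring below the cutoff (default: the gap
trigger) are dropped; surviving HSPs are deduplicated by containment in
canonical (score-descending) order.

**Gapped extension.** An HSP scoring ≥ the gap trigger (default 22 raw)
is extended with affine gaps (open 11, extend 1; a gap of k costs
11 + k) from a seed pair: the first HSP column where the cumulative
segment score reaches half the total. Two independent X-drop DPs run
outward from the seed (X₂ = 15 bits through the gapped λ). The DP masks
cells falling more than X₂ below the running best at row granularity and
tracks the provably-alive column band, so junk extensions stay narrow;
with X₂ = ∞ the DP is the exact optimal local extension through the
seed, and the reported score equals the Smith–Waterman optimum whenever
the optimal alignment passes through the seed pair (otherwise it is a
lower bound — both facts are asserted in the suite). Ties prefer the
earliest cell in row-major order, diagonal moves over gaps, and gap
continuation over opening, making tracebacks deterministic. An HSP
contained in an already-extended alignment of the same sequence is
skipped.

**Statistics and ranking.** Raw scores convert to bit scores
(λS − ln K)/ln 2 and E-values K·m′·n′·e^{−λS} using the published
constants for the (matrix, gap) combination; unsupported combinations
are rejected. m′, n′ come from the classical iterative length
adjustment over the whole database (block searches are always scored
against whole-database letter/sequence counts, which is one of the two
ingredients of block invariance; the other is that no per-sequence
state crosses a block boundary). Alignments with E > 10 are dropped;
reports are ranked by (E-value, −score, accession, coordinates) and
truncated to 500 per query.

**Batch schedule.** The outer loop walks blocks; the inner,
parallelizable loop runs hit detection + ungapped extension for all
queries of the batch against the current block, so concurrent workers
share one block's decoded index. Gapped extension with traceback runs
after the per-block partials are merged. Partials are keyed by (block,
query) and merged in canonical order, making the report independent of
worker count and scheduling; a subject surfacing from two blocks would
violate the partition and raises an integrity error.

## Synthetic data

The generator emulates: Robinson–Robinson background composition,
log-normal lengths (median 250, σ = 0.55, clipped to 60–1000), and
local homology planted by copying a donor segment (50–200 residues)
into a receiver after substituting an exact count of positions to reach
the requested identity (default 60 %, achieved within ±2 % by
construction) and applying indel events (default rate 0.02/position,
lengths 1–3). It does not emulate domain architecture, repeats,
low-complexity sequence, or realistic substitution spectra (mutations
are uniform over the 19 alternatives) — so passing tests demonstrate
algorithmic correctness and BLAST-equivalence on detectable local
homology, not retrieval performance on real proteomes (real databases
also stress low-complexity filtering, which is deliberately not
implemented).

## Numerical and design choices

- Offsets are 0-based half-open internally; reports print 1-based
  inclusive coordinates.
- All index integers are little-endian fixed-width; index and database
  files carry magic + version and fail loudly on mismatch or truncation.
- The overflow split is canonical (padding entries first, maximal count
  entries first), so byte-identical rebuilds are guaranteed for
  identical inputs.
- The gapped DP exists twice: a numba-compiled scalar kernel and a pure
  numpy band implementation with identical recurrences and tie rules,
  cross-checked for exact equality in the suite; the numpy path is the
  fallback when numba is absent. Likewise the two-hit filter.
- Problem sizes in the suite (databases of 10–2000 sequences, 50-trial
  fuzz loops) were chosen so the full suite completes in about two
  minutes while still exercising multi-block indexes, overflow splits
  and all invariants at system level.

## Known limitations

- Composition-based score adjustment and SEG low-complexity filtering
  are not implemented; E-values are standard Karlin–Altschul.
- The Karlin–Altschul table covers BLOSUM62 fully and BLOSUM45/80
  partially; other matrices require user-supplied constants.
- Indexes are memory-resident; databases larger than memory and
  incremental index updates are out of scope, as are nucleotide search
  and PSI-BLAST iteration.
- Parallel workers use threads; the numpy/numba kernels release the GIL
  only partially, so speedups are modest — the contract is determinism,
  not linear scaling.
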