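"""Batch search across index blocks, result merging, report formatting.

The batch schedule is block-major: the outer loop walks index blocks one
by one and the inner, parallelizable loop runs hit detection and
ungapped extension for every query against that block, so concurrent
workers share one block's index.  Gapped extension with traceback runs
after the per-block partials are merged.  Partial results are keyed by
(block, query) and merged in canonical order, so the final report is
independent of the worker count and of the block partitioning.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .db_prep import DatabaseBlock, ProteinSequence, SortedDatabase, partition_blocks
from .errors import IntegrityError, InputError
from .indexer import DatabaseIndex, build_neighbor_table, decode_block
from .search_core import (
    GappedAlignment,
    SearchParams,
    compute_block_hsps,
    gapped_stage,
    make_query_plan,
    rank_alignments,
)

logger = logging.getLogger(__name__)


@dataclass
class BatchResult:
    queries: list  # ProteinSequence
    alignments: list  # list per query, ranked and truncated
    params: SearchParams
    db_letters: int
    db_seqs: int
    metadata: dict = field(default_factory=dict)


def merge_results(partials: dict, params: SearchParams) -> list:
    """Merge per-block alignment lists for one query into the final ranking.

    ``partials`` maps block_id -> list of alignments already carrying
    global accessions.  A subject reported from two different blocks
    violates the partition invariant and raises.
    """
    seen: dict = {}
    merged: list = []
    for block_id in sorted(partials):
        for aln in partials[block_id]:
            prior = seen.setdefault(aln.accession, block_id)
            if prior != block_id:
                raise IntegrityError(
                    f"subject {aln.accession} reported from blocks {prior} and {block_id}"
                )
            merged.append(aln)
    return rank_alignments(merged)[: params.max_reported]


def run_batch(
    queries: list,
    db: SortedDatabase,
    index: DatabaseIndex,
    params: SearchParams | None = None,
    workers: int = 1,
    blocks: list | None = None,
) -> BatchResult:
    """Search a query batch against an indexed database.

    ``blocks`` may be passed when the caller already partitioned the
    database; otherwise the partition is recomputed from the index's
    block sizes.
    """
    params = params or SearchParams(
        word_length=index.w,
        neighbor_threshold=index.threshold,
        overlap=index.w,
        matrix_name=index.matrix_name,
    )
    if params.word_length != index.w or params.matrix_name != index.matrix_name:
        raise InputError("search params are incompatible with the index parameters")
    if not queries:
        raise InputError("empty query batch")
    if blocks is None:
        blocks = _blocks_from_index(db, index)
    db_letters = db.total_letters
    db_seqs = db.n_sequences

    neighbors = index.neighbor_table
    plans = [
        make_query_plan(q, neighbors, index.w) if q.length >= params.word_length else None
        for q in queries
    ]
    for q in queries:
        if q.length < params.word_length:
            logger.warning(
                "query %s shorter than the word length; empty result", q.accession
            )

    # outer loop: blocks; inner (parallel) loop: queries -> ungapped HSPs
    hsp_partials: dict = {}
    for block, bindex in zip(blocks, index.blocks):
        positions = decode_block(bindex)

        def _one(qi: int):
            if plans[qi] is None:
                return qi, []
            return qi, compute_block_hsps(
                queries[qi], block, bindex, params,
                positions=positions, neighbors=neighbors, plan=plans[qi],
            )

        if workers > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                results = list(pool.map(_one, range(len(queries))))
        else:
            results = [_one(qi) for qi in range(len(queries))]
        for qi, hsps in results:
            hsp_partials[(block.block_id, qi)] = hsps

    # gapped extension with traceback after the per-block merge
    per_query: list = []
    for qi, q in enumerate(queries):
        partials: dict = {}
        for block in blocks:
            hsps = hsp_partials.get((block.block_id, qi), [])
            if not hsps:
                continue
            partials[block.block_id] = gapped_stage(
                q, block.sequences, hsps, params, db_letters, db_seqs
            )
        per_query.append(merge_results(partials, params))
    return BatchResult(
        queries=queries,
        alignments=per_query,
        params=params,
        db_letters=db_letters,
        db_seqs=db_seqs,
        metadata={"n_blocks": len(blocks), "workers": workers},
    )


def _blocks_from_index(db: SortedDatabase, index: DatabaseIndex) -> list:
    """Re-slice the sorted database to match the index's block boundaries."""
    blocks = []
    start = 0
    for bi in index.blocks:
        seqs = db.sequences[start : start + bi.n_sequences]
        if len(seqs) != bi.n_sequences or sum(s.length for s in seqs) != bi.letters:
            raise InputError("index does not match the sorted database")
        blocks.append(DatabaseBlock(bi.block_id, seqs, start))
        start += bi.n_sequences
    if start != db.n_sequences:
        raise InputError("index does not cover the whole database")
    return blocks


# -- report formatting -------------------------------------------------------


def _fmt_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    if e < 1e-180:
        return f"{e:.0e}"
    if e < 0.001:
        return f"{e:.2e}"
    if e < 10:
        return f"{e:.3g}"
    return f"{e:.1f}"


def format_tabular(result: BatchResult) -> str:
    """12-column tab-separated report (the standard tabular layout):
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore, with 1-based inclusive coordinates."""
    lines = []
    for q, alns in zip(result.queries, result.alignments):
        for a in alns:
            length = a.align_len
            pident = 100.0 * a.identities / length if length else 0.0
            mismatch = length - a.identities - a.gap_columns
            lines.append(
                "\t".join(
                    [
                        q.accession,
                        a.accession,
                        f"{pident:.3f}",
                        str(length),
                        str(mismatch),
                        str(a.gap_opens),
                        str(a.q_start + 1),
                        str(a.q_end),
                        str(a.s_start + 1),
                        str(a.s_end),
                        _fmt_evalue(a.evalue),
                        f"{a.bit_score:.1f}",
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def _aligned_strings(query: ProteinSequence, subject_seq: str, a: GappedAlignment):
    from .alphabet import decode

    q = query.seq
    s = subject_seq
    qa, sa, mid = [], [], []
    qi, si = a.q_start, a.s_start
    for op in a.ops:
        if op == "M":
            qa.append(q[qi])
            sa.append(s[si])
            mid.append("|" if q[qi] == s[si] else " ")
            qi += 1
            si += 1
        elif op == "I":
            qa.append(q[qi])
            sa.append("-")
            mid.append(" ")
            qi += 1
        else:
            qa.append("-")
            sa.append(s[si])
            mid.append(" ")
            si += 1
    return "".join(qa), "".join(mid), "".join(sa)


def format_pairwise(result: BatchResult, db: SortedDatabase | None = None) -> str:
    """Human-readable pairwise report."""
    subj_by_acc = {}
    if db is not None:
        subj_by_acc = {s.accession: s.seq for s in db.sequences}
    out = []
    for q, alns in zip(result.queries, result.alignments):
        out.append(f"Query= {q.accession}  (length {q.length})")
        if not alns:
            out.append("  No hits found")
        for a in alns:
            out.append(
                f"> {a.accession}  score={a.score} bits={a.bit_score:.1f} "
                f"E={_fmt_evalue(a.evalue)} identities={a.identities}/{a.align_len} "
                f"gaps={a.gap_columns}"
            )
            sseq = subj_by_acc.get(a.accession)
            if sseq is not None:
                qa, mid, sa = _aligned_strings(q, sseq, a)
                for ofs in range(0, len(qa), 60):
                    out.append(f"  Query  {a.q_start + 1 + ofs:>5} {qa[ofs:ofs+60]}")
                    out.append(f"                {mid[ofs:ofs+60]}")
                    out.append(f"  Sbjct  {a.s_start + 1 + ofs:>5} {sa[ofs:ofs+60]}")
        out.append("")
    return "\n".join(out)
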