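"""Brute-force reference implementations used as test oracles.

These deliberately avoid the engine's data structures: hits come from a
quadratic word-by-word scan, two-hit pairs from the classical
query-indexed last-hit-array method, and optimal alignments from a full
Smith-Waterman DP.  They share the SearchParams object with the engine
so equivalence tests are one-line assertions, but they never call the
engine's seeding or binning code.
"""

from __future__ import annotations

import numpy as np

from .db_prep import ProteinSequence
from .errors import InputError
from .search_core import (
    SearchParams,
    extend_two_hit_pairs,
    gapped_stage,
    rank_alignments,
)

_NEG = -(2**40)


# -- Smith-Waterman ----------------------------------------------------------


def sw_local(
    query: np.ndarray,
    subject: np.ndarray,
    matrix_scores: np.ndarray,
    gap_open: int,
    gap_extend: int,
):
    """Optimal affine-gap local alignment, full O(mn) DP with traceback.

    Gap of length k costs gap_open + k * gap_extend.  Ties are broken by
    the earliest best cell in row-major order; the traceback prefers
    diagonal moves, then gap continuation.

    Returns (score, q_start, q_end, s_start, s_end, ops) with 'M'/'I'/'D'
    ops ('I' consumes a query residue, 'D' a subject residue); score 0
    yields an empty alignment.
    """
    m_len, n_len = len(query), len(subject)
    sub = np.asarray(matrix_scores, dtype=np.int64)
    H = np.zeros((m_len + 1, n_len + 1), dtype=np.int64)
    E = np.full((m_len + 1, n_len + 1), _NEG, dtype=np.int64)
    F = np.full((m_len + 1, n_len + 1), _NEG, dtype=np.int64)
    go, ge = gap_open, gap_extend
    best, bi, bj = 0, 0, 0
    for i in range(1, m_len + 1):
        row_sub = sub[query[i - 1], subject] if n_len else np.empty(0, np.int64)
        for j in range(1, n_len + 1):
            E[i, j] = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            F[i, j] = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            h = max(0, H[i - 1, j - 1] + row_sub[j - 1], E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = int(h), i, j
    if best == 0:
        return 0, 0, 0, 0, 0, ""
    ops = []
    i, j = bi, bj
    state = "H"
    while state == "H" and H[i, j] != 0 or state in ("E", "F"):
        if state == "H":
            if H[i, j] == H[i - 1, j - 1] + sub[query[i - 1], subject[j - 1]] and i > 0 and j > 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            nxt_cont = E[i, j] == E[i, j - 1] - ge
            j -= 1
            if not nxt_cont:
                state = "H"
        else:
            ops.append("I")
            nxt_cont = F[i, j] == F[i - 1, j] - ge
            i -= 1
            if not nxt_cont:
                state = "H"
    ops.reverse()
    return best, i, bi, j, bj, "".join(ops)


def sw_aligned_pairs(q_start, s_start, ops) -> set:
    """Set of (query_index, subject_index) aligned as pairs in a traceback."""
    out = set()
    qi, si = q_start, s_start
    for op in ops:
        if op == "M":
            out.add((qi, si))
            qi += 1
            si += 1
        elif op == "I":
            qi += 1
        else:
            si += 1
    return out


# -- quadratic hit scan ------------------------------------------------------


def quadratic_hits(query: ProteinSequence, subject: ProteinSequence, params: SearchParams):
    """All (query_offset, subject_offset) word hits by brute-force scoring.

    A hit is an exact word match or a word pair scoring >= the neighbor
    threshold under the matrix; words containing masked residues never
    hit.  Returns hits sorted by (query_offset, subject_offset).
    """
    w = params.word_length
    t = params.neighbor_threshold
    sub = np.asarray(params.matrix.scores, dtype=np.int64)
    q, s = query.residues, subject.residues
    if query.length < w or subject.length < w:
        return []
    s_win = np.lib.stride_tricks.sliding_window_view(s, w)
    s_valid = (s_win < 20).all(axis=1)
    hits = []
    for p in range(query.length - w + 1):
        qw = q[p : p + w]
        if (qw >= 20).any():
            continue
        scores = np.zeros(len(s_win), dtype=np.int64)
        exact = np.ones(len(s_win), dtype=bool)
        for k in range(w):
            scores += sub[qw[k], s_win[:, k]]
            exact &= s_win[:, k] == qw[k]
        hit = s_valid & (exact | (scores >= t))
        hits.extend((p, int(o)) for o in np.nonzero(hit)[0])
    return hits


def classical_two_hit_pairs(query: ProteinSequence, subject: ProteinSequence, params: SearchParams, hits=None):
    """Two-hit pairs via the classical per-diagonal last-hit array.

    Hits are scanned in query-offset order (the query-indexed traversal);
    the last-hit array is keyed by diagonal.  A hit at distance >= overlap
    from the array entry becomes the new entry (emitting the pair when the
    distance is also < threshold_A); an overlapping hit leaves the entry
    in place.  Returns (diagonal, first_offset, second_offset) triples in
    emission order.
    """
    if hits is None:
        hits = quadratic_hits(query, subject, params)
    last: dict = {}
    pairs = []
    for p, o in hits:
        d = o - p
        prev = last.get(d)
        if prev is None:
            last[d] = o
            continue
        dist = o - prev
        if dist >= params.overlap:
            if dist < params.threshold_a:
                pairs.append((d, prev, o))
            last[d] = o
    return pairs


def naive_search(
    queries,
    database,
    params: SearchParams,
    db_letters: int | None = None,
    db_seqs: int | None = None,
    max_reported: int | None = None,
    gapped_x_drop: float | None = None,
):
    """Query-indexed reference pipeline: quadratic seeding + classical
    two-hit scan, then the shared extension and statistics stages.

    Returns one ranked alignment list per query.
    """
    if not database:
        raise InputError("empty database")
    if db_letters is None:
        db_letters = sum(s.length for s in database)
    if db_seqs is None:
        db_seqs = len(database)
    msub = np.asarray(params.matrix.scores, dtype=np.int64)
    x = params.x_drop_ungapped_raw()
    out = []
    for q in queries:
        hsps = []
        if q.length >= params.word_length:
            for sid, subject in enumerate(database):
                pairs = classical_two_hit_pairs(q, subject, params)
                offs = [o for (_, _, o) in pairs]
                diags = [d for (d, _, _) in pairs]
                hsps.extend(
                    extend_two_hit_pairs(
                        q.residues, subject.residues, sid, offs, diags, params, msub, x
                    )
                )
        alns = gapped_stage(
            q, database, hsps, params, db_letters, db_seqs, gapped_x_drop
        )
        ranked = rank_alignments(alns)
        if max_reported is not None:
            ranked = ranked[:max_reported]
        out.append(ranked[: params.max_reported])
    return out
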