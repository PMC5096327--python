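"""Database-indexed search: seeding, two-level binning, X-drop extension.

The engine walks the query's words (and their neighbor words) through a
block's posting lists, bins the resulting hits first by diagonal and then
by subject sequence, applies the two-hit filter while rebinning, and runs
ungapped then gapped X-drop extensions on the surviving seed pairs.

Hit order matters for equivalence with the classical query-indexed
two-hit scan: first-level bins are scanned in ascending diagonal order,
and within one (sequence, diagonal) the hits arrive in ascending subject
offset, exactly as in the classical method, so the emitted two-hit pair
set is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .db_prep import DatabaseBlock, ProteinSequence
from .errors import InputError
from .indexer import (
    BlockIndex,
    NeighborTable,
    PositionIndex,
    build_neighbor_table,
    decode_block,
    window_word_ids,
)
from .matrices import SubstitutionMatrix, load_matrix
from . import stats

_NEG = np.int64(-(2**40))

try:  # optional acceleration; the pure-Python/numpy paths are the reference
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


@dataclass(frozen=True)
class SearchParams:
    """Tunable search parameters (NCBI BLASTP-convention defaults)."""

    word_length: int = 3
    neighbor_threshold: float = 11.0
    threshold_a: int = 40  # max diagonal distance between the two hits
    overlap: int = 3  # min distance; defaults to word_length
    x_drop_ungapped_bits: float = 7.0
    x_drop_gapped_bits: float = 15.0
    gap_trigger: int = 22  # raw ungapped score that triggers gapped extension
    ungapped_cutoff: int | None = None  # defaults to gap_trigger
    gap_open: int = 11
    gap_extend: int = 1
    matrix_name: str = "BLOSUM62"
    evalue_cutoff: float = 10.0
    max_reported: int = 500

    def __post_init__(self):
        if self.overlap > self.threshold_a:
            raise InputError("overlap must be <= threshold_A")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")

    @property
    def matrix(self) -> SubstitutionMatrix:
        return load_matrix(self.matrix_name)

    @property
    def ka_ungapped(self) -> stats.KarlinParams:
        return stats.karlin_params(self.matrix_name)

    @property
    def ka_gapped(self) -> stats.KarlinParams:
        return stats.karlin_params(self.matrix_name, self.gap_open, self.gap_extend)

    def x_drop_ungapped_raw(self) -> float:
        if np.isinf(self.x_drop_ungapped_bits):
            return float("inf")
        return int(self.x_drop_ungapped_bits * np.log(2) / self.ka_ungapped.lam)

    def x_drop_gapped_raw(self) -> float:
        if np.isinf(self.x_drop_gapped_bits):
            return float("inf")
        return int(self.x_drop_gapped_bits * np.log(2) / self.ka_gapped.lam)

    def effective_ungapped_cutoff(self) -> int:
        return self.gap_trigger if self.ungapped_cutoff is None else self.ungapped_cutoff


@dataclass
class FirstLevelBins:
    """Hits grouped by diagonal id (diagonal = subject_offset - query_offset).

    Arrays are stably sorted by diagonal, so within one bin hits keep the
    append order of the posting-list traversal.
    """

    query_len: int
    diagonals: np.ndarray = field(repr=False)  # int64
    seq_ids: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)  # subject offsets, int64

    @property
    def n_hits(self) -> int:
        return len(self.diagonals)

    def bin(self, diagonal: int) -> list:
        lo = np.searchsorted(self.diagonals, diagonal, side="left")
        hi = np.searchsorted(self.diagonals, diagonal, side="right")
        return list(zip(self.seq_ids[lo:hi].tolist(), self.offsets[lo:hi].tolist()))

    def hit_multiset(self):
        """Multiset of (query_offset, seq_id, subject_offset) for oracles."""
        qoff = self.offsets - self.diagonals
        return sorted(zip(qoff.tolist(), self.seq_ids.tolist(), self.offsets.tolist()))


@dataclass
class SecondLevelBins:
    """Filtered triggering hits grouped by sequence id.

    Within one bin the hits appear in first-level scan order, hence
    naturally sorted by diagonal; each carries the offset of the first
    hit of its two-hit pair for inspection.
    """

    seq_ids: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)
    diagonals: np.ndarray = field(repr=False)
    first_offsets: np.ndarray = field(repr=False)

    @property
    def n_triggers(self) -> int:
        return len(self.seq_ids)

    def pair_set(self) -> set:
        """Set of (seq_id, diagonal, first_offset, second_offset)."""
        return set(
            zip(
                self.seq_ids.tolist(),
                self.diagonals.tolist(),
                self.first_offsets.tolist(),
                self.offsets.tolist(),
            )
        )

    def per_sequence(self):
        """Yield (seq_id, offsets, diagonals) per bin, ascending seq_id."""
        if not len(self.seq_ids):
            return
        bounds = np.nonzero(np.diff(self.seq_ids))[0] + 1
        for chunk in np.split(np.arange(len(self.seq_ids)), bounds):
            yield (
                int(self.seq_ids[chunk[0]]),
                self.offsets[chunk],
                self.diagonals[chunk],
            )


@dataclass(frozen=True)
class HSP:
    """Ungapped high-scoring segment pair (0-based half-open coordinates)."""

    seq_id: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int


@dataclass
class GappedAlignment:
    seq_id: int
    accession: str
    score: int
    bit_score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    ops: str  # M = aligned pair, I = query residue vs gap, D = gap vs subject residue
    identities: int
    positives: int
    gap_columns: int
    gap_opens: int

    @property
    def align_len(self) -> int:
        return len(self.ops)

    def key(self):
        return (
            self.accession, self.score, self.q_start, self.q_end,
            self.s_start, self.s_end, self.ops,
        )


# -- hit detection -----------------------------------------------------------


def make_query_plan(query: ProteinSequence, neighbors: NeighborTable, w: int):
    """(query positions, visited word ids) arrays for every indexable word.

    For each query position the exact word is visited first, then its
    neighbors in ascending word-id order.
    """
    wids = window_word_ids(query.residues, w)
    qpos_parts, word_parts = [], []
    for p, wid in enumerate(wids):
        if wid < 0:
            continue
        nb = neighbors.neighbors(int(wid))
        visit = np.concatenate([[wid], nb]).astype(np.int64)
        word_parts.append(visit)
        qpos_parts.append(np.full(len(visit), p, dtype=np.int64))
    if not word_parts:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(qpos_parts), np.concatenate(word_parts)


def detect_hits(
    query: ProteinSequence,
    index: BlockIndex,
    params: SearchParams,
    positions: PositionIndex | None = None,
    neighbors: NeighborTable | None = None,
    plan=None,
) -> FirstLevelBins:
    """First-level binning of all exact- and neighbor-word hits."""
    if positions is None:
        positions = decode_block(index)
    if plan is None:
        if neighbors is None:
            neighbors = build_neighbor_table(
                index.matrix_name, index.threshold, index.w
            )
        plan = make_query_plan(query, neighbors, index.w)
    qpos, words = plan
    starts = positions.starts
    lo = starts[words]
    lens = starts[words + 1] - lo
    total = int(lens.sum())
    if total == 0:
        e = np.empty(0, np.int64)
        return FirstLevelBins(query.length, e, e.copy(), e.copy())
    out_start = np.cumsum(lens) - lens
    idx = np.arange(total, dtype=np.int64) - np.repeat(out_start, lens) + np.repeat(lo, lens)
    seq = positions.seq_ids[idx].astype(np.int64)
    off = positions.offsets[idx].astype(np.int64)
    qp = np.repeat(qpos, lens)
    diag = off - qp
    order = np.argsort(diag, kind="stable")
    return FirstLevelBins(query.length, diag[order], seq[order], off[order])


def _two_hit_filter_py(seq, diag, off, overlap, threshold_a, emit, prev):
    last_seq = last_diag = last_off = -(2**60)
    for i in range(len(seq)):
        s, d, o = seq[i], diag[i], off[i]
        if s != last_seq or d != last_diag:
            last_seq, last_diag, last_off = s, d, o
            continue
        dist = o - last_off
        if dist >= overlap:
            if dist < threshold_a:
                emit[i] = True
                prev[i] = last_off
            last_off = o
        # an overlapping hit (dist < overlap) never displaces the anchor


if _numba is not None:
    _two_hit_filter = _numba.njit(cache=False)(_two_hit_filter_py)
else:  # pragma: no cover
    _two_hit_filter = _two_hit_filter_py


def bin_and_filter(bins: FirstLevelBins, params: SearchParams) -> SecondLevelBins:
    """Second-level binning with the two-hit filter.

    Scans first-level bins in ascending diagonal order keeping one
    last-hit record per sequence (anchor offset and its diagonal).  A hit
    on the record's diagonal whose distance to the anchor falls in
    [overlap, threshold_A) is emitted as the triggering hit of a two-hit
    pair; any hit at distance >= overlap (or on a new diagonal) becomes
    the new anchor, while a hit overlapping the anchor leaves it in
    place, so runs of overlapping hits (e.g. on the identity diagonal)
    still trigger.
    """
    if bins.n_hits == 0:
        e = np.empty(0, np.int64)
        return SecondLevelBins(e, e.copy(), e.copy(), e.copy())
    order = np.argsort(bins.seq_ids, kind="stable")  # per-seq, scan order kept
    seq = bins.seq_ids[order]
    off = bins.offsets[order]
    diag = bins.diagonals[order]
    emit = np.zeros(len(seq), dtype=np.bool_)
    prev = np.zeros(len(seq), dtype=np.int64)
    _two_hit_filter(
        seq, diag, off, np.int64(params.overlap), np.int64(params.threshold_a), emit, prev
    )
    return SecondLevelBins(seq[emit], off[emit], diag[emit], prev[emit])


# -- ungapped extension ------------------------------------------------------


def _xdrop_run(scores: np.ndarray, x_drop: float):
    """Best non-negative prefix sum under the X-drop stopping rule.

    Returns (gain, length): the running score is followed until it falls
    more than ``x_drop`` below its maximum; the extension ends at the
    first position attaining the maximal prefix sum (0 if none positive).
    """
    if len(scores) == 0:
        return 0, 0
    c = np.cumsum(scores, dtype=np.int64)
    if not np.isinf(x_drop):
        m = np.maximum.accumulate(c)
        dropped = (m - c) > x_drop
        if dropped.any():
            c = c[: int(np.argmax(dropped)) + 1]
    best = int(c.max())
    if best <= 0:
        return 0, 0
    return best, int(np.argmax(c)) + 1


def ungapped_extend(
    query: np.ndarray,
    subject: np.ndarray,
    q_word_start: int,
    s_word_start: int,
    params: SearchParams,
    matrix_scores: np.ndarray | None = None,
    x_drop: float | None = None,
):
    """X-drop ungapped extension of a seed word along its diagonal.

    Extends left then right from the triggering word (whose score is
    always included) and returns ``(score, q_start, q_end, s_start,
    s_end)`` in half-open coordinates.
    """
    m = params.matrix.scores if matrix_scores is None else matrix_scores
    x = params.x_drop_ungapped_raw() if x_drop is None else x_drop
    w = params.word_length
    seed = int(
        m[query[q_word_start : q_word_start + w], subject[s_word_start : s_word_start + w]].sum()
    )
    k = min(q_word_start, s_word_start)
    left_scores = (
        m[query[q_word_start - k : q_word_start][::-1], subject[s_word_start - k : s_word_start][::-1]]
        if k
        else np.empty(0, np.int64)
    )
    r = min(len(query) - q_word_start - w, len(subject) - s_word_start - w)
    right_scores = (
        m[query[q_word_start + w : q_word_start + w + r], subject[s_word_start + w : s_word_start + w + r]]
        if r > 0
        else np.empty(0, np.int64)
    )
    gain_l, ext_l = _xdrop_run(np.asarray(left_scores, dtype=np.int64), x)
    gain_r, ext_r = _xdrop_run(np.asarray(right_scores, dtype=np.int64), x)
    score = seed + gain_l + gain_r
    return (
        score,
        q_word_start - ext_l,
        q_word_start + w + ext_r,
        s_word_start - ext_l,
        s_word_start + w + ext_r,
    )


def extend_two_hit_pairs(
    query: np.ndarray,
    subject: np.ndarray,
    seq_id: int,
    triggers_offsets,
    triggers_diagonals,
    params: SearchParams,
    matrix_scores: np.ndarray | None = None,
    x_drop: float | None = None,
) -> list:
    """Ungapped-extend each triggering hit, skipping already-covered seeds.

    A trigger whose word lies inside the subject span of the previous
    extension on the same diagonal is skipped.  Triggers must arrive in
    ascending subject-offset order per diagonal (both the binned engine
    and the classical scan provide this), which makes the skip rule
    order-independent between the two pipelines.
    """
    m = params.matrix.scores if matrix_scores is None else matrix_scores
    x = params.x_drop_ungapped_raw() if x_drop is None else x_drop
    w = params.word_length
    cutoff = params.effective_ungapped_cutoff()
    last_end: dict = {}
    hsps = []
    for s_off, diag in zip(np.asarray(triggers_offsets).tolist(), np.asarray(triggers_diagonals).tolist()):
        if last_end.get(diag, -1) >= s_off + w:
            continue
        q_off = s_off - diag
        score, qs, qe, ss, se = ungapped_extend(
            query, subject, q_off, s_off, params, m, x
        )
        last_end[diag] = se
        if score >= cutoff:
            hsps.append(HSP(seq_id, qs, qe, ss, se, score))
    return hsps


def dedup_hsps(hsps: list) -> list:
    """Canonical order + containment dedup (same sequence assumed)."""
    out = []
    for h in sorted(hsps, key=lambda h: (-h.score, h.q_start, h.s_start, h.q_end, h.s_end)):
        contained = any(
            h.q_start >= k.q_start
            and h.q_end <= k.q_end
            and h.s_start >= k.s_start
            and h.s_end <= k.s_end
            for k in out
        )
        if not contained:
            out.append(h)
    return out


# -- gapped extension --------------------------------------------------------


if _numba is not None:

    @_numba.njit(cache=False)
    def _xdrop_affine_rows(qa, sa, sub, go, ge, x, masked, hptr, ncptr, eptr, fptr, H, F, neg):
        n_len = len(sa)
        m_len = len(qa)
        if masked:
            hi = min(n_len, max(0, int((x - go) // ge))) if n_len else 0
            slack = max(0, int((x - go) // ge)) + 2
        else:
            hi = n_len
            slack = 0
        lo = 0
        H[0] = 0
        for j in range(1, hi + 1):
            H[j] = -go - ge * j
            hptr[0, j] = 1
            if j >= 2:
                eptr[0, j] = 1
        best = 0
        bi = 0
        bj = 0
        for i in range(1, m_len + 1):
            w_lo = lo
            w_hi = min(n_len, hi + 1 + slack) if masked else n_len
            prev_diag = H[w_lo - 1] if w_lo >= 1 else neg
            e_prev = neg
            nc_prev = neg
            row_best = neg
            row_arg = w_lo
            qrow = sub[qa[i - 1]]
            for j in range(w_lo, w_hi + 1):
                old_h = H[j]
                f_cont = F[j] - ge
                f_open = old_h - go - ge
                if f_cont >= f_open:
                    fj = f_cont
                    fptr[i, j] = 1
                else:
                    fj = f_open
                    fptr[i, j] = 0
                if j >= 1:
                    dv = prev_diag + qrow[sa[j - 1]]
                else:
                    dv = neg
                if dv >= fj:
                    nc = dv
                    ncptr[i, j] = 0
                else:
                    nc = fj
                    ncptr[i, j] = 1
                if j == 0:
                    ncptr[i, 0] = 1
                if j == w_lo:
                    ej = neg
                else:
                    e_cont = e_prev - ge
                    e_open = nc_prev - go - ge
                    if e_cont >= e_open:
                        ej = e_cont
                        eptr[i, j] = 1
                    else:
                        ej = e_open
                        eptr[i, j] = 0
                if nc >= ej:
                    hj = nc
                    hptr[i, j] = 0
                else:
                    hj = ej
                    hptr[i, j] = 1
                if hj > row_best:
                    row_best = hj
                    row_arg = j
                prev_diag = old_h
                H[j] = hj
                F[j] = fj
                e_prev = ej
                nc_prev = nc
            if row_best > best:
                best = row_best
                bi = i
                bj = row_arg
            if masked:
                cut = best - x
                alive_lo = -1
                alive_hi = -1
                for j in range(w_lo, w_hi + 1):
                    if H[j] < cut:
                        H[j] = neg
                    elif alive_lo < 0:
                        alive_lo = j
                        alive_hi = j
                    else:
                        alive_hi = j
                    if F[j] < cut:
                        F[j] = neg
                if alive_lo < 0:
                    break
                lo = alive_lo
                hi = alive_hi
        return best, bi, bj


def _xdrop_affine(qa, sa, sub, gap_open, gap_extend, x_drop):
    """X-drop affine-gap extension DP from the origin corner.

    Returns (best_score, q_used, s_used, ops) where ops run from the
    origin outward.  With infinite ``x_drop`` this is the exact optimal
    extension.  Ties prefer the earliest cell in row-major order and, in
    the traceback, diagonal moves over gaps and gap continuation over
    opening.  Dispatches to the compiled kernel when numba is available;
    both paths implement the same recurrence and tie rules.
    """
    if _numba is not None:
        m_len, n_len = len(qa), len(sa)
        if m_len == 0 and n_len == 0:
            return 0, 0, 0, ""
        n1 = n_len + 1
        hptr = np.zeros((m_len + 1, n1), dtype=np.int8)
        ncptr = np.zeros((m_len + 1, n1), dtype=np.int8)
        eptr = np.zeros((m_len + 1, n1), dtype=np.int8)
        fptr = np.zeros((m_len + 1, n1), dtype=np.int8)
        H = np.full(n1, _NEG, dtype=np.int64)
        F = np.full(n1, _NEG, dtype=np.int64)
        x = np.float64(x_drop)
        masked = not np.isinf(x_drop)
        best, bi, bj = _xdrop_affine_rows(
            np.ascontiguousarray(qa), np.ascontiguousarray(sa),
            np.ascontiguousarray(sub), np.int64(gap_open), np.int64(gap_extend),
            np.int64(x if masked else 0), masked,
            hptr, ncptr, eptr, fptr, H, F, np.int64(_NEG),
        )
        return best, bi, bj, _affine_traceback(hptr, ncptr, eptr, fptr, bi, bj)
    return _xdrop_affine_numpy(qa, sa, sub, gap_open, gap_extend, x_drop)


def _affine_traceback(hptr, ncptr, eptr, fptr, bi, bj) -> str:
    ops = []
    i, j = bi, bj
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            state = "E" if hptr[i, j] else "NC"
        elif state == "NC":
            if ncptr[i, j] == 0:
                ops.append("M")
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            cont = eptr[i, j]
            j -= 1
            state = "E" if cont else "NC"
        else:  # F
            ops.append("I")
            cont = fptr[i, j]
            i -= 1
            state = "F" if cont else "H"
    ops.reverse()
    return "".join(ops)


def _xdrop_affine_numpy(qa, sa, sub, gap_open, gap_extend, x_drop):
    """Pure-numpy band DP (reference path; same semantics as the kernel)."""
    m_len, n_len = len(qa), len(sa)
    if m_len == 0 and n_len == 0:
        return 0, 0, 0, ""
    go, ge = gap_open, gap_extend
    masked = not np.isinf(x_drop)
    n1 = n_len + 1
    j_idx = np.arange(n1, dtype=np.int64)
    # pointer codes -- hptr: 0 = non-gap candidate, 1 = E; ncptr: 0 = diag, 1 = F
    hptr = np.zeros((m_len + 1, n1), dtype=np.int8)
    ncptr = np.zeros((m_len + 1, n1), dtype=np.int8)
    eptr = np.zeros((m_len + 1, n1), dtype=np.int8)  # 1 = continue gap
    fptr = np.zeros((m_len + 1, n1), dtype=np.int8)

    H = np.full(n1, _NEG, dtype=np.int64)
    F = np.full(n1, _NEG, dtype=np.int64)
    H[0] = 0
    # active column window [lo, hi] of the previous row; cells outside any
    # row's window are provably below best - x_drop, so the band is exact
    if masked:
        hi = min(n_len, max(0, int((x_drop - go) // ge))) if n_len else 0
        slack = max(0, int((x_drop - go) // ge)) + 2  # max rightward reach of a gap run
    else:
        hi = n_len
        slack = 0
    lo = 0
    if hi >= 1:
        H[1 : hi + 1] = -go - ge * j_idx[1 : hi + 1]
        hptr[0, 1 : hi + 1] = 1
        eptr[0, 2 : hi + 1] = 1
    best = 0
    bi = bj = 0
    for i in range(1, m_len + 1):
        w_lo = lo
        w_hi = min(n_len, hi + 1 + slack) if masked else n_len
        s0, s1 = w_lo, w_hi + 1
        Hw_prev = H[s0:s1]
        Fw_prev = F[s0:s1]
        F_open = Hw_prev - go - ge
        Fw = np.maximum(Fw_prev - ge, F_open)
        fptr[i, s0:s1] = Fw_prev - ge >= F_open
        width = s1 - s0
        diag = np.full(width, _NEG, dtype=np.int64)
        d0 = max(w_lo, 1)
        diag[d0 - w_lo :] = H[d0 - 1 : w_hi] + sub[qa[i - 1], sa[d0 - 1 : w_hi]]
        nc = np.maximum(diag, Fw)
        ncw = diag < Fw
        if w_lo == 0:
            ncw[0] = True
        ncptr[i, s0:s1] = ncw
        # horizontal gaps via prefix running max over the window
        jg = j_idx[s0:s1]
        run = np.maximum.accumulate(nc + ge * jg)
        E = np.full(width, _NEG, dtype=np.int64)
        if width > 1:
            E[1:] = run[:-1] - go - ge * jg[1:]
            eptr[i, s0 + 1 : s1] = E[:-1] - ge >= nc[:-1] - go - ge
        H_new = np.maximum(nc, E)
        hptr[i, s0:s1] = nc < E
        row_best = int(H_new.max())
        if row_best > best:
            best = row_best
            bi = i
            bj = w_lo + int(np.argmax(H_new))
        if masked:
            cut = best - x_drop
            H_new[H_new < cut] = _NEG
            Fw[Fw < cut] = _NEG
        H[s0:s1] = H_new
        F[s0:s1] = Fw
        if masked:
            alive = np.nonzero(H_new > _NEG // 2)[0]
            if not len(alive):
                break
            lo = w_lo + int(alive[0])
            hi = w_lo + int(alive[-1])
    return best, bi, bj, _affine_traceback(hptr, ncptr, eptr, fptr, bi, bj)


def choose_seed(query, subject, hsp: HSP, matrix_scores) -> tuple:
    """Score-balanced midpoint of the HSP: first aligned pair where the
    cumulative score reaches half the HSP total."""
    v = matrix_scores[query[hsp.q_start : hsp.q_end], subject[hsp.s_start : hsp.s_end]]
    c = np.cumsum(v)
    total = int(c[-1])
    idx = int(np.argmax(2 * c >= total))
    return hsp.q_start + idx, hsp.s_start + idx


def gapped_extend(
    query: np.ndarray,
    subject: np.ndarray,
    hsp: HSP,
    params: SearchParams,
    matrix_scores: np.ndarray | None = None,
    x_drop: float | None = None,
):
    """Two-sided X-drop gapped extension seeded at the HSP midpoint.

    Returns (score, q_start, q_end, s_start, s_end, ops).
    """
    m = params.matrix.scores if matrix_scores is None else matrix_scores
    msub = np.asarray(m, dtype=np.int64)
    x = params.x_drop_gapped_raw() if x_drop is None else x_drop
    qs_seed, ss_seed = choose_seed(query, subject, hsp, msub)
    fwd_score, fq, fs, fops = _xdrop_affine(
        query[qs_seed + 1 :], subject[ss_seed + 1 :], msub,
        params.gap_open, params.gap_extend, x,
    )
    bwd_score, bq, bs, bops = _xdrop_affine(
        query[:qs_seed][::-1], subject[:ss_seed][::-1], msub,
        params.gap_open, params.gap_extend, x,
    )
    score = int(msub[query[qs_seed], subject[ss_seed]]) + fwd_score + bwd_score
    ops = bops[::-1] + "M" + fops
    return (
        score,
        qs_seed - bq,
        qs_seed + 1 + fq,
        ss_seed - bs,
        ss_seed + 1 + fs,
        ops,
    )


def _alignment_counts(query, subject, qs, ss, ops, matrix_scores):
    ident = pos = gaps = opens = 0
    qi, si = qs, ss
    prev = "M"
    for op in ops:
        if op == "M":
            if query[qi] == subject[si]:
                ident += 1
            if matrix_scores[query[qi], subject[si]] > 0:
                pos += 1
            qi += 1
            si += 1
        elif op == "I":
            gaps += 1
            if prev != "I":
                opens += 1
            qi += 1
        else:
            gaps += 1
            if prev != "D":
                opens += 1
            si += 1
        prev = op
    return ident, pos, gaps, opens


def rescore_ops(query, subject, qs, ss, ops, params) -> int:
    """Re-score a traceback (invariant check: must equal the DP score)."""
    m = params.matrix.scores
    total = 0
    qi, si = qs, ss
    prev = None
    for op in ops:
        if op == "M":
            total += int(m[query[qi], subject[si]])
            qi += 1
            si += 1
        else:
            total -= params.gap_extend
            if op != prev:
                total -= params.gap_open
            if op == "I":
                qi += 1
            else:
                si += 1
        prev = op if op != "M" else None
    return total


def gapped_stage(
    query: ProteinSequence,
    subjects: list,
    hsps: list,
    params: SearchParams,
    db_letters: int,
    db_seqs: int,
    x_drop: float | None = None,
) -> list:
    """Gapped extension + statistics for the surviving HSPs of one block.

    HSPs are processed per sequence in canonical order; an HSP contained
    in an already-produced alignment of the same sequence is skipped.
    Alignments failing the E-value cutoff are dropped.
    """
    msub = np.asarray(params.matrix.scores, dtype=np.int64)
    kp = params.ka_gapped
    by_seq: dict = {}
    for h in hsps:
        by_seq.setdefault(h.seq_id, []).append(h)
    out = []
    for seq_id in sorted(by_seq):
        subject = subjects[seq_id]
        kept: list = []
        for h in dedup_hsps(by_seq[seq_id]):
            if h.score < params.gap_trigger:
                continue
            covered = any(
                h.q_start >= a.q_start and h.q_end <= a.q_end
                and h.s_start >= a.s_start and h.s_end <= a.s_end
                for a in kept
            )
            if covered:
                continue
            score, qs, qe, ss, se, ops = gapped_extend(
                query.residues, subject.residues, h, params, msub, x_drop
            )
            ev = stats.evalue(score, query.length, db_letters, db_seqs, kp)
            ident, pos, gaps, opens = _alignment_counts(
                query.residues, subject.residues, qs, ss, ops, msub
            )
            aln = GappedAlignment(
                seq_id=seq_id,
                accession=subject.accession,
                score=score,
                bit_score=stats.bit_score(score, kp),
                evalue=ev,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                ops=ops,
                identities=ident,
                positives=pos,
                gap_columns=gaps,
                gap_opens=opens,
            )
            kept.append(aln)
        out.extend(a for a in kept if a.evalue <= params.evalue_cutoff)
    return out


def rank_alignments(alignments: list) -> list:
    return sorted(
        alignments,
        key=lambda a: (a.evalue, -a.score, a.accession, a.q_start, a.s_start),
    )


def compute_block_hsps(
    query: ProteinSequence,
    block: DatabaseBlock,
    index: BlockIndex,
    params: SearchParams,
    positions: PositionIndex | None = None,
    neighbors: NeighborTable | None = None,
    plan=None,
) -> list:
    """Stages 1-2 for one (query, block): hit detection through ungapped HSPs."""
    flb = detect_hits(query, index, params, positions, neighbors, plan)
    slb = bin_and_filter(flb, params)
    msub = np.asarray(params.matrix.scores, dtype=np.int64)
    x = params.x_drop_ungapped_raw()
    hsps = []
    for seq_id, offs, diags in slb.per_sequence():
        hsps.extend(
            extend_two_hit_pairs(
                query.residues, block.sequences[seq_id].residues, seq_id,
                offs, diags, params, msub, x,
            )
        )
    return hsps


def search_block(
    query: ProteinSequence,
    block: DatabaseBlock,
    index: BlockIndex,
    params: SearchParams,
    db_letters: int | None = None,
    db_seqs: int | None = None,
    positions: PositionIndex | None = None,
    neighbors: NeighborTable | None = None,
    plan=None,
    gapped_x_drop: float | None = None,
) -> list:
    """Full single-block pipeline; returns ranked block-local alignments.

    E-values default to the block's own letter/sequence counts; callers
    searching a multi-block database pass the whole-database numbers so
    results are independent of the partitioning.
    """
    if query.length < params.word_length:
        return []
    if db_letters is None:
        db_letters = block.letters
    if db_seqs is None:
        db_seqs = block.n_sequences
    hsps = compute_block_hsps(query, block, index, params, positions, neighbors, plan)
    alns = gapped_stage(
        query, block.sequences, hsps, params, db_letters, db_seqs, gapped_x_drop
    )
    return rank_alignments(alns)
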