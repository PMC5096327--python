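"""Blocked, sorted, delta-compressed inverted word index.

Per database block the index maps every indexable W-mer (word) to the
sorted list of its (sequence id, subject offset) positions, stored as a
compressed stream: positions sharing a subject offset are merged into one
entry holding the offset once plus all sequence ids, and offsets are
stored as 8-bit increments over the previous entry (first increment taken
from 0).  Increments or position counts above 255 are split across
entries: padding entries ``(255, 0, [])`` absorb offset overflow, and
count overflow is emitted as maximal 255-id entries followed by the
remainder.

Neighbor words (words scoring >= T against a word under the substitution
matrix) are not materialized as positions; the lookup table instead
carries per-word neighbor lists into a shared pool, and the search walks
those posting lists at query time — same visited position multiset, far
smaller index.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alphabet import ALPHABET_SIZE, MASK_CODE
from .db_prep import DatabaseBlock
from .errors import FormatError, InputError
from .matrices import SubstitutionMatrix, load_matrix

DEFAULT_WORD_LENGTH = 3
DEFAULT_NEIGHBOR_THRESHOLD = 11  # BLOSUM62 protein-search convention

_IX_MAGIC = b"IBIX"
_IX_VERSION = 1


# -- word ids ----------------------------------------------------------------


def n_words(w: int = DEFAULT_WORD_LENGTH, a: int = ALPHABET_SIZE) -> int:
    return a**w

def word_to_id(codes, a: int = ALPHABET_SIZE) -> int:
    """Big-endian word id: first residue is the most significant digit."""
    wid = 0
    for c in codes:
        if c >= a:
            raise InputError("masked residue has no word id")
        wid = wid * a + int(c)
    return wid


def id_to_word(wid: int, w: int = DEFAULT_WORD_LENGTH, a: int = ALPHABET_SIZE) -> np.ndarray:
    codes = np.empty(w, dtype=np.uint8)
    for i in range(w - 1, -1, -1):
        codes[i] = wid % a
        wid //= a
    return codes


def window_word_ids(codes: np.ndarray, w: int, a: int = ALPHABET_SIZE):
    """Word ids of all overlapping windows; masked windows get id -1."""
    L = len(codes)
    if L < w:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    wid = np.zeros(L - w + 1, dtype=np.int64)
    ok = np.ones(L - w + 1, dtype=bool)
    for i in range(w):
        win = c[i : L - w + 1 + i]
        wid = wid * a + win
        ok &= win < a
    wid[~ok] = -1
    return wid


# -- basic (uncompressed) index ---------------------------------------------


@dataclass
class BasicIndex:
    """Positions grouped per word in CSR form.

    ``starts`` has a^W + 1 entries; positions of word ``w`` are
    ``(seq_ids[starts[w]:starts[w+1]], offsets[starts[w]:starts[w+1]])``.
    """

    w: int
    starts: np.ndarray = field(repr=False)
    seq_ids: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)
    sorted_by_offset: bool = False

    @property
    def n_positions(self) -> int:
        return len(self.seq_ids)

    def positions(self, wid: int):
        lo, hi = int(self.starts[wid]), int(self.starts[wid + 1])
        return list(zip(self.seq_ids[lo:hi].tolist(), self.offsets[lo:hi].tolist()))

    def nonempty_words(self) -> np.ndarray:
        return np.nonzero(np.diff(self.starts))[0]


def build_basic_index(block: DatabaseBlock, w: int = DEFAULT_WORD_LENGTH) -> BasicIndex:
    """Index every fully indexable W-mer of every sequence in the block.

    Positions are kept in scan order (ascending sequence id, then offset)
    within each word's list.
    """
    if w < 1:
        raise InputError("word length must be >= 1")
    wid_parts, seq_parts, off_parts = [], [], []
    for local_id, s in enumerate(block.sequences):
        wids = window_word_ids(s.residues, w)
        keep = wids >= 0
        if keep.any():
            wid_parts.append(wids[keep])
            off_parts.append(np.nonzero(keep)[0].astype(np.uint32))
            seq_parts.append(np.full(int(keep.sum()), local_id, dtype=np.uint32))
    if wid_parts:
        wids = np.concatenate(wid_parts)
        seqs = np.concatenate(seq_parts)
        offs = np.concatenate(off_parts)
    else:
        wids = np.empty(0, dtype=np.int64)
        seqs = offs = np.empty(0, dtype=np.uint32)
    order = np.argsort(wids, kind="stable")  # scan order preserved per word
    wids = wids[order]
    starts = np.zeros(n_words(w) + 1, dtype=np.int64)
    np.add.at(starts, wids + 1, 1)
    np.cumsum(starts, out=starts)
    return BasicIndex(w, starts, seqs[order], offs[order], sorted_by_offset=False)


def sort_positions(index: BasicIndex) -> BasicIndex:
    """Per word, order positions by (subject offset, sequence id)."""
    sizes = np.diff(index.starts)
    word_of_pos = np.repeat(np.arange(len(sizes)), sizes)
    order = np.lexsort((index.seq_ids, index.offsets, word_of_pos))
    return BasicIndex(
        index.w, index.starts.copy(), index.seq_ids[order], index.offsets[order],
        sorted_by_offset=True,
    )


# -- compression -------------------------------------------------------------


@dataclass(frozen=True)
class CompressedEntry:
    """One unit of the compressed stream: 8-bit offset increment, 8-bit count."""

    delta_offset: int
    count: int
    seq_ids: tuple = ()

    def __post_init__(self):
        if not (0 <= self.delta_offset <= 255):
            raise InputError(f"delta_offset {self.delta_offset} out of 8-bit range")
        if not (0 <= self.count <= 255):
            raise InputError(f"count {self.count} out of 8-bit range")
        if len(self.seq_ids) != self.count:
            raise InputError("count does not match number of sequence ids")


def split_overflow(delta: int, count: int, seq_ids) -> list:
    """Split one merged position entry so every field fits in 8 bits.

    Offset overflow is absorbed by padding entries ``(255, 0, [])``;
    count overflow by maximal 255-id entries followed by the remainder.
    """
    if delta < 0:
        raise InputError("negative offset increment")
    seq_ids = tuple(seq_ids)
    if count != len(seq_ids):
        raise InputError("count does not match number of sequence ids")
    out = []
    while delta > 255:
        out.append(CompressedEntry(255, 0))
        delta -= 255
    pos = 0
    first = True
    while first or pos < count:
        take = min(255, count - pos)
        out.append(CompressedEntry(delta if first else 0, take, seq_ids[pos : pos + take]))
        pos += take
        first = False
    return out


def compress_positions(positions) -> list:
    """Compress one word's sorted positions (merge + increment + overflow).

    ``positions`` is a sequence of ``(seq_id, subject_offset)`` sorted by
    (offset, seq_id).
    """
    entries: list = []
    prev_abs = 0
    i = 0
    pos = list(positions)
    n = len(pos)
    while i < n:
        off = pos[i][1]
        j = i
        ids = []
        while j < n and pos[j][1] == off:
            ids.append(pos[j][0])
            j += 1
        if off < prev_abs or (i > 0 and off == prev_abs):
            raise InputError("positions are not sorted by subject offset")
        entries.extend(split_overflow(off - prev_abs, len(ids), ids))
        prev_abs = off
        i = j
    return entries


def decode_positions(entries) -> list:
    """Exact inverse of compression: absolute ``(seq_id, offset)`` list."""
    out = []
    abs_off = 0
    for e in entries:
        if len(e.seq_ids) != e.count:
            raise InputError("entry id-list length does not match count")
        abs_off += e.delta_offset
        out.extend((sid, abs_off) for sid in e.seq_ids)
    return out


# -- neighbor words ----------------------------------------------------------


def _word_scores(wid: int, matrix: SubstitutionMatrix, w: int) -> np.ndarray:
    """Scores of every a^W word against word ``wid`` (vectorized)."""
    a = ALPHABET_SIZE
    codes = id_to_word(wid, w)
    m = matrix.scores[:a, :a]
    total = np.zeros(1, dtype=np.int64)
    for c in codes:
        total = (total[:, None] + m[c][None, :]).ravel()
    return total


def compute_neighbor_words(
    wid: int,
    matrix: SubstitutionMatrix,
    threshold: float = DEFAULT_NEIGHBOR_THRESHOLD,
    w: int = DEFAULT_WORD_LENGTH,
) -> np.ndarray:
    """All words != wid scoring >= threshold against wid, ascending id."""
    if threshold == float("inf"):
        return np.empty(0, dtype=np.uint32)
    scores = _word_scores(wid, matrix, w)
    hits = np.nonzero(scores >= threshold)[0]
    return hits[hits != wid].astype(np.uint32)


@dataclass
class NeighborTable:
    """Neighbor lists for all a^W words in CSR form (shared across blocks)."""

    w: int
    threshold: float
    matrix_name: str
    starts: np.ndarray = field(repr=False)
    pool: np.ndarray = field(repr=False)

    def neighbors(self, wid: int) -> np.ndarray:
        return self.pool[self.starts[wid] : self.starts[wid + 1]]


@lru_cache(maxsize=4)
def _cached_neighbor_table(matrix_name: str, threshold: float, w: int) -> NeighborTable:
    matrix = load_matrix(matrix_name)
    a = ALPHABET_SIZE
    nw = a**w
    # per-word loop with a vectorized inner scan over all a^w candidates
    lists = []
    sizes = np.zeros(nw, dtype=np.int64)
    if threshold != float("inf"):
        for wid in range(nw):
            nb = compute_neighbor_words(wid, matrix, threshold, w)
            sizes[wid] = len(nb)
            lists.append(nb)
    else:
        lists = [np.empty(0, dtype=np.uint32)] * nw
    starts = np.zeros(nw + 1, dtype=np.int64)
    np.cumsum(sizes, out=starts[1:])
    pool = np.concatenate(lists) if lists else np.empty(0, dtype=np.uint32)
    return NeighborTable(w, threshold, matrix_name, starts, pool.astype(np.uint32))


def build_neighbor_table(
    matrix_name: str = "BLOSUM62",
    threshold: float = DEFAULT_NEIGHBOR_THRESHOLD,
    w: int = DEFAULT_WORD_LENGTH,
) -> NeighborTable:
    return _cached_neighbor_table(matrix_name, float(threshold), w)


# -- block index -------------------------------------------------------------


@dataclass
class BlockIndex:
    """Compressed index of one database block.

    The lookup table is the pair (``entry_starts``, per-word position
    counts); the compressed stream is (``deltas``, ``counts``,
    ``seq_id_stream``).  Word ``w``'s entries are
    ``entry_starts[w]:entry_starts[w+1]``; its id-stream slice starts at
    ``id_starts[entry_starts[w]]``.
    """

    block_id: int
    w: int
    threshold: float
    matrix_name: str
    n_sequences: int
    letters: int
    max_seq_length: int
    entry_starts: np.ndarray = field(repr=False)
    deltas: np.ndarray = field(repr=False)  # uint8
    counts: np.ndarray = field(repr=False)  # uint8
    seq_id_stream: np.ndarray = field(repr=False)  # uint32

    @property
    def id_starts(self) -> np.ndarray:
        out = np.zeros(len(self.counts) + 1, dtype=np.int64)
        np.cumsum(self.counts, out=out[1:])
        return out

    def word_entries(self, wid: int) -> list:
        """Decode the entry objects for one word (testing/inspection API)."""
        lo, hi = int(self.entry_starts[wid]), int(self.entry_starts[wid + 1])
        ids = self.id_starts
        out = []
        for e in range(lo, hi):
            out.append(
                CompressedEntry(
                    int(self.deltas[e]),
                    int(self.counts[e]),
                    tuple(self.seq_id_stream[ids[e] : ids[e + 1]].tolist()),
                )
            )
        return out

    def equals(self, other: "BlockIndex") -> bool:
        return (
            self.block_id == other.block_id
            and self.w == other.w
            and self.threshold == other.threshold
            and self.matrix_name == other.matrix_name
            and self.n_sequences == other.n_sequences
            and self.letters == other.letters
            and self.max_seq_length == other.max_seq_length
            and np.array_equal(self.entry_starts, other.entry_starts)
            and np.array_equal(self.deltas, other.deltas)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.seq_id_stream, other.seq_id_stream)
        )


def build_block_index(
    block: DatabaseBlock,
    w: int = DEFAULT_WORD_LENGTH,
    threshold: float = DEFAULT_NEIGHBOR_THRESHOLD,
    matrix_name: str = "BLOSUM62",
) -> BlockIndex:
    """Full pipeline: basic index -> offset sort -> merge/increment compress."""
    basic = sort_positions(build_basic_index(block, w))
    delta_parts, count_parts, id_parts = [], [], []
    entry_starts = np.zeros(n_words(w) + 1, dtype=np.int64)
    for wid in basic.nonempty_words():
        lo, hi = int(basic.starts[wid]), int(basic.starts[wid + 1])
        offs = basic.offsets[lo:hi]
        sids = basic.seq_ids[lo:hi]
        uniq, first, cnt = np.unique(offs, return_index=True, return_counts=True)
        deltas = np.diff(uniq, prepend=0)
        if (deltas > 255).any() or (cnt > 255).any():
            entries = []
            for k in range(len(uniq)):
                ids = sids[first[k] : first[k] + cnt[k]]
                entries.extend(split_overflow(int(deltas[k]), int(cnt[k]), ids.tolist()))
            delta_parts.append(np.array([e.delta_offset for e in entries], dtype=np.uint8))
            count_parts.append(np.array([e.count for e in entries], dtype=np.uint8))
            id_parts.append(
                np.concatenate([np.asarray(e.seq_ids, dtype=np.uint32) for e in entries])
                if any(e.count for e in entries)
                else np.empty(0, dtype=np.uint32)
            )
            entry_starts[wid + 1] = len(entries)
        else:
            delta_parts.append(deltas.astype(np.uint8))
            count_parts.append(cnt.astype(np.uint8))
            id_parts.append(sids.astype(np.uint32))
            entry_starts[wid + 1] = len(uniq)
    np.cumsum(entry_starts, out=entry_starts)
    cat = lambda parts, dt: (np.concatenate(parts) if parts else np.empty(0, dtype=dt))
    return BlockIndex(
        block_id=block.block_id,
        w=w,
        threshold=float(threshold),
        matrix_name=matrix_name,
        n_sequences=block.n_sequences,
        letters=block.letters,
        max_seq_length=block.max_seq_length,
        entry_starts=entry_starts,
        deltas=cat(delta_parts, np.uint8),
        counts=cat(count_parts, np.uint8),
        seq_id_stream=cat(id_parts, np.uint32),
    )


@dataclass
class PositionIndex:
    """Decoded per-word positions in CSR form (search-time view)."""

    starts: np.ndarray = field(repr=False)
    seq_ids: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)


def decode_block(bi: BlockIndex) -> PositionIndex:
    """Vectorized decode of the whole compressed stream."""
    deltas = bi.deltas.astype(np.int64)
    csum = np.cumsum(deltas)
    n_entries_per_word = np.diff(bi.entry_starts)
    # base = cumulative sum just before each word's first entry
    base_per_word = np.where(
        bi.entry_starts[:-1] > 0, csum[bi.entry_starts[:-1] - 1], 0
    ) if len(csum) else np.zeros(len(n_entries_per_word), dtype=np.int64)
    abs_off = csum - np.repeat(base_per_word, n_entries_per_word)
    counts = bi.counts.astype(np.int64)
    offsets = np.repeat(abs_off, counts).astype(np.uint32)
    pos_per_word = np.add.reduceat(
        np.concatenate([counts, [0]]), bi.entry_starts[:-1]
    )
    pos_per_word[n_entries_per_word == 0] = 0
    starts = np.zeros(len(n_entries_per_word) + 1, dtype=np.int64)
    np.cumsum(pos_per_word, out=starts[1:])
    return PositionIndex(starts, bi.seq_id_stream.astype(np.uint32), offsets)


@dataclass
class DatabaseIndex:
    """All block indexes of one database plus the shared neighbor table."""

    w: int
    threshold: float
    matrix_name: str
    block_cap: int
    blocks: list  # BlockIndex
    neighbor_table: NeighborTable = None

    def __post_init__(self):
        if self.neighbor_table is None:
            self.neighbor_table = build_neighbor_table(self.matrix_name, self.threshold, self.w)

    def save(self, path) -> None:
        save_index(self, path)

    @classmethod
    def load(cls, path) -> "DatabaseIndex":
        return load_index(path)


def build_database_index(
    blocks,
    w: int = DEFAULT_WORD_LENGTH,
    threshold: float = DEFAULT_NEIGHBOR_THRESHOLD,
    matrix_name: str = "BLOSUM62",
    block_cap: int = 0,
) -> DatabaseIndex:
    bis = [build_block_index(b, w, threshold, matrix_name) for b in blocks]
    return DatabaseIndex(w, float(threshold), matrix_name, block_cap, bis)


# -- serialization -----------------------------------------------------------


def _write_arr(fh, arr, dtype) -> None:
    a = np.ascontiguousarray(arr, dtype=dtype)
    fh.write(struct.pack("<Q", a.size))
    fh.write(a.tobytes())


def _read_arr(fh, dtype):
    raw = fh.read(8)
    if len(raw) != 8:
        raise FormatError("truncated index file")
    (n,) = struct.unpack("<Q", raw)
    nbytes = n * np.dtype(dtype).itemsize
    b = fh.read(nbytes)
    if len(b) != nbytes:
        raise FormatError("truncated index file")
    return np.frombuffer(b, dtype=dtype).copy()


def save_index(index, path) -> None:
    """Serialize a DatabaseIndex (or a single BlockIndex) to a binary file."""
    if isinstance(index, BlockIndex):
        index = DatabaseIndex(
            index.w, index.threshold, index.matrix_name, 0, [index]
        )
    with open(path, "wb") as fh:
        fh.write(_IX_MAGIC)
        name = index.matrix_name.encode("utf-8")
        fh.write(
            struct.pack(
                "<HBdH", _IX_VERSION, index.w, float(index.threshold), len(name)
            )
        )
        fh.write(name)
        fh.write(struct.pack("<QI", index.block_cap, len(index.blocks)))
        for b in index.blocks:
            fh.write(struct.pack("<IIQI", b.block_id, b.n_sequences, b.letters, b.max_seq_length))
            _write_arr(fh, b.entry_starts, "<i8")
            _write_arr(fh, b.deltas, "u1")
            _write_arr(fh, b.counts, "u1")
            _write_arr(fh, b.seq_id_stream, "<u4")


def load_index(path) -> DatabaseIndex:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _IX_MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}, expected {_IX_MAGIC!r}")
        hdr = fh.read(13)
        if len(hdr) != 13:
            raise FormatError(f"{path}: truncated header")
        version, w, threshold, name_len = struct.unpack("<HBdH", hdr)
        if version != _IX_VERSION:
            raise FormatError(f"{path}: version {version}, expected {_IX_VERSION}")
        matrix_name = fh.read(name_len).decode("utf-8")
        block_cap, n_blocks = struct.unpack("<QI", fh.read(12))
        blocks = []
        for _ in range(n_blocks):
            raw = fh.read(20)
            if len(raw) != 20:
                raise FormatError(f"{path}: truncated block header")
            block_id, n_seq, letters, max_len = struct.unpack("<IIQI", raw)
            entry_starts = _read_arr(fh, "<i8")
            deltas = _read_arr(fh, "u1")
            counts = _read_arr(fh, "u1")
            stream = _read_arr(fh, "<u4")
            blocks.append(
                BlockIndex(
                    block_id, w, threshold, matrix_name, n_seq, int(letters), max_len,
                    entry_starts, deltas, counts, stream,
                )
            )
    return DatabaseIndex(w, threshold, matrix_name, int(block_cap), blocks)
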