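"""Database preparation: FASTA reading, length sorting, block partitioning.

The search engine never works on a raw FASTA file: the database is first
encoded, sorted by sequence length (ascending, stable) and partitioned
into letter-capped blocks.  Sorting lets short blocks use narrow subject
offsets, and blocking bounds the per-block sequence-id width and keeps
each block's index cache-sized; results are reported with the original
accessions through the recorded id map.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field

import numpy as np

from . import alphabet
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_CAP = 131072  # 128 K letters

_DB_MAGIC = b"IBDB"
_DB_VERSION = 1


@dataclass
class ProteinSequence:
    accession: str
    description: str
    residues: np.ndarray = field(repr=False)  # uint8 codes, mask = 20

    def __post_init__(self):
        if len(self.residues) < 1:
            raise InputError(f"sequence {self.accession!r} is empty")

    @classmethod
    def from_string(cls, accession: str, seq: str, description: str = "") -> "ProteinSequence":
        return cls(accession, description, alphabet.encode(seq))

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def seq(self) -> str:
        return alphabet.decode(self.residues)

    def __eq__(self, other):
        return (
            isinstance(other, ProteinSequence)
            and self.accession == other.accession
            and self.description == other.description
            and np.array_equal(self.residues, other.residues)
        )


@dataclass
class SortedDatabase:
    """Length-sorted database plus the bijection back to input order."""

    sequences: list  # ProteinSequence, non-decreasing length
    sorted_to_orig: np.ndarray  # sorted position -> original position
    orig_to_sorted: np.ndarray

    @property
    def total_letters(self) -> int:
        return int(sum(s.length for s in self.sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def save(self, path) -> None:
        save_database(self.sequences, path, sorted_to_orig=self.sorted_to_orig)

    @classmethod
    def load(cls, path) -> "SortedDatabase":
        seqs, s2o = load_database(path)
        if s2o is None:
            raise FormatError(f"{path}: not a sorted database (run sortdb first)")
        o2s = np.empty_like(s2o)
        o2s[s2o] = np.arange(len(s2o))
        return cls(seqs, s2o, o2s)


@dataclass
class DatabaseBlock:
    """Contiguous slice of a SortedDatabase; no sequence spans two blocks."""

    block_id: int
    sequences: list
    global_start: int  # sorted-global id of local sequence 0

    @property
    def letters(self) -> int:
        return int(sum(s.length for s in self.sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def max_seq_length(self) -> int:
        return max(s.length for s in self.sequences)

    def local_to_global(self, local_id: int) -> int:
        return self.global_start + local_id


def read_fasta(path) -> list:
    """Read a protein FASTA file into encoded sequences.

    Residues are uppercased; characters outside the alphabet are masked
    with a logged warning.  An empty file or sequence data before the
    first header is an error.
    """
    with open(path, "rt") as fh:
        text = fh.read()
    seqs: list = []
    acc = None
    desc = ""
    chunks: list = []
    n_masked = 0
    saw_any = False

    def _flush(line_no):
        nonlocal n_masked
        if acc is None:
            return
        s = "".join(chunks)
        if not s:
            raise InputError(f"{path}: record {acc!r} has no sequence (line {line_no})")
        n_masked += alphabet.count_nonstandard(s)
        seqs.append(ProteinSequence.from_string(acc, s, desc))

    for line_no, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush(line_no)
            header = line[1:].split(None, 1)
            if not header:
                raise InputError(f"{path}: empty FASTA header at line {line_no}")
            acc = header[0]
            desc = header[1] if len(header) > 1 else ""
            chunks = []
            saw_any = True
        else:
            if not saw_any:
                raise InputError(
                    f"{path}: sequence data before first '>' header at line {line_no}"
                )
            chunks.append(line)
    _flush(line_no="EOF")
    if not seqs:
        raise InputError(f"{path}: empty FASTA file")
    if n_masked:
        logger.warning(
            "%s: %d non-alphabet character(s) masked to %s", path, n_masked, alphabet.MASK_CHAR
        )
    return seqs


def write_fasta(seqs, path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for s in seqs:
            header = f">{s.accession}"
            if s.description:
                header += f" {s.description}"
            fh.write(header + "\n")
            txt = s.seq
            for i in range(0, len(txt), width):
                fh.write(txt[i : i + width] + "\n")


def sort_database(seqs) -> SortedDatabase:
    """Stable ascending length sort; records the original-order bijection."""
    if not seqs:
        raise InputError("cannot sort an empty database")
    order = np.argsort([s.length for s in seqs], kind="stable")
    o2s = np.empty(len(seqs), dtype=np.uint32)
    o2s[order] = np.arange(len(seqs), dtype=np.uint32)
    return SortedDatabase(
        sequences=[seqs[i] for i in order],
        sorted_to_orig=order.astype(np.uint32),
        orig_to_sorted=o2s,
    )


def partition_blocks(db: SortedDatabase, block_cap: int = DEFAULT_BLOCK_CAP) -> list:
    """Greedy letter-capped partition of the sorted database.

    A sequence that would overflow the current block starts the next one;
    a single sequence longer than the cap occupies a block by itself.
    """
    if block_cap < 1:
        raise InputError(f"block_cap must be >= 1, got {block_cap}")
    blocks: list = []
    cur: list = []
    cur_letters = 0
    start = 0
    for i, s in enumerate(db.sequences):
        if cur and cur_letters + s.length > block_cap:
            blocks.append(DatabaseBlock(len(blocks), cur, start))
            start = i
            cur = []
            cur_letters = 0
        cur.append(s)
        cur_letters += s.length
    blocks.append(DatabaseBlock(len(blocks), cur, start))
    return blocks


def seq_id_bits(n_sequences: int) -> int:
    """Bits needed to address ``n_sequences`` distinct sequence ids."""
    if n_sequences < 1:
        raise InputError("need at least one sequence")
    return max(1, int(np.ceil(np.log2(n_sequences))))


# -- formatted database file (the formatdb/sortdb stages) --------------------


def _write_str(fh, s: str) -> None:
    b = s.encode("utf-8")
    fh.write(struct.pack("<I", len(b)))
    fh.write(b)


def _read_str(fh) -> str:
    (n,) = struct.unpack("<I", _read_exact(fh, 4))
    return _read_exact(fh, n).decode("utf-8")


def _read_exact(fh, n: int) -> bytes:
    b = fh.read(n)
    if len(b) != n:
        raise FormatError("truncated database file")
    return b


def save_database(seqs, path, sorted_to_orig=None) -> None:
    """Write the binary formatted-database file (little-endian, versioned)."""
    flags = 1 if sorted_to_orig is not None else 0
    with open(path, "wb") as fh:
        fh.write(_DB_MAGIC)
        fh.write(struct.pack("<HHI", _DB_VERSION, flags, len(seqs)))
        lengths = np.array([s.length for s in seqs], dtype=np.uint32)
        fh.write(lengths.tobytes())
        if sorted_to_orig is not None:
            fh.write(np.asarray(sorted_to_orig, dtype=np.uint32).tobytes())
        for s in seqs:
            fh.write(s.residues.astype(np.uint8).tobytes())
        for s in seqs:
            _write_str(fh, s.accession)
            _write_str(fh, s.description)


def load_database(path):
    """Inverse of :func:`save_database` -> (sequences, sorted_to_orig | None)."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _DB_MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}, expected {_DB_MAGIC!r}")
        version, flags, n = struct.unpack("<HHI", _read_exact(fh, 8))
        if version != _DB_VERSION:
            raise FormatError(f"{path}: version {version}, expected {_DB_VERSION}")
        lengths = np.frombuffer(_read_exact(fh, 4 * n), dtype="<u4")
        s2o = None
        if flags & 1:
            s2o = np.frombuffer(_read_exact(fh, 4 * n), dtype="<u4").copy()
        residues = [
            np.frombuffer(_read_exact(fh, int(L)), dtype=np.uint8).copy() for L in lengths
        ]
        seqs = []
        for r in residues:
            acc = _read_str(fh)
            desc = _read_str(fh)
            seqs.append(ProteinSequence(acc, desc, r))
    return seqs, s2o
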