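"""Residue alphabet and integer encoding.

Only the 20 canonical amino acids receive word-indexable codes (0..19, in
the conventional substitution-matrix row order).  Ambiguity and
non-standard letters (X, B, Z, U, J, O, the stop ``*``) and anything else
map to a single mask code that never participates in an indexed word.
"""

from __future__ import annotations

import numpy as np

RESIDUES = "ARNDCQEGHILKMFPSTWYV"
ALPHABET_SIZE = len(RESIDUES)
MASK_CODE = ALPHABET_SIZE  # 20
MASK_CHAR = "X"
#: letters that are legal FASTA content but are masked rather than indexed
AMBIGUITY_CHARS = "XBZUJO*"

_DECODE = RESIDUES + MASK_CHAR

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(RESIDUES):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i
for _ch in AMBIGUITY_CHARS:
    _CODE[ord(_ch)] = MASK_CODE
    _CODE[ord(_ch.lower())] = MASK_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to uint8 codes; unknown characters mask to 20."""
    raw = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    codes = np.where(codes == 255, np.uint8(MASK_CODE), codes)
    return codes.astype(np.uint8)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; every masked code renders as ``X``."""
    return "".join(_DECODE[c] for c in codes)


def count_nonstandard(seq: str) -> int:
    """Number of characters outside the 20-letter + ambiguity alphabet."""
    raw = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    return int((_CODE[raw] == 255).sum())
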