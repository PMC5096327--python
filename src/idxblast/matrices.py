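"""Substitution matrices over the internal 21-code alphabet (20 residues + mask).

Score tables come from Biopython's collection of the standard NCBI
matrices; arbitrary matrices in NCBI text format can be loaded from disk.
The mask code scores are taken from the matrix's own ``X`` column when
present, else a flat -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET_SIZE, MASK_CODE, RESIDUES
from .errors import InputError


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Integer substitution scores indexed by residue codes.

    ``scores`` is a (21, 21) symmetric int32 array; row/column 20 is the
    mask code.
    """

    name: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        s = self.scores
        if s.shape != (ALPHABET_SIZE + 1, ALPHABET_SIZE + 1):
            raise InputError(f"matrix {self.name}: bad shape {s.shape}")
        if not np.array_equal(s, s.T):
            raise InputError(f"matrix {self.name}: not symmetric")

    def score(self, a: int, b: int) -> int:
        return int(self.scores[a, b])

    @property
    def min_score(self) -> int:
        return int(self.scores.min())


def _from_biopython_array(name: str, arr) -> SubstitutionMatrix:
    alpha = arr.alphabet
    missing = [r for r in RESIDUES if r not in alpha]
    if missing:
        raise InputError(f"matrix {name} lacks residues {missing}")
    m = np.zeros((ALPHABET_SIZE + 1, ALPHABET_SIZE + 1), dtype=np.int32)
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            m[i, j] = int(arr[a, b])
    if "X" in alpha:
        for i, a in enumerate(RESIDUES):
            m[i, MASK_CODE] = m[MASK_CODE, i] = int(arr[a, "X"])
        m[MASK_CODE, MASK_CODE] = int(arr["X", "X"])
    else:
        m[MASK_CODE, :] = m[:, MASK_CODE] = -1
    return SubstitutionMatrix(name=name, scores=m)


@lru_cache(maxsize=None)
def load_matrix(name: str) -> SubstitutionMatrix:
    """Load one of the standard matrices (BLOSUM62, BLOSUM45, BLOSUM50, ...)."""
    try:
        arr = substitution_matrices.load(name.upper())
    except FileNotFoundError as exc:
        raise InputError(f"unknown substitution matrix {name!r}") from exc
    return _from_biopython_array(name.upper(), arr)


def read_matrix_file(path, name: str | None = None) -> SubstitutionMatrix:
    """Read a matrix in NCBI text format (e.g. the files ``blastp`` ships)."""
    arr = substitution_matrices.read(str(path))
    return _from_biopython_array(name or str(path), arr)
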