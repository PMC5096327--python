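"""Karlin-Altschul significance statistics.

Raw alignment scores are converted to bit scores and E-values with the
published NCBI constants for each (matrix, gap_open, gap_extend)
combination; the classical iterative length adjustment shrinks the query
and database lengths to an effective search space.  Composition-based
score adjustment is deliberately not implemented, so E-values follow the
standard Karlin-Altschul model rather than matching NCBI's
composition-adjusted output digit for digit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class KarlinParams:
    lam: float  # lambda, nats per raw score unit
    K: float
    H: float  # relative entropy, nats per aligned position

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise InputError("Karlin-Altschul lambda and K must be positive")


# Published NCBI constants: (matrix, None) = ungapped, else (gap_open, gap_extend).
_KA_TABLE = {
    ("BLOSUM62", None): KarlinParams(0.3176, 0.134, 0.4012),
    ("BLOSUM62", (11, 1)): KarlinParams(0.267, 0.041, 0.14),
    ("BLOSUM62", (12, 1)): KarlinParams(0.283, 0.059, 0.19),
    ("BLOSUM62", (13, 1)): KarlinParams(0.292, 0.071, 0.23),
    ("BLOSUM62", (10, 1)): KarlinParams(0.243, 0.024, 0.10),
    ("BLOSUM62", (9, 1)): KarlinParams(0.206, 0.010, 0.052),
    ("BLOSUM62", (11, 2)): KarlinParams(0.297, 0.082, 0.27),
    ("BLOSUM62", (10, 2)): KarlinParams(0.291, 0.075, 0.23),
    ("BLOSUM62", (9, 2)): KarlinParams(0.279, 0.058, 0.19),
    ("BLOSUM62", (8, 2)): KarlinParams(0.264, 0.045, 0.15),
    ("BLOSUM62", (7, 2)): KarlinParams(0.239, 0.027, 0.10),
    ("BLOSUM62", (6, 2)): KarlinParams(0.201, 0.021, 0.066),
    ("BLOSUM45", None): KarlinParams(0.2291, 0.0924, 0.2514),
    ("BLOSUM45", (14, 2)): KarlinParams(0.199, 0.040, 0.11),
    ("BLOSUM45", (15, 2)): KarlinParams(0.206, 0.049, 0.13),
    ("BLOSUM80", None): KarlinParams(0.3430, 0.177, 0.6568),
    ("BLOSUM80", (10, 1)): KarlinParams(0.299, 0.071, 0.27),
    ("BLOSUM80", (11, 1)): KarlinParams(0.314, 0.095, 0.35),
}


def karlin_params(matrix_name: str, gap_open: int | None = None, gap_extend: int | None = None) -> KarlinParams:
    """Look up constants; ``gap_open=None`` selects the ungapped set."""
    key = (matrix_name.upper(), None if gap_open is None else (int(gap_open), int(gap_extend)))
    try:
        return _KA_TABLE[key]
    except KeyError:
        raise InputError(
            f"no Karlin-Altschul constants for matrix {matrix_name} with gap "
            f"penalties {key[1]}; supported: "
            f"{sorted(str(k[1]) for k in _KA_TABLE if k[0] == matrix_name.upper())}"
        ) from None


def bit_score(raw: float, kp: KarlinParams) -> float:
    """(lambda * S - ln K) / ln 2."""
    return (kp.lam * raw - math.log(kp.K)) / math.log(2)


def raw_score_for_bits(bits: float, kp: KarlinParams) -> int:
    """Largest raw score whose bit score is <= ``bits`` ... rounded NCBI-style."""
    return int((bits * math.log(2) + math.log(kp.K)) / kp.lam)


def length_adjustment(kp: KarlinParams, query_len: int, db_letters: int, db_seqs: int) -> int:
    """Classical iterative edge-effect correction (expected HSP length)."""
    if query_len < 1 or db_letters < 1 or db_seqs < 1:
        raise InputError("lengths must be >= 1")
    ell = 0.0
    for _ in range(5):
        m_eff = max(query_len - ell, 1.0)
        n_eff = max(db_letters - db_seqs * ell, 1.0)
        ell = math.log(kp.K * m_eff * n_eff) / kp.H
        ell = max(ell, 0.0)
    ell = int(ell)
    # never shrink the query below 1/K (keeps the effective space positive)
    if query_len - ell < 1.0 / kp.K:
        ell = max(0, int(query_len - 1.0 / kp.K))
    return ell


def effective_search_space(
    kp: KarlinParams, query_len: int, db_letters: int, db_seqs: int,
    length_adjust: bool = True,
) -> float:
    ell = length_adjustment(kp, query_len, db_letters, db_seqs) if length_adjust else 0
    m_eff = max(query_len - ell, 1)
    n_eff = max(db_letters - db_seqs * ell, 1)
    return float(m_eff) * float(n_eff)


def evalue(
    raw: float,
    query_len: int,
    db_letters: int,
    db_seqs: int = 1,
    kp: KarlinParams | None = None,
    length_adjust: bool = True,
) -> float:
    """E = K * m' * n' * exp(-lambda * S) over the effective search space."""
    if kp is None:
        raise InputError("Karlin-Altschul parameters required")
    space = effective_search_space(kp, query_len, db_letters, db_seqs, length_adjust)
    return kp.K * space * math.exp(-kp.lam * raw)
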