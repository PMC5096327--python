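"""Synthetic protein databases with planted homologies.

Sequences are drawn i.i.d. from the Robinson-Robinson background
amino-acid composition with log-normally distributed lengths clipped to
the 60-1000 residue range typical of protein databases.  Homology is
planted by copying a segment from a donor sequence into a receiver after
mutating it to a requested percent identity (exact substitution count)
and applying indels at a requested rate; the ground truth (coordinates
and achieved identity) is emitted alongside.

What this emulates: realistic residue composition, realistic length
spread, and detectable local homology with known coordinates.  What it
does not: domain architecture, repeats, low-complexity regions, or
evolutionary substitution patterns (mutations are uniform over the 19
alternative residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import ALPHABET_SIZE, RESIDUES
from .db_prep import ProteinSequence
from .errors import InputError

#: Robinson-Robinson (1991) background frequencies, order ARNDCQEGHILKMFPSTWYV
ROBINSON_FREQS = np.array(
    [
        78.05, 51.29, 44.87, 53.64, 19.25, 42.64, 62.95, 73.77, 21.99, 51.42,
        90.19, 57.44, 22.43, 38.56, 52.03, 71.20, 58.41, 13.30, 32.16, 64.41,
    ]
)
ROBINSON_FREQS = ROBINSON_FREQS / ROBINSON_FREQS.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic database."""

    n_sequences: int = 500
    median_length: float = 250.0
    length_sigma: float = 0.55  # log-normal shape
    min_length: int = 60
    max_length: int = 1000
    n_planted: int = 20  # homolog pairs
    identity: float = 60.0  # percent, on the planted segment
    indel_rate: float = 0.02  # per-position event probability
    min_segment: int = 50
    max_segment: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.identity <= 100.0):
            raise InputError("identity must be in (0, 100]")
        if not (0.0 <= self.indel_rate <= 0.3):
            raise InputError("indel_rate must be in [0, 0.3]")
        if 2 * self.n_planted > self.n_sequences:
            raise InputError("need at least two sequences per planted pair")
        if self.min_segment < 10:
            raise InputError("planted segments must be at least 10 residues")
        # a 2% identity tolerance needs enough positions to hit the target
        if self.min_segment < 100.0 / max(100.0 - self.identity, 2.0):
            raise InputError("segment too short to realize the requested identity")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(ALPHABET_SIZE, size=length, p=ROBINSON_FREQS).astype(np.uint8)


def _mutate_segment(rng: np.random.Generator, seg: np.ndarray, identity: float, indel_rate: float):
    """Substitute an exact count of positions, then apply indels.

    Returns (mutated segment, n_substitutions, n_indel_events).
    """
    L = len(seg)
    n_sub = int(round((1.0 - identity / 100.0) * L))
    out = seg.copy()
    if n_sub:
        pos = rng.choice(L, size=n_sub, replace=False)
        shift = rng.integers(1, ALPHABET_SIZE, size=n_sub)
        out[pos] = (out[pos] + shift) % ALPHABET_SIZE
    pieces = []
    n_events = 0
    i = 0
    while i < L:
        if rng.random() < indel_rate:
            n_events += 1
            glen = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion into the mutated copy
                pieces.append(out[i : i + 1])
                pieces.append(_random_sequence(rng, glen))
                i += 1
            else:  # deletion from the mutated copy
                i += glen
        else:
            pieces.append(out[i : i + 1])
            i += 1
    mutated = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    if len(mutated) < 10:
        raise InputError("indel rate destroyed the planted segment")
    return mutated, n_sub, n_events


def generate_database(spec: SyntheticSpec):
    """Generate (sequences, truth table); deterministic under spec.seed.

    The truth table records, per planted pair, the donor/receiver
    accessions, the segment coordinates in both sequences, and the
    achieved identity of the planted (gap-free) columns.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.median_length)
    lengths = np.exp(rng.normal(mu, spec.length_sigma, size=spec.n_sequences))
    lengths = np.clip(np.round(lengths), spec.min_length, spec.max_length).astype(int)
    seqs = [
        ProteinSequence(f"syn{idx:05d}", "synthetic background", _random_sequence(rng, L))
        for idx, L in enumerate(lengths)
    ]
    chosen = rng.choice(spec.n_sequences, size=2 * spec.n_planted, replace=False)
    rows = []
    for k in range(spec.n_planted):
        donor_i, recv_i = int(chosen[2 * k]), int(chosen[2 * k + 1])
        donor, recv = seqs[donor_i], seqs[recv_i]
        # cap at half the receiver so indel expansion cannot overflow it
        seg_len = int(
            min(
                rng.integers(spec.min_segment, spec.max_segment + 1),
                donor.length,
                recv.length // 2,
            )
        )
        d_start = int(rng.integers(0, donor.length - seg_len + 1))
        seg = donor.residues[d_start : d_start + seg_len]
        mutated, n_sub, n_events = _mutate_segment(rng, seg, spec.identity, spec.indel_rate)
        if len(mutated) > recv.length:
            raise InputError(
                f"planted pair {k}: indel expansion exceeded the receiver length "
                f"(infeasible identity/indel combination)"
            )
        r_start = int(rng.integers(0, recv.length - len(mutated) + 1))
        new_res = recv.residues.copy()
        new_res[r_start : r_start + len(mutated)] = mutated
        seqs[recv_i] = ProteinSequence(recv.accession, "synthetic homolog", new_res)
        achieved = 100.0 * (seg_len - n_sub) / seg_len
        if abs(achieved - spec.identity) > 2.0:
            raise InputError(
                f"planted pair {k}: achieved identity {achieved:.1f}% is outside "
                f"the +/-2% tolerance of the requested {spec.identity}%"
            )
        rows.append(
            {
                "pair": k,
                "donor": donor.accession,
                "receiver": recv.accession,
                "donor_start": d_start,
                "donor_end": d_start + seg_len,
                "receiver_start": r_start,
                "receiver_end": r_start + len(mutated),
                "segment_length": seg_len,
                "n_substitutions": n_sub,
                "n_indel_events": n_events,
                "target_identity": spec.identity,
                "achieved_identity": achieved,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "pair", "donor", "receiver", "donor_start", "donor_end",
            "receiver_start", "receiver_end", "segment_length",
            "n_substitutions", "n_indel_events", "target_identity",
            "achieved_identity",
        ],
    )
    return seqs, truth


def generate_queries(
    rng_or_seed, n_queries: int, length: int = 200
) -> list:
    """Background-composition query sequences (no planted relationship)."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    return [
        ProteinSequence(f"query{t:03d}", "synthetic query", _random_sequence(rng, length))
        for t in range(n_queries)
    ]
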