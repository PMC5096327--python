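import numpy as np
import pytest

import idxblast as ib
from idxblast import oracles
from idxblast import search_core as sc
from idxblast.alphabet import encode
from idxblast.db_prep import DatabaseBlock, ProteinSequence
from idxblast.search_core import SearchParams
from idxblast.synth import SyntheticSpec, _random_sequence, generate_database


def one_block(seqs) -> DatabaseBlock:
    return DatabaseBlock(0, seqs, 0)


def indexed(seqs):
    block = one_block(seqs)
    return block, ib.build_block_index(block)


@pytest.fixture(scope="module")
def msub(default_params):
    return np.asarray(default_params.matrix.scores, dtype=np.int64)


class TestDetectHits:
    def test_unindexable_query_yields_no_hits(self, default_params):
        block, bi = indexed([ProteinSequence.from_string("s0", "ARNDCQ")])
        q = ProteinSequence.from_string("q", "XXXXXX")
        assert sc.detect_hits(q, bi, default_params).n_hits == 0

    def test_exact_self_hit_on_diagonal_zero(self):
        params = SearchParams(neighbor_threshold=float("inf"))
        block = one_block([ProteinSequence.from_string("s0", "ARN")])
        bi = ib.build_block_index(block, threshold=float("inf"))
        q = ProteinSequence.from_string("q", "ARN")
        flb = sc.detect_hits(q, bi, params)
        assert flb.n_hits == 1
        assert flb.bin(0) == [(0, 0)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadratic_scan(self, seed, default_params):
        rng = np.random.default_rng(seed)
        seqs = [
            ProteinSequence(f"s{i}", "", _random_sequence(rng, int(rng.integers(10, 120))))
            for i in range(12)
        ]
        block, bi = indexed(seqs)
        q = ProteinSequence("q", "", _random_sequence(rng, 70))
        flb = sc.detect_hits(q, bi, default_params)
        oracle = []
        for sid, s in enumerate(seqs):
            oracle.extend(
                (p, sid, o) for (p, o) in oracles.quadratic_hits(q, s, default_params)
            )
        assert flb.hit_multiset() == sorted(oracle)

    def test_neighbor_indirection_equals_materialized_index(self, default_params):
        """Walking neighbor posting lists visits exactly the positions a
        materialized-neighbor index would store for the query word."""
        rng = np.random.default_rng(3)
        seqs = [
            ProteinSequence(f"s{i}", "", _random_sequence(rng, 60)) for i in range(6)
        ]
        block, bi = indexed(seqs)
        pos = ib.decode_block(bi)
        table = ib.build_neighbor_table("BLOSUM62", 11)
        m = default_params.matrix
        for wid in rng.integers(0, 20**3, size=5):
            wid = int(wid)
            visited = []
            for v in [wid, *table.neighbors(wid).tolist()]:
                lo, hi = int(pos.starts[v]), int(pos.starts[v + 1])
                visited.extend(zip(pos.seq_ids[lo:hi].tolist(), pos.offsets[lo:hi].tolist()))
            # materialized: scan every window of every sequence, keep scoring ones
            materialized = []
            q = ib.indexer.id_to_word(wid)
            for sid, s in enumerate(seqs):
                for o in range(s.length - 2):
                    wcodes = s.residues[o : o + 3]
                    if (wcodes >= 20).any():
                        continue
                    if np.array_equal(wcodes, q) or int(m.scores[q, wcodes].sum()) >= 11:
                        materialized.append((sid, o))
            assert sorted(visited) == sorted(materialized)


class TestBinAndFilter:
    def _bins(self, hits, qlen=50):
        """Build FirstLevelBins from (seq, offset, diagonal) triples in scan order."""
        diag = np.array([h[2] for h in hits], dtype=np.int64)
        order = np.argsort(diag, kind="stable")
        return sc.FirstLevelBins(
            qlen,
            diag[order],
            np.array([h[0] for h in hits], dtype=np.int64)[order],
            np.array([h[1] for h in hits], dtype=np.int64)[order],
        )

    def test_single_hit_never_triggers(self, default_params):
        slb = sc.bin_and_filter(self._bins([(0, 10, 2), (1, 12, 4)]), default_params)
        assert slb.n_triggers == 0

    def test_window_arithmetic(self):
        params = SearchParams(threshold_a=40, overlap=3)
        slb = sc.bin_and_filter(self._bins([(0, 10, 0), (0, 20, 0)]), params)
        assert slb.pair_set() == {(0, 0, 10, 20)}

    def test_too_close_or_too_far_rejected(self):
        params = SearchParams(threshold_a=40, overlap=3)
        slb = sc.bin_and_filter(
            self._bins([(0, 10, 0), (0, 11, 0), (0, 80, 0)]), params
        )
        assert slb.n_triggers == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_classical_last_hit_scan(self, seed, default_params):
        rng = np.random.default_rng(seed)
        seqs = [
            ProteinSequence(f"s{i}", "", _random_sequence(rng, int(rng.integers(30, 150))))
            for i in range(10)
        ]
        block, bi = indexed(seqs)
        q = ProteinSequence("q", "", _random_sequence(rng, 80))
        slb = sc.bin_and_filter(sc.detect_hits(q, bi, default_params), default_params)
        oracle = set()
        for sid, s in enumerate(seqs):
            for d, o1, o2 in oracles.classical_two_hit_pairs(q, s, default_params):
                oracle.add((sid, d, o1, o2))
        assert slb.pair_set() == oracle


class TestUngappedExtend:
    def test_perfect_match_spans_sequence(self, default_params, msub):
        rng = np.random.default_rng(0)
        a = _random_sequence(rng, 40)
        score, qs, qe, ss, se = sc.ungapped_extend(a, a, 15, 15, default_params, msub)
        assert (qs, qe, ss, se) == (0, 40, 0, 40)
        assert score == int(msub[a, a].sum())

    def test_zero_xdrop_confines_to_seed_word(self, default_params, msub):
        q = encode("CCCWWWCCC")
        s = encode("AAAWWWAAA")  # C-A flanks score -0 < 0? (C,A)=0; use different
        q = encode("WWWHHHWWW")
        s = encode("CCCHHHCCC")  # W-C = -2 on both flanks
        score, qs, qe, ss, se = sc.ungapped_extend(q, s, 3, 3, default_params, msub, x_drop=0)
        assert (qs, qe, ss, se) == (3, 6, 3, 6)
        assert score == int(msub[encode("HHH"), encode("HHH")].sum())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_infinite_xdrop_matches_exhaustive_diagonal_scan(self, seed, default_params, msub):
        rng = np.random.default_rng(seed)
        L = 60
        q = _random_sequence(rng, L)
        s = q.copy()
        mut = rng.choice(L, size=20, replace=False)
        s[mut] = (s[mut] + rng.integers(1, 20, size=20)) % 20
        q0 = s0 = 30
        inf_score, qs, qe, ss, se = sc.ungapped_extend(
            q, s, q0, s0, default_params, msub, x_drop=float("inf")
        )
        # oracle: best contiguous diagonal segment containing the seed word
        v = msub[q, s]
        best = -(10**9)
        for a in range(0, q0 + 1):
            for b in range(q0 + 3, L + 1):
                best = max(best, int(v[a:b].sum()))
        assert inf_score == best
        fin_score, *_ = sc.ungapped_extend(q, s, q0, s0, default_params, msub)
        assert fin_score <= inf_score
        # the segment re-scores to its reported score and has equal-length axes
        assert (qe - qs) == (se - ss)
        assert int(v[qs:qe].sum()) == inf_score


class TestGappedExtend:
    def test_exact_duplicate_full_identity(self, default_params, msub):
        rng = np.random.default_rng(1)
        a = _random_sequence(rng, 80)
        hsp = sc.HSP(0, 30, 40, 30, 40, int(msub[a[30:40], a[30:40]].sum()))
        score, qs, qe, ss, se, ops = sc.gapped_extend(a, a, hsp, default_params, msub)
        assert ops == "M" * 80
        assert (qs, qe, ss, se) == (0, 80, 0, 80)
        assert score == int(msub[a, a].sum())

    def test_planted_insertion_recovered(self, default_params, msub):
        rng = np.random.default_rng(2)
        a = _random_sequence(rng, 60)
        b = np.concatenate([a[:30], _random_sequence(rng, 2), a[30:]])
        hsp = sc.HSP(0, 5, 15, 5, 15, 0)
        score, qs, qe, ss, se, ops = sc.gapped_extend(
            a, b, hsp, default_params, msub, x_drop=float("inf")
        )
        assert ops.count("D") == 2 and ops.count("I") == 0
        assert "DD" in ops
        sw = oracles.sw_local(a, b, msub, 11, 1)
        assert score == sw[0]

    @pytest.mark.parametrize("seed", range(6))
    def test_bounded_by_smith_waterman(self, seed, default_params, msub):
        rng = np.random.default_rng(seed)
        L = 90
        a = _random_sequence(rng, L)
        b = a.copy()
        mut = rng.choice(L, size=int(0.35 * L), replace=False)
        b[mut] = (b[mut] + rng.integers(1, 20, size=len(mut))) % 20
        hsp = sc.HSP(0, 40, 43, 40, 43, 0)
        sw_score = oracles.sw_local(a, b, msub, 11, 1)[0]
        fin, *_ = sc.gapped_extend(a, b, hsp, default_params, msub)
        inf_score, qs, qe, ss, se, ops = sc.gapped_extend(
            a, b, hsp, default_params, msub, x_drop=float("inf")
        )
        assert fin <= inf_score <= sw_score
        assert sc.rescore_ops(a, b, qs, ss, ops, default_params) == inf_score

    def test_traceback_rescores_with_finite_xdrop(self, default_params, msub):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = _random_sequence(rng, 70)
            b = a.copy()
            mut = rng.choice(70, size=25, replace=False)
            b[mut] = (b[mut] + rng.integers(1, 20, size=25)) % 20
            hsp = sc.HSP(0, 30, 33, 30, 33, 0)
            score, qs, qe, ss, se, ops = sc.gapped_extend(a, b, hsp, default_params, msub)
            assert sc.rescore_ops(a, b, qs, ss, ops, default_params) == score


class TestSearchBlock:
    def test_no_homologs_above_cutoff(self):
        params = SearchParams(evalue_cutoff=1e-6)
        rng = np.random.default_rng(4)
        seqs = [
            ProteinSequence(f"s{i}", "", _random_sequence(rng, 100)) for i in range(10)
        ]
        block, bi = indexed(seqs)
        q = ProteinSequence("q", "", _random_sequence(rng, 80))
        assert sc.search_block(q, block, bi, params) == []

    def test_planted_homolog_found(self, small_indexed):
        db, blocks, index, truth = small_indexed
        params = SearchParams(evalue_cutoff=1e-3)
        for _, row in truth.iterrows():
            query = next(s for s in db.sequences if s.accession == row.donor)
            alns = sc.search_block(
                query, blocks[0], index.blocks[0], params,
                db.total_letters, db.n_sequences,
            )
            assert row.receiver in {a.accession for a in alns}

    def test_query_shorter_than_word_is_empty(self, small_indexed, default_params):
        db, blocks, index, _ = small_indexed
        q = ProteinSequence.from_string("tiny", "MK")
        assert sc.search_block(q, blocks[0], index.blocks[0], default_params) == []

    def test_partition_invariance(self, small_planted, default_params):
        seqs, truth = small_planted
        db = ib.sort_database(seqs)
        query = next(s for s in seqs if s.accession == truth.donor[0])
        results = []
        for cap in (500, 2000, 10**6):
            blocks = ib.partition_blocks(db, cap)
            index = ib.build_database_index(blocks, block_cap=cap)
            alns = []
            for blk, bidx in zip(blocks, index.blocks):
                alns.extend(
                    sc.search_block(
                        query, blk, bidx, default_params,
                        db.total_letters, db.n_sequences,
                    )
                )
            results.append(sorted(a.key() for a in alns))
        assert results[0] == results[1] == results[2]
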