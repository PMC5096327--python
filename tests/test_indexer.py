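import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import idxblast as ib
from idxblast import indexer as ix
from idxblast.alphabet import encode
from idxblast.db_prep import DatabaseBlock, ProteinSequence
from idxblast.errors import FormatError, InputError
from idxblast.matrices import load_matrix
from idxblast.synth import _random_sequence


def block_of(*seqs) -> DatabaseBlock:
    return DatabaseBlock(
        0, [ProteinSequence.from_string(f"s{i}", s) for i, s in enumerate(seqs)], 0
    )


def random_block(rng, n=10, max_len=80, with_mask=False) -> DatabaseBlock:
    seqs = []
    for i in range(n):
        codes = _random_sequence(rng, int(rng.integers(1, max_len)))
        if with_mask and len(codes) > 4 and rng.random() < 0.5:
            codes[rng.integers(0, len(codes))] = 20
        seqs.append(ProteinSequence(f"s{i}", "", codes))
    return DatabaseBlock(0, seqs, 0)


class TestBasicIndex:
    def test_single_word(self):
        idx = ib.build_basic_index(block_of("ARN"), 3)
        wid = ix.word_to_id(encode("ARN"))
        assert idx.positions(wid) == [(0, 0)]
        assert idx.n_positions == 1

    def test_overlapping_words(self):
        idx = ib.build_basic_index(block_of("ARAR"), 3)
        assert idx.positions(ix.word_to_id(encode("ARA"))) == [(0, 0)]
        assert idx.positions(ix.word_to_id(encode("RAR"))) == [(0, 1)]

    def test_masked_windows_skipped(self):
        idx = ib.build_basic_index(block_of("ARXRA"), 3)
        assert idx.n_positions == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_position_counting(self, seed):
        rng = np.random.default_rng(seed)
        block = random_block(rng, with_mask=True)
        idx = ib.build_basic_index(block, 3)
        expected = 0
        for s in block.sequences:
            win = np.lib.stride_tricks.sliding_window_view(s.residues, 3) if s.length >= 3 else None
            if win is not None:
                expected += int((win < 20).all(axis=1).sum())
        assert idx.n_positions == expected


class TestSortPositions:
    def test_key_order(self):
        # positions (seq, offset): order by offset then seq
        block = block_of("M" * 8, "M" * 8, "M" * 8, "M" * 8)
        idx = ib.build_basic_index(block, 3)
        srt = ib.sort_positions(idx)
        wid = ix.word_to_id(encode("MMM"))
        pos = srt.positions(wid)
        assert pos == sorted(pos, key=lambda t: (t[1], t[0]))

    def test_idempotent_and_permutation(self):
        rng = np.random.default_rng(2)
        idx = ib.build_basic_index(random_block(rng), 3)
        s1 = ib.sort_positions(idx)
        s2 = ib.sort_positions(s1)
        for wid in idx.nonempty_words():
            assert s1.positions(int(wid)) == s2.positions(int(wid))
            assert sorted(s1.positions(int(wid))) == sorted(idx.positions(int(wid)))
            offs = [o for _, o in s1.positions(int(wid))]
            assert offs == sorted(offs)


# positions sorted by (offset, seq_id), unique pairs
sorted_positions = st.lists(
    st.tuples(st.integers(0, 2000), st.integers(0, 600)), max_size=60, unique=True
).map(lambda ps: sorted(ps, key=lambda t: (t[1], t[0])))


class TestCompression:
    def test_merge_same_offset(self):
        # one word at position 0 of sequences 1 and 3 -> single merged entry
        entries = ib.compress_positions([(1, 0), (3, 0)])
        assert entries == [ix.CompressedEntry(0, 2, (1, 3))]

    def test_delta_arithmetic(self):
        entries = ib.compress_positions([(0, 2), (1, 5), (2, 5)])
        assert entries == [
            ix.CompressedEntry(2, 1, (0,)),
            ix.CompressedEntry(3, 2, (1, 2)),
        ]

    def test_unsorted_input_is_error(self):
        with pytest.raises(InputError, match="sorted"):
            ib.compress_positions([(0, 5), (0, 2)])

    @settings(max_examples=200, deadline=None)
    @given(sorted_positions)
    def test_round_trip(self, positions):
        entries = ib.compress_positions(positions)
        assert all(e.delta_offset <= 255 and e.count <= 255 for e in entries)
        assert ib.decode_positions(entries) == positions

    @settings(max_examples=100, deadline=None)
    @given(sorted_positions)
    def test_canonical_form_fixed_point(self, positions):
        entries = ib.compress_positions(positions)
        again = ib.compress_positions(ib.decode_positions(entries))
        assert again == entries


class TestSplitOverflow:
    def test_offset_overflow(self):
        ids = tuple(range(25))
        assert ib.split_overflow(300, 25, ids) == [
            ix.CompressedEntry(255, 0),
            ix.CompressedEntry(45, 25, ids),
        ]

    def test_count_overflow(self):
        ids = tuple(range(300))
        assert ib.split_overflow(2, 300, ids) == [
            ix.CompressedEntry(2, 255, ids[:255]),
            ix.CompressedEntry(0, 45, ids[255:]),
        ]

    def test_repeated_offset_padding(self):
        out = ib.split_overflow(600, 1, (7,))
        assert [(e.delta_offset, e.count) for e in out] == [(255, 0), (255, 0), (90, 1)]
        assert ib.decode_positions(out) == [(7, 600)]

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 3000), st.lists(st.integers(0, 10**6), max_size=600))
    def test_decode_oracle(self, delta, ids):
        entries = ib.split_overflow(delta, len(ids), ids)
        assert all(e.delta_offset <= 255 and e.count <= 255 for e in entries)
        decoded = ib.decode_positions(entries)
        assert decoded == [(i, delta) for i in ids]

    def test_decode_rejects_wrong_id_count(self):
        bad = ix.CompressedEntry.__new__(ix.CompressedEntry)
        object.__setattr__(bad, "delta_offset", 1)
        object.__setattr__(bad, "count", 2)
        object.__setattr__(bad, "seq_ids", (1,))
        with pytest.raises(InputError, match="count"):
            ib.decode_positions([bad])

    def test_decode_empty(self):
        assert ib.decode_positions([]) == []


class TestNeighborWords:
    def test_infinite_threshold_empty(self):
        m = load_matrix("BLOSUM62")
        assert len(ib.compute_neighbor_words(0, m, float("inf"))) == 0

    def test_minus_infinite_threshold_exhaustive(self):
        m = load_matrix("BLOSUM62")
        nb = ib.compute_neighbor_words(0, m, -(10**9))
        assert len(nb) == 20**3 - 1

    def test_brute_force_oracle_pqg(self):
        m = load_matrix("BLOSUM62")
        wid = ix.word_to_id(encode("PQG"))
        expected = []
        q = encode("PQG")
        for x in range(20**3):
            codes = ix.id_to_word(x)
            score = sum(int(m.scores[a, b]) for a, b in zip(q, codes))
            if score >= 13 and x != wid:
                expected.append(x)
        assert list(ib.compute_neighbor_words(wid, m, 13)) == expected

    def test_table_matches_per_word(self):
        m = load_matrix("BLOSUM62")
        table = ib.build_neighbor_table("BLOSUM62", 11)
        rng = np.random.default_rng(0)
        for wid in rng.integers(0, 20**3, size=10):
            assert np.array_equal(
                table.neighbors(int(wid)), ib.compute_neighbor_words(int(wid), m, 11)
            )
            assert int(wid) not in table.neighbors(int(wid)).tolist()


class TestBlockIndex:
    def test_all_short_sequences(self):
        bi = ib.build_block_index(block_of("MK", "A"))
        assert len(bi.deltas) == 0
        pos = ib.decode_block(bi)
        assert (np.diff(pos.starts) == 0).all()

    def test_toy_merged_entry(self):
        # the same word at offset 0 of sequences 1 and 3 merges into one entry
        bi = ib.build_block_index(block_of("WWWWW", "ARNDC", "YYYYY", "ARNKM"))
        wid = ix.word_to_id(encode("ARN"))
        assert bi.word_entries(wid) == [ix.CompressedEntry(0, 2, (1, 3))]

    @pytest.mark.parametrize("seed", [0, 7])
    def test_lossless_against_sorted_basic(self, seed):
        rng = np.random.default_rng(seed)
        block = random_block(rng, n=25, max_len=120, with_mask=True)
        basic = ib.sort_positions(ib.build_basic_index(block, 3))
        bi = ib.build_block_index(block)
        pos = ib.decode_block(bi)
        assert int(pos.starts[-1]) == basic.n_positions
        for wid in basic.nonempty_words():
            lo, hi = int(pos.starts[wid]), int(pos.starts[wid + 1])
            decoded = list(zip(pos.seq_ids[lo:hi].tolist(), pos.offsets[lo:hi].tolist()))
            assert decoded == basic.positions(int(wid))
            assert decoded == ib.decode_positions(bi.word_entries(int(wid)))

    def test_deterministic_build(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        b1 = ib.build_block_index(random_block(rng1))
        b2 = ib.build_block_index(random_block(rng2))
        assert b1.equals(b2)


class TestSerialization:
    def test_round_trip_and_byte_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        seqs = [
            ProteinSequence(f"s{i}", "", _random_sequence(rng, int(rng.integers(10, 80))))
            for i in range(1000)
        ]
        db = ib.sort_database(seqs)
        index = ib.build_database_index(ib.partition_blocks(db, 8000), block_cap=8000)
        p1, p2 = tmp_path / "a.idx", tmp_path / "b.idx"
        index.save(p1)
        loaded = ib.load_index(p1)
        assert loaded.w == index.w and loaded.matrix_name == index.matrix_name
        assert all(a.equals(b) for a, b in zip(index.blocks, loaded.blocks))
        loaded.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_block_api(self, tmp_path):
        bi = ib.build_block_index(block_of("ARNDCQEGH"))
        p = tmp_path / "one.idx"
        ib.save_index(bi, p)
        loaded = ib.load_index(p)
        assert len(loaded.blocks) == 1
        assert loaded.blocks[0].equals(bi)

    def test_bad_magic(self, tmp_path):
        p = tmp_path / "x.idx"
        p.write_bytes(b"WHAT" + b"\x00" * 64)
        with pytest.raises(FormatError, match="IBIX"):
            ib.load_index(p)

    def test_truncated_file(self, tmp_path):
        bi = ib.build_block_index(block_of("ARNDCQEGH"))
        p = tmp_path / "one.idx"
        ib.save_index(bi, p)
        p.write_bytes(p.read_bytes()[:-30])
        with pytest.raises(FormatError, match="truncated"):
            ib.load_index(p)
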