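"""The compressed index stream: merge, increment and overflow splitting.

Positions sharing a subject offset merge into one entry; offsets become
8-bit increments; increments or counts above 255 split across entries.
"""

from idxblast import compress_positions, decode_positions, split_overflow

# word positions (sequence id, subject offset), sorted by offset
positions = [(1, 0), (3, 0), (0, 2), (2, 5), (5, 5)]
entries = compress_positions(positions)
for e in entries:
    print(f"delta={e.delta_offset:<3} count={e.count} ids={list(e.seq_ids)}")
assert decode_positions(entries) == positions

print()
print("offset increment 300 with 25 positions splits into:")
for e in split_overflow(300, 25, tuple(range(25))):
    print(f"  delta={e.delta_offset:<3} count={e.count}")
print("300 positions at increment 2 split into:")
for e in split_overflow(2, 300, tuple(range(300))):
    print(f"  delta={e.delta_offset:<3} count={e.count}")
# Every stored field fits in 8 bits; decoding recovers the exact
# (id, offset) list, so the compression is lossless.
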