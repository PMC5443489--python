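"""Per-cytosine methylation calling from a toy bisulfite pileup.

Three read pairs and two single reads over one CpG show the counting
rules: C/T tallying, single-counting of overlapping mates, context
classification and the CT > 10 reliability filter.
"""

from glycometh.wgbs import (
    AlignedReadRecord,
    calls_to_frame,
    classify_context,
    count_calls,
    filter_reliable,
)

reference = "TACGTTACAGTA"        # CpG at position 3 (+) / 4 (-), CHG at 8

reads = [
    # pair p1: both mates cover position 3 -> counted once (mate 1's C)
    AlignedReadRecord("p1", 1, "chr", "+", {3: "C"}),
    AlignedReadRecord("p1", 2, "chr", "+", {3: "T"}),
    AlignedReadRecord("p2", 1, "chr", "+", {3: "C"}),
    AlignedReadRecord("p3", 1, "chr", "+", {3: "T"}),
    AlignedReadRecord("s1", 1, "chr", "+", {3: "C", 8: "T"}),
    AlignedReadRecord("s2", 1, "chr", "+", {3: "C", 8: "T"}),
]

calls = count_calls(reads, reference)
print("Calls from the toy pileup:")
print(calls_to_frame(calls).to_string(index=False))
print()
print("Context of position 3 (+):", classify_context(reference, 3, "+"))
print("Context of position 4 (-):", classify_context(reference, 4, "-"))
print("Context of position 8 (+):", classify_context(reference, 8, "+"))
print()
reliable = filter_reliable(calls)
print(f"Reliable calls (effective CT count > 10): {len(reliable)} of "
      f"{len(calls)} — the toy pileup is far below the threshold, so a")
print("real analysis would ignore these sites until coverage reaches 11+.")
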