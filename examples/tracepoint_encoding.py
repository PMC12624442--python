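"""Trace-point encoding: constant-size alignment storage and exact recovery.

Aligns a 10 kb sequence against a 20%-divergent copy, encodes the alignment
as per-panel B-lengths (one byte per 100 bp of A, regardless of divergence),
reconstructs the path from the trace points, and compares against the CIGAR
representation whose size grows with the difference count.  Finally shows
minimum-gap refinement tidying scattered indels.
"""

import numpy as np

from adaptalign.align import la_finder, AlignParams
from adaptalign.tracepoint import (
    count_gaps,
    decode_tracepoints,
    encode_tracepoints,
    path_to_cigar,
    refine_path,
)

rng = np.random.default_rng(11)
A = rng.integers(0, 4, 10_000, dtype=np.uint8)
B = list(A)
for _ in range(2000):  # ~20% divergence: 80/10/10 subs/ins/dels
    p = int(rng.integers(0, len(B)))
    r = rng.random()
    if r < 0.8:
        B[p] = int((B[p] + 1 + rng.integers(0, 3)) % 4)
    elif r < 0.9:
        B.insert(p, int(rng.integers(0, 4)))
    else:
        del B[p]
B = np.array(B, dtype=np.uint8)

alns, _ = la_finder(A, B, len(A), -128, 128, AlignParams(max_divergence=0.4))
aln = max(alns, key=lambda a: a.length)
print(f"alignment A[{aln.ab},{aln.ae}] x B[{aln.bb},{aln.be}], "
      f"{aln.diffs} diffs (eps = {aln.epsilon:.2f})")

tpa = encode_tracepoints(aln.path, aln.ab, aln.ae, aln.bb, aln.be, delta=100)
cigar = path_to_cigar(aln.path, A, B, aln.ab, aln.bb, "=X")
print(f"trace-point array: {tpa.panels} one-byte panel entries")
print(f"=X CIGAR string  : {len(cigar)} characters (grows with divergence)")

path, diffs = decode_tracepoints(tpa, aln.ab, aln.ae, aln.bb, aln.be, A, B)
print(f"decoded from trace points: {diffs} diffs "
      f"(<= encoded path: per-panel sub-alignments are optimal)")

refined = refine_path(path, aln.ab, aln.bb, A, B)
print(f"gap refinement: {count_gaps(path)} gaps -> {count_gaps(refined)} "
      f"(same endpoints, scattered indels fused at <=1 mismatch per gap saved)")
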