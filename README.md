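# adaptalign

Whole-genome local alignment with adaptive seeds, at desk scale.

`adaptalign` finds all statistically significant local alignments between two
genome sequences. It is built around the sort-and-merge architecture used by
modern cache-local aligners instead of per-position index lookups:

1. **Genome database** — each FASTA scaffold is split into contigs at runs of
   `N`, packed 2 bits/base.
2. **Genome index** — every K-mer (default K=40) of the genome *and its
   complement* whose first s=12 bases form a **closed (s,m) syncmer**
   (m=8) is recorded with a signed position and sorted by an in-place **MSD
   radix sort** that also emits the **lcp array** (longest common prefix of
   each record with its predecessor) as a side product — together a suffix
   array truncated at depth K. Syncmer subsampling keeps ~43% of positions
   while guaranteeing retained positions are never more than s−m apart.
3. **Adaptamer merge** — the two indices are merged in one linear sweep. For
   every K-mer of genome A the sweep maintains the range `[fst, lst)` of
   B-index records sharing the longest possible prefix `L`: the **adaptamer**
   (adaptive seed, 1/2-MEM) at each A position, with every matching B
   location. Ranges with more than τ (default 10) occurrences are repetitive
   and suppressed; `lst` is capped at `fst+τ+1` so the sweep stays linear.
4. **Chaining** — seed hits become sextuples
   `(c_i, c_j, ⌊(p_i−p_j)/D⌋, p_i+p_j, (p_i−p_j) mod D, t)`; after sorting,
   runs of seeds in adjacent diagonal bands (width D=64) with anti-diagonal
   gaps ≤ A=1000 form chains, each defining a rectangular **tube** of the
   alignment matrix.
5. **Wave alignment** — each tube is swept by a local aligner that runs
   unit-cost furthest-reaching waves bidirectionally from a seed
   anti-diagonal, trims to the maximal-scoring segment, and reports
   endpoints, the difference count d (always equal to the unit-cost edit
   distance of the reported segment pair) and a **trace-point** encoding:
   the array of B-panel lengths ⟨b₀…b_t⟩ induced by cutting A every δ=100
   bases — one byte per 100 bp of alignment, independent of divergence, from
   which the exact path is reconstructed in O(n + δd).
6. **Output** — PAF (with `=X` or `M` CIGAR), 21-column PSL, or a compact
   ASCII ALN document; before CIGAR conversion, alignments are refined to
   the equivalent unit-cost path with the fewest gaps (gap-open 1,
   gap-extend 0, mismatch 1 via a compressed wave over each indel run).

A benchmark module generates planted-similarity genome pairs (10 kb blocks,
regions of 100 bp–5 kb at 1–65% divergence; edits drawn 80% substitutions /
10% insertions / 10% deletions) and scores alignment output for complete
recoveries, falsely aligned bases and false positives.

## Worked example

```sh
python examples/align_genome_pair.py
```

simulates a 60 kb pair with six planted regions and prints, e.g.:

```
genomeA  60000  10000  11001  +  genomeB  60000  0      1000   992   1002  255  NM:i:10
genomeA  60000  20000  22000  +  genomeB  60000  10000  12003  1983  2003  255  NM:i:20
```

Each row is one local alignment: the 1 kb region planted at 1% divergence is
recovered with 10 differences (`NM:i:10`) over a 1002-column block with 992
residue matches; the 2 kb region at 1% shows 20 differences, and so on — the
difference counts track length × divergence of the planted truth. Other
examples show the index/seed layer (`index_and_seeds.py`), the trace-point
size advantage over CIGAR (`tracepoint_encoding.py`: 100 one-byte panels vs
a 6.3 kB CIGAR at 17% divergence) and a sensitivity/specificity sweep
(`benchmark_sensitivity.py`).

Command-line wrappers mirror the library: `adaptalign A.fa B.fa` (PAF to
stdout), `gixmake` (persist an index), `alnconvert` (ALN → PAF/PSL),
`alnsim` (benchmark generation/scoring), `alnview` (inspect an ALN file).

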