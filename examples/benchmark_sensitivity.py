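"""Sensitivity/specificity evaluation on a small planted benchmark.

Generates a reduced benchmark grid (region lengths 500-5000 bp, divergence
1-20%, 3 replicates per cell), aligns the pair, and scores the output
against the planted truth: complete recoveries per cell (aligned bases
covering >=95% of the region on both genomes), falsely aligned bases, and
false-positive alignments.
"""

import tempfile
from pathlib import Path

import pandas as pd

import adaptalign as aa
from adaptalign.simulate import (
    SimParams,
    evaluate_alignments,
    simulate_genome_pair,
    write_benchmark_fasta,
)

params = SimParams(
    region_lengths=(500, 1000, 2000, 5000),
    divergences=(0.01, 0.05, 0.10, 0.15, 0.20),
    replicates=3,
    seed=1,
)
genome_a, genome_b, truth = simulate_genome_pair(params)
print(f"benchmark: {params.genome_length/1e6:.1f} Mb per genome, "
      f"{params.n_blocks} planted regions")

tmp = Path(tempfile.mkdtemp())
write_benchmark_fasta(genome_a, "genomeA", tmp / "A.fa")
write_benchmark_fasta(genome_b, "genomeB", tmp / "B.fa")
gdb_a = aa.fasta_to_gdb(tmp / "A.fa")
gdb_b = aa.fasta_to_gdb(tmp / "B.fa")

alignments = aa.align_genomes(gdb_a, gdb_b)
records = aa.to_records(alignments, gdb_a, gdb_b, refine=False)
frame = pd.DataFrame(
    {
        "a_start": [r.qstart for r in records],
        "a_end": [r.qend for r in records],
        "b_start": [r.tstart for r in records],
        "b_end": [r.tend for r in records],
    }
)
report = evaluate_alignments(frame, truth)
print(f"\n{report.n_alignments} alignments reported")
print("\ncomplete recoveries per cell (out of 3; rows = divergence, cols = length):")
print(report.complete.to_string())
print(f"\nfalsely aligned bases: {report.false_bases}")
print(f"false-positive alignments: {report.false_positives}")
print("\nrecovery falls with divergence and rises with region length; "
      "specificity stays clean because random filler cannot sustain "
      ">=100 bp at <=30% divergence")
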