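"""Align a small simulated genome pair and print the PAF output.

Builds a 60 kb benchmark pair with six planted similarity regions (1-2 kb,
1-10% divergence), runs the full index/merge/chain/align pipeline, and
streams PAF.  Each PAF row is one local alignment: query and target
intervals, strand, residue matches out of the aligned block length, and an
NM tag with the unit-cost difference count.
"""

import sys
import tempfile
from pathlib import Path

import adaptalign as aa
from adaptalign.simulate import SimParams, simulate_genome_pair, write_benchmark_fasta

params = SimParams(
    region_lengths=(1000, 2000),
    divergences=(0.01, 0.05, 0.10),
    replicates=1,
    seed=42,
)
genome_a, genome_b, truth = simulate_genome_pair(params)
print(f"simulated {params.genome_length:,} bp per genome, "
      f"{params.n_blocks} blocks with planted regions\n", file=sys.stderr)

tmp = Path(tempfile.mkdtemp())
write_benchmark_fasta(genome_a, "genomeA", tmp / "A.fa")
write_benchmark_fasta(genome_b, "genomeB", tmp / "B.fa")

gdb_a = aa.fasta_to_gdb(tmp / "A.fa")
gdb_b = aa.fasta_to_gdb(tmp / "B.fa")
alignments = aa.align_genomes(gdb_a, gdb_b)

print(f"found {len(alignments)} local alignments "
      f"(expected ~{params.n_blocks}: one per planted region)\n", file=sys.stderr)
aa.write_paf(alignments, gdb_a, gdb_b, sys.stdout, cigar=None)
print("\ncolumns: query name/len/start/end, strand, target name/len/start/end, "
      "matches, block length, mapq(255), NM:i:differences", file=sys.stderr)
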