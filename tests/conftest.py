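import numpy as np
import pytest

from adaptalign.genome_db import GenomeDB, codes_to_seq, fasta_to_gdb


@pytest.fixture
def gdb_factory(tmp_path):
    """Build a GenomeDB from raw sequence strings (one scaffold each)."""

    def make(*seqs, names=None):
        p = tmp_path / f"g{len(list(tmp_path.iterdir()))}.fa"
        with open(p, "w") as fh:
            for i, s in enumerate(seqs):
                nm = names[i] if names else f"s{i}"
                fh.write(f">{nm}\n{s}\n")
        return fasta_to_gdb(p)

    return make


def random_seq(rng, n):
    return codes_to_seq(rng.integers(0, 4, n, dtype=np.uint8))


def mutate_codes(rng, codes, n_edits):
    """Simple independent mutator used as test input generator (not the
    package's own simulator): random subs/ins/dels."""
    out = list(np.asarray(codes).tolist())
    for _ in range(n_edits):
        if not out:
            break
        p = int(rng.integers(0, len(out)))
        op = int(rng.integers(0, 3))
        if op == 0:
            out[p] = int((out[p] + 1 + rng.integers(0, 3)) % 4)
        elif op == 1:
            out.insert(p, int(rng.integers(0, 4)))
        else:
            del out[p]
    return np.array(out, dtype=np.uint8)


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """One scaled-down benchmark pipeline run shared by the acceptance tests:
    region lengths 500..5000, divergences 1..20%, 10 replicates per cell."""
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
        replicates=10,
        seed=0,
    )
    genome_a, genome_b, truth = simulate_genome_pair(params)
    d = tmp_path_factory.mktemp("bench")
    write_benchmark_fasta(genome_a, "genomeA", d / "A.fa")
    write_benchmark_fasta(genome_b, "genomeB", d / "B.fa")
    gA = fasta_to_gdb(d / "A.fa")
    gB = fasta_to_gdb(d / "B.fa")
    alns = aa.align_genomes(gA, gB)
    recs = aa.to_records(alns, gA, gB, refine=False)
    frame = pd.DataFrame(
        {
            "a_start": [r.qstart for r in recs],
            "a_end": [r.qend for r in recs],
            "b_start": [r.tstart for r in recs],
            "b_end": [r.tend for r in recs],
        }
    )
    report = evaluate_alignments(frame, truth)
    return {
        "params": params,
        "truth": truth,
        "alignments": alns,
        "gdbs": (gA, gB),
        "report": report,
    }
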