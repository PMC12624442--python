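"""Planted-similarity benchmark genomes and alignment evaluation.

A benchmark pair is built from 10 kb blocks, one per (region length,
divergence, replicate) triple: each block starts with a planted region of
similarity followed by random filler.  Genome B carries a mutated copy of
each region -- divergence * length edits drawn as 80% single-nucleotide
substitutions, 10% single-base insertions and 10% single-base deletions --
followed by its own filler, and the block orders of the two genomes are
shuffled independently so no long-range alignment spans blocks.  The default
grid (6 lengths x 14 divergence levels x 100 replicates x 10 kb) makes each
genome 84,000,000 bp.

The evaluator scores an alignment set against the planted truth: a region is
*completely recovered* when aligned bases cover at least 95% of its interval
on both genomes; an alignment is a *false positive* when it spans multiple
target regions or has more than 95% of its aligned bases outside the target
region on either genome; *falsely aligned bases* are genome-A positions
covered by alignments outside every target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from adaptalign.genome_db import codes_to_seq

__all__ = [
    "SimParams",
    "SimTruth",
    "SimReport",
    "mutate_sequence",
    "replay_edits",
    "simulate_genome_pair",
    "evaluate_alignments",
]

DEFAULT_REGION_LENGTHS = (100, 200, 500, 1000, 2000, 5000)
# 1% then 5..65% in steps of 5: fourteen levels spanning the printed range
DEFAULT_DIVERGENCES = (0.01,) + tuple(np.round(np.arange(0.05, 0.66, 0.05), 2))


@dataclass(frozen=True)
class SimParams:
    block_len: int = 10_000
    region_lengths: Tuple[int, ...] = DEFAULT_REGION_LENGTHS
    divergences: Tuple[float, ...] = DEFAULT_DIVERGENCES
    replicates: int = 100
    edit_mix: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.edit_mix) - 1.0) > 1e-9:
            raise ValueError("edit mix must sum to 1")
        if max(self.region_lengths) >= self.block_len:
            raise ValueError("region length must be smaller than the block")

    @property
    def n_blocks(self) -> int:
        return len(self.region_lengths) * len(self.divergences) * self.replicates

    @property
    def genome_length(self) -> int:
        """Total length of each simulated genome (blocks are fixed size)."""
        return self.n_blocks * self.block_len


@dataclass
class SimTruth:
    """Planted-region coordinates: one row per block, in both genomes."""

    table: pd.DataFrame  # block, length, divergence, replicate, a_start, a_end, b_start, b_end
    genome_length_a: int
    genome_length_b: int


def mutate_sequence(
    codes: np.ndarray,
    divergence: float,
    mix: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[Tuple[int, str, int]]]:
    """Apply ``round(divergence * len)`` random edits to a code sequence.

    Edit types are drawn from ``mix`` = (substitution, insertion, deletion);
    substitutions never rewrite the original base; insertions place a random
    base before the chosen position.  Returns the mutated sequence and an
    edit log of (position, op, base) entries, positions in original
    coordinates, applicable via :func:`replay_edits`.
    """
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    rng = rng or np.random.default_rng()
    codes = np.asarray(codes, dtype=np.uint8)
    n = len(codes)
    n_edits = int(round(divergence * n))
    if n_edits == 0:
        return codes.copy(), []
    positions = np.sort(rng.choice(n, size=min(n_edits, n), replace=False))
    kinds = rng.choice(3, size=len(positions), p=list(mix))
    log: List[Tuple[int, str, int]] = []
    for p, k in zip(positions.tolist(), kinds.tolist()):
        if k == 0:
            base = int((codes[p] + 1 + rng.integers(0, 3)) % 4)
            log.append((p, "S", base))
        elif k == 1:
            log.append((p, "I", int(rng.integers(0, 4))))
        else:
            log.append((p, "D", -1))
    return replay_edits(codes, log), log


def replay_edits(codes: np.ndarray, log: Sequence[Tuple[int, str, int]]) -> np.ndarray:
    """Apply an edit log (positions in original coordinates) to a sequence."""
    out = list(np.asarray(codes, dtype=np.uint8).tolist())
    for p, op, base in sorted(log, reverse=True):
        if op == "S":
            out[p] = base
        elif op == "I":
            out.insert(p, base)
        elif op == "D":
            del out[p]
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return np.array(out, dtype=np.uint8)


def simulate_genome_pair(params: SimParams) -> Tuple[np.ndarray, np.ndarray, SimTruth]:
    """Generate the benchmark genome pair and its planted truth.

    Deterministic for a fixed ``params.seed``: the same parameters always
    yield byte-identical genomes.
    """
    rng = np.random.default_rng(params.seed)
    blocks_a: List[np.ndarray] = []
    blocks_b: List[np.ndarray] = []
    rows = []
    bid = 0
    for length in params.region_lengths:
        for div in params.divergences:
            for rep in range(params.replicates):
                region = rng.integers(0, 4, length, dtype=np.uint8)
                filler_a = rng.integers(0, 4, params.block_len - length, dtype=np.uint8)
                mut, _ = mutate_sequence(region, div, params.edit_mix, rng)
                filler_b = rng.integers(0, 4, params.block_len - len(mut), dtype=np.uint8)
                blocks_a.append(np.concatenate([region, filler_a]))
                blocks_b.append(np.concatenate([mut, filler_b]))
                rows.append((bid, length, div, rep, len(region), len(mut)))
                bid += 1
    order_a = rng.permutation(bid)
    order_b = rng.permutation(bid)
    pos_a = np.empty(bid, dtype=np.int64)
    pos_b = np.empty(bid, dtype=np.int64)
    pos_a[order_a] = np.arange(bid) * params.block_len
    pos_b[order_b] = np.arange(bid) * params.block_len
    table = pd.DataFrame(
        rows, columns=["block", "length", "divergence", "replicate", "_alen", "_blen"]
    )
    table["a_start"] = pos_a
    table["a_end"] = pos_a + table["_alen"]
    table["b_start"] = pos_b
    table["b_end"] = pos_b + table["_blen"]
    table = table.drop(columns=["_alen", "_blen"])
    genome_a = np.concatenate([blocks_a[i] for i in order_a])
    genome_b = np.concatenate([blocks_b[i] for i in order_b])
    truth = SimTruth(
        table=table, genome_length_a=len(genome_a), genome_length_b=len(genome_b)
    )
    return genome_a, genome_b, truth


def write_benchmark_fasta(genome: np.ndarray, name: str, path, width: int = 80) -> None:
    seq = codes_to_seq(genome)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


@dataclass
class SimReport:
    complete: pd.DataFrame  # rows: divergence, cols: length -> complete count
    per_region: pd.DataFrame
    false_bases: int
    false_positives: int
    n_alignments: int


def _interval_overlap(starts, ends, lo, hi):
    return np.maximum(0, np.minimum(ends, hi) - np.maximum(starts, lo))


def evaluate_alignments(alignments: pd.DataFrame, truth: SimTruth) -> SimReport:
    """Score alignments (columns a_start, a_end, b_start, b_end; forward
    genome coordinates) against the planted truth."""
    tt = truth.table
    need = {"a_start", "a_end", "b_start", "b_end"}
    if not need.issubset(alignments.columns):
        raise ValueError(f"alignments frame needs columns {sorted(need)}")
    a_starts = alignments["a_start"].to_numpy(dtype=np.int64)
    a_ends = alignments["a_end"].to_numpy(dtype=np.int64)
    b_starts = alignments["b_start"].to_numpy(dtype=np.int64)
    b_ends = alignments["b_end"].to_numpy(dtype=np.int64)
    if len(a_starts) and (
        a_starts.min() < 0
        or a_ends.max() > truth.genome_length_a
        or b_starts.min() < 0
        or b_ends.max() > truth.genome_length_b
    ):
        raise ValueError("alignment coordinates outside the genomes")
    ta_s = tt["a_start"].to_numpy()
    ta_e = tt["a_end"].to_numpy()
    tb_s = tt["b_start"].to_numpy()
    tb_e = tt["b_end"].to_numpy()
    # falsely aligned bases: A positions covered outside every target region
    cov = np.zeros(truth.genome_length_a, dtype=bool)
    for s, e in zip(a_starts, a_ends):
        cov[s:e] = True
    tmask = np.zeros(truth.genome_length_a, dtype=bool)
    for s, e in zip(ta_s, ta_e):
        tmask[s:e] = True
    false_bases = int((cov & ~tmask).sum())
    # false positives per alignment
    fp = 0
    for s, e, bs, be in zip(a_starts, a_ends, b_starts, b_ends):
        ova = _interval_overlap(ta_s, ta_e, s, e)
        ovb = _interval_overlap(tb_s, tb_e, bs, be)
        spans = max(int((ova > 0).sum()), int((ovb > 0).sum()))
        out_a = 1.0 - ova.sum() / max(1, e - s)
        out_b = 1.0 - ovb.sum() / max(1, be - bs)
        if spans >= 2 or out_a > 0.95 or out_b > 0.95:
            fp += 1
    # complete recovery per region: union coverage >= 95% on both genomes,
    # counting only alignments consistent with the region pair
    rec = []
    for _, row in tt.iterrows():
        sa, ea, sb, eb = int(row.a_start), int(row.a_end), int(row.b_start), int(row.b_end)
        sel = (a_ends > sa) & (a_starts < ea) & (b_ends > sb) & (b_starts < eb)
        if sel.any():
            cova = np.zeros(ea - sa, dtype=bool)
            covb = np.zeros(eb - sb, dtype=bool)
            for s, e, bs, be in zip(a_starts[sel], a_ends[sel], b_starts[sel], b_ends[sel]):
                cova[max(0, s - sa) : max(0, e - sa)] = True
                covb[max(0, bs - sb) : max(0, be - sb)] = True
            ok = cova.mean() >= 0.95 and covb.mean() >= 0.95
        else:
            ok = False
        rec.append(ok)
    per_region = tt.assign(complete=rec)
    complete = (
        per_region.groupby(["divergence", "length"])["complete"].sum().unstack("length")
    )
    return SimReport(
        complete=complete,
        per_region=per_region,
        false_bases=false_bases,
        false_positives=fp,
        n_alignments=len(alignments),
    )
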