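"""Local alignment search through chain tubes, and the end-to-end driver.

The LA-finder contract: given two contig sequences, an anti-diagonal and a
pair of diagonal bounds, find the best local alignment passing through that
anti-diagonal between the bounds, reporting its endpoints, its unit-cost
difference count and a trace-point representation; a length-0 alignment is
the no-similarity signal.  Internally the finder runs furthest-reaching
unit-cost waves bidirectionally from the seed anti-diagonal, trims each
direction at its maximal-scoring frontier point (score = aligned
anti-diagonal progress minus differences weighted by 1/max_divergence, so
the score peaks where local identity falls below 1 - max_divergence), stops
a direction once a trailing window of anti-diagonals brings no improvement,
and then recovers the exact path between the trimmed endpoints with the
global wave so that the reported diffs equal the unit-cost edit distance of
the reported segment pair.  Runs of indels longer than ``max_gap`` are
considered breaks in similarity and split the alignment (this also keeps
every trace-point panel within its one-byte budget).

Each chain tube is swept with repeated LA-finder calls: first on
anti-diagonal a_low + 2D (or the tube midpoint for short tubes), then
restarting past the far end of whatever was found, until the tube is
exhausted.  Alignments that are duplicates, or whose bounding box lies
inside another alignment's box (satellite-repeat echoes), are removed, and
the survivors are reported in order of start coordinate in the first genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from adaptalign.adaptamer import SeedHits, merge_indices, symmetric_merge
from adaptalign.chain import ChainParams, ChainTube, find_chains, hits_to_band_records
from adaptalign.genome_db import GenomeDB, rc_codes
from adaptalign.kmer_index import GenomeIndex, IndexParams, build_index
from adaptalign.tracepoint import (
    DEFAULT_DELTA,
    TracePointOverflow,
    encode_tracepoints,
)
from adaptalign.wavefront import (
    OP_DIAG,
    OP_INS,
    extend_local,
    global_path,
    path_intervals,
    path_stats,
    split_at_long_gaps,
)

__all__ = ["AlignParams", "Alignment", "la_finder", "sweep_tube", "remove_redundant", "align_genomes"]


@dataclass(frozen=True)
class AlignParams:
    """min_length: shortest reported alignment (bases of the first genome);
    max_divergence: largest reported diffs/length fraction; max_gap: largest
    single indel tolerated inside one alignment; window: anti-diagonal
    trailing window for extension termination; delta: trace-point spacing."""

    min_length: int = 100
    max_divergence: float = 0.3
    max_gap: int = 40
    D: int = 64  # band width, shared with the chain stage
    window: int = 100
    delta: int = DEFAULT_DELTA
    max_diffs: int = 4096

    def __post_init__(self) -> None:
        if not (0.0 < self.max_divergence < 1.0):
            raise ValueError("max_divergence must be in (0, 1)")


@dataclass
class Alignment:
    """A local alignment of G contig interval [ab, ae) against H contig
    interval [bb, be); for strand -1 the H interval is in coordinates of the
    reverse-complemented contig."""

    contig_g: int
    contig_h: int
    strand: int
    ab: int
    ae: int
    bb: int
    be: int
    diffs: int
    tracepoints: Optional[object] = None
    path: Optional[np.ndarray] = None

    @property
    def epsilon(self) -> float:
        return self.diffs / max(1, self.ae - self.ab)

    @property
    def length(self) -> int:
        return self.ae - self.ab

    def bounding_box(self) -> Tuple[int, int, int, int]:
        return (self.ab, self.ae, self.bb, self.be)


def _encode_with_splits(pieces, params):
    """Encode trace points for path pieces, splitting further on overflow."""
    out = []
    stack = list(pieces)
    while stack:
        ops, ab, ae, bb, be = stack.pop()
        try:
            tpa = encode_tracepoints(ops, ab, ae, bb, be, params.delta)
            out.append((ops, ab, ae, bb, be, tpa))
        except TracePointOverflow:
            # split at the longest gap and retry
            sub = split_at_long_gaps(ops, max_gap=max(1, _longest_gap(ops) - 1))
            if len(sub) <= 1:
                continue  # irreducible: drop (cannot be represented)
            for sops, da, db in sub:
                na, nb = path_intervals(sops)
                stack.append((sops, ab + da, ab + da + na, bb + db, bb + db + nb))
    return out


def _longest_gap(ops: np.ndarray) -> int:
    n = len(ops)
    if n == 0:
        return 0
    change = np.r_[True, np.diff(ops) != 0]
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:], n]
    lens = ends - starts
    gap = ops[starts] != OP_DIAG
    return int(lens[gap].max()) if gap.any() else 0


def la_finder(
    Aseq: np.ndarray,
    Bseq: np.ndarray,
    anti: int,
    d_low: int,
    d_high: int,
    params: AlignParams = AlignParams(),
    Arev: Optional[np.ndarray] = None,
    Brev: Optional[np.ndarray] = None,
    contig_g: int = 0,
    contig_h: int = 0,
    strand: int = 1,
) -> Tuple[List[Alignment], int]:
    """Best local alignment through ``anti`` within [d_low, d_high].

    Returns (alignments, a_top): the alignment may come back in several
    pieces if a gap longer than max_gap splits it; an empty list is the
    length-0 signal.  a_top is the far-end anti-diagonal reached (== anti
    when nothing was found), which drives the tube sweep.
    """
    n, m = len(Aseq), len(Bseq)
    if Arev is None:
        Arev = np.ascontiguousarray(Aseq[::-1])
    if Brev is None:
        Brev = np.ascontiguousarray(Bseq[::-1])
    anti = int(min(max(anti, 0), n + m))
    fi, fj, _ = extend_local(Aseq, Bseq, anti, d_low, d_high, params.max_divergence, params.window)
    ri, rj, _ = extend_local(
        Arev,
        Brev,
        (n + m) - anti,
        (n - m) - d_high,
        (n - m) - d_low,
        params.max_divergence,
        params.window,
    )
    if fi < 0 or ri < 0:
        return [], anti
    ae, be = int(fi), int(fj)
    ab, bb = n - int(ri), m - int(rj)
    if ae - ab <= 0 or be - bb <= 0:
        return [], anti
    res = global_path(Aseq[ab:ae], Bseq[bb:be], max_diffs=params.max_diffs)
    if res is None:
        return [], anti
    ops, _ = res
    pieces = []
    for sops, da, db in split_at_long_gaps(ops, params.max_gap):
        na, nb = path_intervals(sops)
        pieces.append((sops, ab + da, ab + da + na, bb + db, bb + db + nb))
    out = []
    a_top = anti
    for sops, pab, pae, pbb, pbe, tpa in _encode_with_splits(pieces, params):
        diffs, _ = path_stats(sops, Aseq, Bseq, pab, pbb)
        a_top = max(a_top, pae + pbe)
        out.append(
            Alignment(
                contig_g=contig_g,
                contig_h=contig_h,
                strand=strand,
                ab=pab,
                ae=pae,
                bb=pbb,
                be=pbe,
                diffs=diffs,
                tracepoints=tpa,
                path=sops,
            )
        )
    return out, int(a_top)


def _passes(aln: Alignment, params: AlignParams) -> bool:
    return aln.length >= params.min_length and aln.epsilon <= params.max_divergence


def sweep_tube(
    tube: ChainTube,
    Aseq: np.ndarray,
    Bseq: np.ndarray,
    params: AlignParams = AlignParams(),
    Arev: Optional[np.ndarray] = None,
    Brev: Optional[np.ndarray] = None,
) -> List[Alignment]:
    """Sweep a chain tube with LA-finder calls until it is processed.

    The first call is on anti-diagonal a_low + 2D (or the midpoint of short
    tubes); after each call the tube is truncated to start past the far end
    of the alignment found.  Only alignments passing the length and
    divergence thresholds are retained.
    """
    D = params.D
    a_low, a_high = tube.a_low, tube.a_high
    out: List[Alignment] = []
    while a_low < a_high:
        if a_low + D < a_high:
            anti = a_low + 2 * D
        else:
            anti = (a_low + a_high) // 2
        alns, a_top = la_finder(
            Aseq,
            Bseq,
            anti,
            tube.d_low,
            tube.d_high,
            params,
            Arev=Arev,
            Brev=Brev,
            contig_g=tube.contig_g,
            contig_h=tube.contig_h,
            strand=tube.strand,
        )
        out.extend(a for a in alns if _passes(a, params))
        if a_top >= a_high:
            break
        a_low = max(a_top, a_low + 1)
    return out


def remove_redundant(alignments: List[Alignment]) -> List[Alignment]:
    """Drop duplicate alignments and alignments whose bounding box lies
    entirely inside another's (within each contig-pair/strand group); sort
    the survivors by start coordinate in the first genome."""
    if not alignments:
        return []
    groups: Dict[Tuple[int, int, int], List[Alignment]] = {}
    for a in alignments:
        groups.setdefault((a.contig_g, a.contig_h, a.strand), []).append(a)
    kept: List[Alignment] = []
    for group in groups.values():
        n = len(group)
        ab = np.array([a.ab for a in group])
        ae = np.array([a.ae for a in group])
        bb = np.array([a.bb for a in group])
        be = np.array([a.be for a in group])
        idx = np.arange(n)
        inside = (
            (ab[:, None] >= ab[None, :])
            & (ae[:, None] <= ae[None, :])
            & (bb[:, None] >= bb[None, :])
            & (be[:, None] <= be[None, :])
        )
        same = inside & inside.T  # identical boxes
        proper = inside & ~same
        # redundant: properly inside another, or a later copy of an equal box
        dup = same & (idx[None, :] < idx[:, None])
        redundant = (proper | dup).any(axis=1)
        kept.extend(a for a, r in zip(group, redundant) if not r)
    kept.sort(key=lambda a: (a.contig_g, a.ab, a.contig_h, a.strand, a.bb))
    return kept


def align_genomes(
    gdbG: GenomeDB,
    gdbH: GenomeDB,
    index_params: IndexParams = IndexParams(),
    chain_params: ChainParams = ChainParams(),
    align_params: AlignParams = AlignParams(),
    symmetric: bool = False,
    indexG: Optional[GenomeIndex] = None,
    indexH: Optional[GenomeIndex] = None,
) -> List[Alignment]:
    """Full pipeline: index both genomes, merge for adaptamer seeds, chain,
    sweep every tube, and remove redundant alignments.  Deterministic given
    inputs and parameters."""
    iG = indexG if indexG is not None else build_index(gdbG, index_params)
    iH = indexH if indexH is not None else build_index(gdbH, index_params)
    if symmetric:
        hits = symmetric_merge(iG, iH, tau=index_params.tau, min_len=index_params.s)
    else:
        hits = merge_indices(iG, iH, tau=index_params.tau, min_len=index_params.s)
    records = hits_to_band_records(hits, chain_params, gdbH.contig_lengths)
    tubes = find_chains(records, chain_params)
    fwd_cache: Dict[int, np.ndarray] = {}
    rev_cache: Dict[Tuple[int, int], np.ndarray] = {}

    def g_codes(cid: int) -> np.ndarray:
        if cid not in fwd_cache:
            fwd_cache[cid] = gdbG.contigs[cid].codes()
        return fwd_cache[cid]

    def h_codes(cid: int, strand: int) -> np.ndarray:
        key = (cid, strand)
        if key not in rev_cache:
            codes = gdbH.contigs[cid].codes()
            rev_cache[key] = codes if strand > 0 else rc_codes(codes)
        return rev_cache[key]

    rev_of: Dict[int, np.ndarray] = {}
    rev_of_h: Dict[Tuple[int, int], np.ndarray] = {}
    alns: List[Alignment] = []
    for tube in tubes:
        A = g_codes(tube.contig_g)
        B = h_codes(tube.contig_h, tube.strand)
        if tube.contig_g not in rev_of:
            rev_of[tube.contig_g] = np.ascontiguousarray(A[::-1])
        key = (tube.contig_h, tube.strand)
        if key not in rev_of_h:
            rev_of_h[key] = np.ascontiguousarray(B[::-1])
        alns.extend(
            sweep_tube(tube, A, B, align_params, Arev=rev_of[tube.contig_g], Brev=rev_of_h[key])
        )
    return remove_redundant(alns)
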