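"""Diagonal-band chaining of seed hits.

Each seed hit is a point (p_i, p_j) in the dynamic-programming matrix of a
contig pair, living on diagonal ``p_i - p_j`` and anti-diagonal
``p_i + p_j``.  Hits are bucketed into diagonal bands of width D via the
sextuple record (c_i, c_j, b, a, r, t) with band ``b = floor((p_i-p_j)/D)``,
anti-diagonal ``a`` and remainder ``r = (p_i-p_j) mod D``, from which the
exact point is reconstructible.  After sorting, the seeds of each pair of
adjacent bands (b, b+1) are merged in anti-diagonal order and maximal runs
with successive anti-diagonal gaps of at most A become chains; a chain's
*tube* -- the rectangle bounded by its extreme diagonals and anti-diagonals,
both ends of every seed included -- is the region later swept for local
alignments.  Merging adjacent bands admits chains up to width 2D, which only
costs a little alignment-time work, never sensitivity.

Reverse-strand hits are first mapped to coordinates in the reverse-
complemented H contig so that a co-linear inverted repeat lies on a single
diagonal; the two strands are chained separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from adaptalign.adaptamer import SeedHits

__all__ = ["ChainParams", "BandRecords", "ChainTube", "hits_to_band_records", "find_chains"]


@dataclass(frozen=True)
class ChainParams:
    """D: band width in diagonals; A: maximum anti-diagonal gap within a chain."""

    D: int = 64
    A: int = 1000
    min_chain_seeds: int = 1

    def __post_init__(self) -> None:
        if self.D < 1 or self.A < 1:
            raise ValueError("D and A must be >= 1")


@dataclass
class BandRecords:
    """Sorted sextuple records; pos_i/pos_j are retained for convenience."""

    contig_g: np.ndarray
    contig_h: np.ndarray
    strand: np.ndarray
    b: np.ndarray
    a: np.ndarray
    r: np.ndarray
    t: np.ndarray
    D: int

    @property
    def n(self) -> int:
        return len(self.t)

    def reconstruct(self) -> Tuple[np.ndarray, np.ndarray]:
        """Exact (p_i, p_j) from (b, a, r): the algebraic round trip."""
        diag = self.D * self.b + self.r
        pi = (self.a + diag) // 2
        pj = (self.a - diag) // 2
        return pi, pj


@dataclass
class ChainTube:
    contig_g: int
    contig_h: int
    strand: int
    d_low: int
    d_high: int
    a_low: int
    a_high: int
    seed_count: int
    seed_idx: Optional[np.ndarray] = None  # indices into the band records

    def key(self) -> tuple:
        return (self.contig_g, self.contig_h, self.strand, self.d_low, self.d_high, self.a_low, self.a_high)


def hits_to_band_records(hits: SeedHits, params: ChainParams, h_contig_lengths: np.ndarray) -> BandRecords:
    """Convert seed hits to band records sorted on (c_g, c_h, strand, b, a).

    For reverse-strand hits p_j is the hit's start in the reverse-complement
    of contig_h (``len - pos_h - t``), so that diagonals of an inversion are
    consistent.  Band index uses floor division, hence is negative below the
    main diagonal.
    """
    pi = hits.pos_g.astype(np.int64)
    clen = np.asarray(h_contig_lengths, dtype=np.int64)
    pj = np.where(
        hits.strand > 0,
        hits.pos_h,
        clen[hits.contig_h] - hits.pos_h - hits.t,
    ).astype(np.int64)
    D = params.D
    diag = pi - pj
    b = np.floor_divide(diag, D)
    r = np.mod(diag, D)
    a = pi + pj
    order = np.lexsort((a, b, hits.strand, hits.contig_h, hits.contig_g))
    return BandRecords(
        contig_g=hits.contig_g[order].astype(np.int64),
        contig_h=hits.contig_h[order].astype(np.int64),
        strand=hits.strand[order].astype(np.int64),
        b=b[order],
        a=a[order],
        r=r[order],
        t=hits.t[order].astype(np.int64),
        D=D,
    )


def find_chains(records: BandRecords, params: ChainParams) -> List[ChainTube]:
    """Chains (as tubes) from sorted band records, linear in the seeds.

    Every existing band b is merged with band b+1 (possibly empty) of the
    same (contig_g, contig_h, strand) group, so every seed lands in at least
    one tube; a chain found identically from (b-1, b) and (b, b+1) is
    deduplicated by its seed set.
    """
    tubes: List[ChainTube] = []
    seen: Dict[tuple, bool] = {}
    n = records.n
    if n == 0:
        return tubes
    pi, pj = records.reconstruct()
    diag = pi - pj
    group_key = np.column_stack([records.contig_g, records.contig_h, records.strand])
    group_change = np.r_[True, (np.diff(group_key, axis=0) != 0).any(axis=1)]
    group_starts = np.flatnonzero(group_change)
    group_ends = np.r_[group_starts[1:], n]
    for gs, ge in zip(group_starts, group_ends):
        bs = records.b[gs:ge]
        # per-band sub-ranges (records sorted by b then a within the group)
        band_change = np.r_[True, np.diff(bs) != 0]
        band_starts = np.flatnonzero(band_change) + gs
        band_vals = records.b[band_starts]
        band_ends = np.r_[band_starts[1:], ge]
        band_of = dict(zip(band_vals.tolist(), zip(band_starts.tolist(), band_ends.tolist())))
        for bv, (s0, e0) in band_of.items():
            idx = np.arange(s0, e0)
            if bv + 1 in band_of:
                s1, e1 = band_of[bv + 1]
                idx = np.concatenate([idx, np.arange(s1, e1)])
                idx = idx[np.argsort(records.a[idx], kind="stable")]
            a_vals = records.a[idx]
            gap_break = np.r_[True, np.diff(a_vals) > params.A]
            chain_starts = np.flatnonzero(gap_break)
            chain_ends = np.r_[chain_starts[1:], len(idx)]
            for cs, ce in zip(chain_starts, chain_ends):
                members = idx[cs:ce]
                if len(members) < params.min_chain_seeds:
                    continue
                key = tuple(members.tolist())
                if key in seen:
                    continue
                seen[key] = True
                d = diag[members]
                a_lo = int(records.a[members].min())
                a_hi = int((records.a[members] + 2 * records.t[members]).max())
                tubes.append(
                    ChainTube(
                        contig_g=int(records.contig_g[members[0]]),
                        contig_h=int(records.contig_h[members[0]]),
                        strand=int(records.strand[members[0]]),
                        d_low=int(d.min()),
                        d_high=int(d.max()),
                        a_low=a_lo,
                        a_high=a_hi,
                        seed_count=len(members),
                        seed_idx=members,
                    )
                )
    return tubes
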