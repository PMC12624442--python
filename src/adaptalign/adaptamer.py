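"""Adaptamer (adaptive seed / 1/2-MEM) discovery by merging two genome indices.

For every K-mer record in the first index G (forward strand only), the merge
finds the range ``[fst, lst)`` of records in the second index H sharing the
longest possible prefix with it, and the length ``L`` of that prefix: the
adaptamer at each occurrence of the G K-mer is its L-prefix, and it matches
at every H location in the range.  The sweep is linear in the two indices:
the lcp arrays let the state (fst, lst, L, cur, wall) for one G record be
updated to the next without rescanning, so the total number of base
comparisons is proportional to the number of edges in the intersection of
the two (truncated) suffix tries.

Repetitive adaptamers -- ranges whose occurrence total in H exceeds ``tau``
-- are suppressed; the scan caps ``lst`` at ``fst + tau + 1`` so that no
unbounded forward search is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from adaptalign.kmer_index import GenomeIndex

__all__ = ["SeedHits", "merge_indices", "symmetric_merge"]


@dataclass
class SeedHits:
    """Columnar seed matches between two genomes.

    ``strand`` is the orientation of the H occurrence; positions are 0-based
    forward-strand offsets of the leftmost matched base within the contig,
    i.e. for a hit of length t:

    * strand +1: ``G[pos_g : pos_g+t] == H[pos_h : pos_h+t]``
    * strand -1: ``G[pos_g : pos_g+t] == rc(H[pos_h : pos_h+t])``
    """

    contig_g: np.ndarray
    pos_g: np.ndarray
    contig_h: np.ndarray
    pos_h: np.ndarray
    strand: np.ndarray
    t: np.ndarray

    @property
    def n(self) -> int:
        return len(self.t)

    def as_tuples(self):
        return list(
            zip(
                self.contig_g.tolist(),
                self.pos_g.tolist(),
                self.contig_h.tolist(),
                self.pos_h.tolist(),
                self.strand.tolist(),
                self.t.tolist(),
            )
        )


@njit(cache=True, inline="never")
def _base(kmers, i, b):  # pragma: no cover
    return (kmers[i, b >> 2] >> (6 - 2 * (b & 3))) & 3


@njit(cache=True)
def _extension(Hk, Hlcp, Nh, K, tau, beta, L, cur, fst, lst, wall, stats):  # pragma: no cover
    """Advance cur / grow L for the current G K-mer ``beta`` (unpacked codes)."""
    while L < K:
        while True:
            stats[0] += 1
            if cur < Nh and _base(Hk, cur, L) < beta[L]:
                cur += 1
                hl = Hlcp[cur] if cur < Nh else -1
                if hl < L:
                    lst = cur
                    return L, cur, fst, lst
            else:
                break
        hb = _base(Hk, cur, L) if cur < Nh else 4
        if hb > beta[L]:
            break
        L += 1
        fst = cur
        wall[L] = cur
    lst = cur + 1
    if L < K:
        while lst < Nh and Hlcp[lst] >= L and lst <= fst + tau:
            lst += 1
    return L, cur, fst, lst


@njit(cache=True)
def _merge_kernel(
    Gk, Glcp, Gcontig, Gpos, Hk, Hlcp, Hcontig, Hpos, Hstrand, Hclen, K, tau, min_len, stats
):  # pragma: no cover
    """Algorithm: linear adaptamer sweep of index G (forward records) over H.

    Returns hit columns (contig_g, pos_g, contig_h, pos_h, strand, t); stats
    accumulates (base comparisons, emitted adaptamer record count).
    """
    Ng = Gk.shape[0]
    Nh = Hk.shape[0]
    cap = 1024
    out = np.empty((cap, 6), np.int64)
    nout = 0
    if Ng == 0 or Nh == 0:
        return out[:0]
    wall = np.zeros(K + 1, np.int64)
    beta = np.empty(K, np.uint8)
    fst = -1
    lst = 0
    L = K
    cur = -1
    for i in range(Ng):
        for b in range(K):
            beta[b] = _base(Gk, i, b)
        lam = Glcp[i]
        if lam == L and cur < lst:
            L, cur, fst, lst = _extension(Hk, Hlcp, Nh, K, tau, beta, L, cur, fst, lst, wall, stats)
        elif lam < L:
            cur = lst
            while cur < Nh and Hlcp[cur] > lam:
                cur += 1
            L = lam
            fst = wall[lam]
            hl = Hlcp[cur] if cur < Nh else -1
            if hl == lam:
                L, cur, fst, lst = _extension(
                    Hk, Hlcp, Nh, K, tau, beta, L, cur, fst, lst, wall, stats
                )
            else:
                lst = cur
        # else lam > L: state unchanged, same adaptamer range applies
        size = lst - fst
        if L >= min_len and 1 <= size <= tau and fst >= 0:
            stats[1] += 1
            if nout + size > cap:
                while nout + size > cap:
                    cap *= 2
                grown = np.empty((cap, 6), np.int64)
                grown[:nout] = out[:nout]
                out = grown
            for j in range(fst, lst):
                out[nout, 0] = Gcontig[i]
                out[nout, 1] = Gpos[i]
                out[nout, 2] = Hcontig[j]
                if Hstrand[j] > 0:
                    out[nout, 3] = Hpos[j]
                else:
                    out[nout, 3] = Hclen[Hcontig[j]] - Hpos[j] - L
                out[nout, 4] = Hstrand[j]
                out[nout, 5] = L
                nout += 1
    return out[:nout]


def merge_indices(
    G: GenomeIndex,
    H: GenomeIndex,
    tau: Optional[int] = None,
    min_len: Optional[int] = None,
    stats: Optional[np.ndarray] = None,
) -> SeedHits:
    """All non-repetitive adaptamer matches of G (forward strand) in H.

    ``tau`` defaults to H's index tau; ``min_len`` (the shortest reported
    adaptamer) defaults to the syncmer length ``s`` -- shorter matches are
    both unreliable as seeds and partially lost to syncmer subsampling
    anyway.
    """
    if G.params.K != H.params.K:
        raise ValueError("indices were built with different K")
    if tau is None:
        tau = H.params.tau
    if min_len is None:
        min_len = G.params.s
    if stats is None:
        stats = np.zeros(2, dtype=np.int64)
    fwd_idx, fwd_lcp = G.forward_subset()
    cols = _merge_kernel(
        np.ascontiguousarray(G.kmers[fwd_idx]),
        fwd_lcp,
        G.contig[fwd_idx].astype(np.int64),
        G.pos[fwd_idx].astype(np.int64),
        H.kmers,
        H.lcp.astype(np.int64),
        H.contig.astype(np.int64),
        H.pos.astype(np.int64),
        H.strand.astype(np.int64),
        H.contig_lengths.astype(np.int64),
        G.params.K,
        tau,
        min_len,
        stats,
    )
    return SeedHits(
        contig_g=cols[:, 0].copy(),
        pos_g=cols[:, 1].copy(),
        contig_h=cols[:, 2].copy(),
        pos_h=cols[:, 3].copy(),
        strand=cols[:, 4].copy(),
        t=cols[:, 5].copy(),
    )


def symmetric_merge(
    G: GenomeIndex, H: GenomeIndex, tau: Optional[int] = None, min_len: Optional[int] = None
) -> SeedHits:
    """Union of the directed merges G-vs-H and H-vs-G.

    Adaptamers are not symmetric: the longest match starting at a G position
    need not be the longest match starting at the H position it pairs with,
    so the reverse sweep can contribute extra seed locations.  Hits from the
    H-vs-G direction are mapped into G/H frame and the union deduplicated on
    (contig_g, contig_h, pos_g, pos_h, strand), keeping the longer t.
    """
    fwd = merge_indices(G, H, tau=tau, min_len=min_len)
    rev = merge_indices(H, G, tau=tau, min_len=min_len)
    # swap roles: an H-vs-G hit (c_h, p_h) x (c_g, p_g) is the same matched
    # pair seen from the other side, on the same relative strand
    cols = np.column_stack(
        [
            np.concatenate([fwd.contig_g, rev.contig_h]),
            np.concatenate([fwd.pos_g, rev.pos_h]),
            np.concatenate([fwd.contig_h, rev.contig_g]),
            np.concatenate([fwd.pos_h, rev.pos_g]),
            np.concatenate([fwd.strand, rev.strand]),
            np.concatenate([fwd.t, rev.t]),
        ]
    )
    if len(cols) == 0:
        return fwd
    # sort so duplicates are adjacent with the longest t last, keep longest
    order = np.lexsort((cols[:, 5], cols[:, 4], cols[:, 3], cols[:, 1], cols[:, 2], cols[:, 0]))
    cols = cols[order]
    key = cols[:, [0, 2, 1, 3, 4]]
    last = np.r_[(np.diff(key, axis=0) != 0).any(axis=1), True]
    cols = cols[last]
    return SeedHits(
        contig_g=cols[:, 0].copy(),
        pos_g=cols[:, 1].copy(),
        contig_h=cols[:, 2].copy(),
        pos_h=cols[:, 3].copy(),
        strand=cols[:, 4].copy(),
        t=cols[:, 5].copy(),
    )
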