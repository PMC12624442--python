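"""Unit-cost furthest-reaching wave kernels.

Two flavours are provided:

* :func:`global_path` -- optimal unit-cost global alignment of two short
  segments with traceback, via the classic furthest-reaching wave recurrence
  (cost-d wave holds, per diagonal, the furthest row reachable with d
  differences; "snakes" of matching bases are free).  This is the workhorse
  for per-panel trace-point decoding and for deriving the exact path (and
  hence diffs) of a reported local alignment.
* :func:`extend_local` -- greedy bidirectional-capable local extension used
  by the LA-finder: waves seeded across a diagonal band on a given
  anti-diagonal, scored so the maximum-score frontier point marks the end of
  the locally similar region, and terminated once a trailing window of
  anti-diagonals has failed to improve the best score.

Alignment paths are uint8 op arrays: 0 = diagonal (match or substitution),
1 = insertion (consumes B only), 2 = deletion (consumes A only).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numba import njit

__all__ = ["global_path", "extend_local", "path_stats", "split_at_long_gaps", "path_intervals"]

OP_DIAG = 0
OP_INS = 1
OP_DEL = 2

_DEAD = np.int64(-(1 << 50))
_DEAD2 = np.int64(-(1 << 45))


@njit(cache=True)
def _global_kernel(A, B, dmax):  # pragma: no cover
    n = len(A)
    m = len(B)
    kfin = n - m
    empty = np.empty(0, np.uint8)
    if abs(kfin) > dmax:
        return empty, -1
    width = 2 * dmax + 3
    off = dmax + 1
    W = np.full((dmax + 1, width), _DEAD, np.int64)
    i = 0
    while i < n and i < m and A[i] == B[i]:
        i += 1
    W[0, off] = i
    dfin = -1
    if kfin == 0 and i >= n:
        dfin = 0
    d = 0
    while dfin < 0 and d < dmax:
        d += 1
        for k in range(-d, d + 1):
            if k < -m or k > n:
                continue
            best = _DEAD
            f = W[d - 1, k + off]
            if f > _DEAD2 and f < n and f - k < m:
                best = f + 1
            f = W[d - 1, k - 1 + off]
            if f > _DEAD2 and f < n and f + 1 > best:
                best = f + 1
            f = W[d - 1, k + 1 + off]
            if f > _DEAD2 and f - (k + 1) < m and f > best:
                best = f
            if best == _DEAD:
                continue
            i = best
            j = i - k
            while i < n and j < m and A[i] == B[j]:
                i += 1
                j += 1
            W[d, k + off] = i
            if k == kfin and i >= n:
                dfin = d
    if dfin < 0:
        return empty, -1
    # traceback: recompute the wave candidates at each step
    ops = np.empty(n + m + 2, np.uint8)
    nops = 0
    d = dfin
    k = kfin
    i = n
    while d > 0:
        c_sub = _DEAD
        c_del = _DEAD
        c_ins = _DEAD
        f = W[d - 1, k + off]
        if f > _DEAD2 and f < n and f - k < m:
            c_sub = f + 1
        f = W[d - 1, k - 1 + off]
        if f > _DEAD2 and f < n:
            c_del = f + 1
        f = W[d - 1, k + 1 + off]
        if f > _DEAD2 and f - (k + 1) < m:
            c_ins = f
        i0 = max(c_sub, max(c_del, c_ins))
        while i > i0:
            ops[nops] = 0
            nops += 1
            i -= 1
        if c_sub == i0:
            ops[nops] = 0  # substitution column
            nops += 1
            i = i0 - 1
        elif c_del == i0:
            ops[nops] = 2
            nops += 1
            i = i0 - 1
            k -= 1
        else:
            ops[nops] = 1
            nops += 1
            i = i0
            k += 1
        d -= 1
    while i > 0:
        ops[nops] = 0
        nops += 1
        i -= 1
    return ops[:nops][::-1].copy(), dfin


def global_path(A: np.ndarray, B: np.ndarray, max_diffs: int = 4096) -> Optional[Tuple[np.ndarray, int]]:
    """Optimal unit-cost global alignment path of A vs B, or None if the
    edit distance exceeds ``max_diffs`` (wave storage is O(d^2))."""
    A = np.ascontiguousarray(A, dtype=np.uint8)
    B = np.ascontiguousarray(B, dtype=np.uint8)
    d0 = 64
    while True:
        d0 = min(d0, max_diffs)
        ops, d = _global_kernel(A, B, d0)
        if d >= 0:
            return ops, int(d)
        if d0 >= max_diffs:
            return None
        d0 *= 4


@njit(cache=True)
def _extend_kernel(A, B, a0, dlo, dhi, slope, window):  # pragma: no cover
    """Forward local extension from anti-diagonal a0 across diagonals
    [dlo, dhi].  Scores frontier points as (anti-a0)/2 - slope*d and stops
    once the frontier has moved 2*window anti-diagonals past the best.

    Returns (best_i, best_j, best_score); best_i < 0 if no seed diagonal
    intersects the matrix on a0.
    """
    n = len(A)
    m = len(B)
    grow = 2048
    cap = (dhi - dlo + 1) + 2 * grow + 8
    off = grow + 4 - dlo
    F = np.full(cap, _DEAD, np.int64)
    Fn = np.full(cap, _DEAD, np.int64)
    best_score = -1.0
    best_i = np.int64(-1)
    best_j = np.int64(-1)
    best_anti = a0
    alive = False
    for k in range(dlo, dhi + 1):
        i = (a0 + k) // 2
        j = i - k
        if i < 0 or j < 0 or i > n or j > m:
            continue
        while i < n and j < m and A[i] == B[j]:
            i += 1
            j += 1
        F[k + off] = i
        alive = True
        sc = (2 * i - k - a0) / 2.0
        if sc > best_score:
            best_score = sc
            best_i = i
            best_j = i - k
            best_anti = 2 * i - k
    if not alive:
        return best_i, best_j, 0.0
    d = 0
    klo = dlo
    khi = dhi
    while True:
        d += 1
        klo -= 1
        khi += 1
        if khi + off + 1 >= cap or klo + off - 1 < 0:
            ncap = cap + 2 * grow
            noff = off + grow
            G = np.full(ncap, _DEAD, np.int64)
            G[noff + klo + 1 : noff + khi] = F[off + klo + 1 : off + khi]
            F = G
            Fn = np.full(ncap, _DEAD, np.int64)
            cap = ncap
            off = noff
        frontier = np.int64(-(1 << 60))
        alive = False
        for k in range(klo, khi + 1):
            best = _DEAD
            f = F[k + off]
            if f > _DEAD2 and f < n and f - k < m:
                best = f + 1
            f = F[k - 1 + off]
            if f > _DEAD2 and f < n and f + 1 > best:
                best = f + 1
            f = F[k + 1 + off]
            if f > _DEAD2 and f - (k + 1) < m and f > best:
                best = f
            if best == _DEAD:
                Fn[k + off] = _DEAD
                continue
            i = best
            j = i - k
            while i < n and j < m and A[i] == B[j]:
                i += 1
                j += 1
            Fn[k + off] = i
            alive = True
            anti = 2 * i - k
            if anti > frontier:
                frontier = anti
            sc = (anti - a0) / 2.0 - slope * d
            if sc > best_score:
                best_score = sc
                best_i = i
                best_j = j
                best_anti = anti
        tmp = F
        F = Fn
        Fn = tmp
        if not alive:
            break
        if frontier - best_anti > 2 * window:
            break
    return best_i, best_j, best_score


def extend_local(
    A: np.ndarray,
    B: np.ndarray,
    anti: int,
    d_low: int,
    d_high: int,
    max_divergence: float,
    window: int = 100,
) -> Tuple[int, int, float]:
    slope = 1.0 / max_divergence
    return _extend_kernel(A, B, anti, d_low, d_high, slope, window)


def path_intervals(ops: np.ndarray) -> Tuple[int, int]:
    """(A bases consumed, B bases consumed) by a path."""
    na = int((ops != OP_INS).sum())
    nb = int((ops != OP_DEL).sum())
    return na, nb


def path_stats(ops: np.ndarray, A: np.ndarray, B: np.ndarray, ab: int, bb: int) -> Tuple[int, int]:
    """(diffs, matches) of a path: indels plus mismatching diagonal columns."""
    if len(ops) == 0:
        return 0, 0
    ca = np.cumsum(ops != OP_INS)
    cb = np.cumsum(ops != OP_DEL)
    diag = ops == OP_DIAG
    ai = ab + ca[diag] - 1
    bi = bb + cb[diag] - 1
    mism = int((np.asarray(A)[ai] != np.asarray(B)[bi]).sum())
    indels = int((~diag).sum())
    return indels + mism, int(diag.sum()) - mism


def split_at_long_gaps(ops: np.ndarray, max_gap: int) -> List[Tuple[np.ndarray, int, int]]:
    """Split a path at indel runs longer than ``max_gap``.

    Returns pieces as (ops, a_offset, b_offset) with offsets the A/B bases
    consumed before the piece starts; gap runs that caused a split are not
    part of any piece.  A single piece (offset 0, 0) is returned when no gap
    exceeds the cap.
    """
    n = len(ops)
    if n == 0:
        return [(ops, 0, 0)]
    change = np.r_[True, np.diff(ops) != 0]
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:], n]
    lens = ends - starts
    vals = ops[starts]
    bad = (vals != OP_DIAG) & (lens > max_gap)
    if not bad.any():
        return [(ops, 0, 0)]
    ca = np.r_[0, np.cumsum(ops != OP_INS)]
    cb = np.r_[0, np.cumsum(ops != OP_DEL)]
    pieces = []
    at = 0
    for s, e in zip(starts[bad], ends[bad]):
        if s > at:
            pieces.append((ops[at:s], int(ca[at]), int(cb[at])))
        at = e
    if at < n:
        pieces.append((ops[at:], int(ca[at]), int(cb[at])))
    return [p for p in pieces if len(p[0])]
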