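"""Trace-point encoding of alignments and minimum-gap refinement.

An alignment of A[ab, ae] against B[bb, be] is stored as the array of
B-panel lengths <b0..bt> induced by cutting A at every multiple of the
trace-point spacing delta: panel boundaries in A are implicit, so t+1 bytes
(delta=100 keeps each b_i under 256) encode the whole path, independent of
its divergence.  Reconstruction solves one delta-by-delta sub-problem per
panel with the unit-cost wave, so it runs in O(n + delta*d) for d total
differences.  B symbols inserted exactly at a panel boundary are attributed
to the left panel.

For display and refinement a path is also representable as an *indel array*
of signed 1-based positions: +p means a dash goes before symbol p of (the
aligned slice of) A -- an inserted B base -- and -q a dash before symbol q
of B.  Runs of nearby same-sign indels are re-aligned inside their
trapezoidal region with gap-open cost 1, gap-extension cost 0 and mismatch
cost 1 (equivalent to an infinitesimal gap-open surcharge on the unit-cost
model), minimising gaps+mismatches; a single mismatch may be spent to fuse
two gaps into one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from adaptalign.wavefront import OP_DEL, OP_DIAG, OP_INS, global_path, path_intervals, path_stats

__all__ = [
    "TracePointArray",
    "Trapezoid",
    "TracePointOverflow",
    "encode_tracepoints",
    "decode_tracepoints",
    "extract_indel_array",
    "find_refinable_segments",
    "refine_segment",
    "refine_path",
    "refine_alignment",
    "path_to_cigar",
    "cigar_to_path",
    "alignment_to_cigar",
]

DEFAULT_DELTA = 100
DEFAULT_R = 50


class TracePointOverflow(ValueError):
    """A panel's B-length exceeds one byte; the caller should split the
    alignment at the offending gap."""


@dataclass
class TracePointArray:
    delta: int
    b: np.ndarray  # int32 panel B-lengths, each in [0, 255]

    @property
    def panels(self) -> int:
        return len(self.b)

    def nbytes(self) -> int:
        return len(self.b)


def panel_edges(ab: int, ae: int, delta: int) -> np.ndarray:
    """A-coordinates of the panel cuts: ab, then every multiple of delta, then ae."""
    first = (ab // delta + 1) * delta
    inner = np.arange(first, ae, delta, dtype=np.int64)
    return np.r_[ab, inner, ae]


def encode_tracepoints(
    path: np.ndarray, ab: int, ae: int, bb: int, be: int, delta: int = DEFAULT_DELTA
) -> TracePointArray:
    """Panel B-lengths of a path; raises :class:`TracePointOverflow` if a
    panel would not fit in one byte."""
    edges = panel_edges(ab, ae, delta)
    npanel = len(edges) - 1
    b = np.zeros(npanel, dtype=np.int64)
    i = ab
    p = 0
    for op in path:
        if op == OP_INS:
            # inserted B symbol: left panel when exactly on a boundary
            idx = p
            if i == edges[p] and p > 0 and i % delta == 0:
                idx = p - 1
            b[idx] += 1
        else:
            if op == OP_DIAG:
                b[p] += 1
            i += 1
            if p < npanel - 1 and i == edges[p + 1]:
                p += 1
    if i != ae:
        raise ValueError(f"path consumes {i - ab} A bases, interval has {ae - ab}")
    if int(b.sum()) != be - bb:
        raise ValueError("path B-consumption disagrees with interval")
    if (b > 255).any():
        raise TracePointOverflow(f"panel B-length {int(b.max())} exceeds 255")
    return TracePointArray(delta=delta, b=b.astype(np.int32))


def decode_tracepoints(
    tpa: TracePointArray,
    ab: int,
    ae: int,
    bb: int,
    be: int,
    Acodes: np.ndarray,
    Bcodes: np.ndarray,
) -> Tuple[np.ndarray, int]:
    """Reconstruct a path through every trace point.

    Each panel sub-problem is solved optimally under unit cost, so the total
    diffs of the reconstruction never exceed those of the encoded path.
    """
    edges = panel_edges(ab, ae, tpa.delta)
    bedges = bb + np.r_[0, np.cumsum(tpa.b.astype(np.int64))]
    if bedges[-1] != be:
        raise ValueError("sum of panel lengths disagrees with B interval")
    parts = []
    diffs = 0
    for p in range(len(edges) - 1):
        a0, a1 = int(edges[p]), int(edges[p + 1])
        b0, b1 = int(bedges[p]), int(bedges[p + 1])
        res = global_path(Acodes[a0:a1], Bcodes[b0:b1], max_diffs=4 * tpa.delta + 512)
        if res is None:  # cannot happen for byte-bounded panels
            raise RuntimeError("panel reconstruction failed")
        ops, d = res
        parts.append(ops)
        diffs += d
    path = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    return path, diffs


# ---------------------------------------------------------------------------
# indel arrays and gap refinement
# ---------------------------------------------------------------------------


def extract_indel_array(path: np.ndarray) -> np.ndarray:
    """Signed dash positions of a path (1-based within the aligned slices)."""
    if len(path) == 0:
        return np.empty(0, dtype=np.int64)
    ca = np.cumsum(path != OP_INS)
    cb = np.cumsum(path != OP_DEL)
    out = []
    for t in np.flatnonzero(path != OP_DIAG):
        if path[t] == OP_INS:
            out.append(int(ca[t]) + 1)  # dash before A symbol ca[t]+1
        else:
            out.append(-(int(cb[t]) + 1))
    return np.array(out, dtype=np.int64)


def apply_indel_array(o: np.ndarray, na: int, nb: int) -> Tuple[str, str]:
    """Padded display rows (as '*'-for-base, '-'-for-dash strings) for tests:
    dashes placed per the indel array over sequences of lengths na, nb."""
    rowa = ["*"] * na
    rowb = ["*"] * nb
    # dashes are inserted left-to-right; equal positions stack in order
    outa: List[str] = []
    outb: List[str] = []
    ia = ib = 0
    for v in o:
        if v > 0:
            while ia < v - 1:
                outa.append(rowa[ia])
                ia += 1
                outb.append(rowb[ib])
                ib += 1
            outa.append("-")
            outb.append(rowb[ib])
            ib += 1
        else:
            while ib < -v - 1:
                outa.append(rowa[ia])
                ia += 1
                outb.append(rowb[ib])
                ib += 1
            outb.append("-")
            outa.append(rowa[ia])
            ia += 1
    while ia < na:
        outa.append(rowa[ia])
        ia += 1
    while ib < nb:
        outb.append(rowb[ib])
        ib += 1
    return "".join(outa), "".join(outb)


def find_refinable_segments(o: np.ndarray, R: int = DEFAULT_R) -> List[Tuple[int, int]]:
    """Maximal index ranges [x, y] (inclusive) of the indel array such that
    all entries share a sign, y - x >= 1, and successive magnitudes differ by
    less than R.  One linear sweep."""
    segs: List[Tuple[int, int]] = []
    n = len(o)
    x = 0
    while x < n:
        y = x
        while (
            y + 1 < n
            and (o[y + 1] > 0) == (o[x] > 0)
            and abs(abs(int(o[y + 1])) - abs(int(o[y]))) < R
        ):
            y += 1
        if y > x:
            segs.append((x, y))
        x = y + 1
    return segs


@dataclass
class Trapezoid:
    """Insertion-only re-alignment region around a same-sign indel run.

    ``Aseg`` spans the L columns between the first and last insertion;
    ``Bseg`` the L + D B-symbols they consume.  Deletion runs are handled by
    mirroring (A and B swapped before construction).  After
    :func:`refine_segment`, ``waves`` holds every furthest-reaching wave and
    ``k`` the optimal gaps+mismatches count.
    """

    Aseg: np.ndarray
    Bseg: np.ndarray
    Dgaps: int
    Lspan: int
    mirrored: bool = False
    waves: Optional[List[np.ndarray]] = None
    k: int = -1


_NEG = -(1 << 40)


def _snake(A: np.ndarray, B: np.ndarray, i: int, j: int, L: int) -> int:
    s = 0
    while i + s < L and A[i + s] == B[j + s]:
        s += 1
    return s


def refine_segment(trap: Trapezoid) -> np.ndarray:
    """Minimum gaps+mismatches insertion-only path through the trapezoid.

    Wave k holds, per diagonal e (= insertions used, 0..D), the furthest A
    column reachable at cost k, where a gap opening costs 1, gap extension 0
    and a mismatch 1; snakes of matches are free.  All waves are kept for the
    traceback (a linear-space bidirectional variant is believed impossible
    for this compressed-cost wave).  Returns the op path (0 diagonal,
    1 insertion) from (0,0) to (L, L+D); also sets ``trap.k`` and
    ``trap.waves``.
    """
    A, B, D, L = trap.Aseg, trap.Bseg, trap.Dgaps, trap.Lspan
    if len(B) != L + D:
        raise ValueError("Bseg must have Lspan + Dgaps symbols")
    F = np.full(D + 1, _NEG, dtype=np.int64)
    F[0] = _snake(A, B, 0, 0, L)
    waves = [F.copy()]
    k = 0
    while F[D] < L:
        k += 1
        m = _NEG
        for e in range(D + 1):
            fe = F[e]
            i = m  # gap open from a lower diagonal, landing at its frontier
            if fe > _NEG and fe + 1 > i and fe < L:
                i = fe + 1  # mismatch along the same diagonal
            if fe > m:
                m = fe
            if i <= _NEG or i < 0 or i > L:
                F[e] = fe if fe > _NEG else _NEG
                continue
            F[e] = max(fe, i + _snake(A, B, i, i + e, L))
        waves.append(F.copy())
        if k > 2 * (D + L) + 4:
            raise RuntimeError("refinement wave failed to converge")
    trap.k = k
    trap.waves = waves
    # traceback
    ops_rev: List[int] = []
    e = D
    i = L
    while k >= 0:
        W = waves[k]
        Wp = waves[k - 1] if k > 0 else None
        if k == 0:
            # cost-0: pure snake along diagonal 0
            ops_rev.extend([OP_DIAG] * i)
            if e != 0:
                raise RuntimeError("traceback stranded off diagonal 0")
            break
        # find the snake start for the wave that first reached (e, >= i)
        m = _NEG
        arg = -1
        for ee in range(e):
            if Wp[ee] > m:
                m = Wp[ee]
                arg = ee
        c_sub = Wp[e] + 1 if (Wp[e] > _NEG and Wp[e] < L) else _NEG
        i0 = max(m, c_sub)
        v = i0 + _snake(A, B, i0, i0 + e, L) if i0 > _NEG and 0 <= i0 <= L else _NEG
        if i0 <= _NEG or i0 > i or i > v:
            # wave k did not produce this point: it was already reachable at
            # cost k-1 on this diagonal (the frontier is carried forward)
            k -= 1
            continue
        ops_rev.extend([OP_DIAG] * (i - i0))
        if c_sub == i0 and c_sub >= m:
            ops_rev.append(OP_DIAG)  # the mismatch column
            i = i0 - 1
        else:
            # gap: e - arg insertions opened at column i0
            ops_rev.extend([OP_INS] * (e - arg))
            e = arg
            i = i0
        k -= 1
    path = np.array(ops_rev[::-1], dtype=np.uint8)
    na, nb = path_intervals(path)
    if na != L or nb != L + D:
        raise RuntimeError("refined path does not span the trapezoid")
    return path


def _segment_path_range(path: np.ndarray, sign: int, x: int, y: int) -> Tuple[int, int]:
    """Op-index range [q_x, q_y] of the x-th..y-th indels of the given sign's
    op code in the path (counting all indels in array order)."""
    idx = np.flatnonzero(path != OP_DIAG)
    return int(idx[x]), int(idx[y])


def refine_path(
    path: np.ndarray,
    ab: int,
    bb: int,
    Acodes: np.ndarray,
    Bcodes: np.ndarray,
    R: int = DEFAULT_R,
) -> np.ndarray:
    """Apply minimum-gap refinement to every refinable indel run of a path."""
    o = extract_indel_array(path)
    segs = find_refinable_segments(o, R)
    if not segs:
        return path
    new = path.copy()
    # process right-to-left so earlier op indices stay valid
    for x, y in reversed(segs):
        qx, qy = _segment_path_range(new, 1 if o[x] > 0 else -1, x, y)
        sub = new[qx : qy + 1]
        ca = int((new[:qx] != OP_INS).sum())
        cb = int((new[:qx] != OP_DEL).sum())
        na, nb = path_intervals(sub)
        if o[x] > 0:
            # insertion run: D extra B symbols over L = na columns
            D = int((sub == OP_INS).sum())
            L = na
            if nb != L + D:
                continue  # mixed run (should not happen): leave untouched
            trap = Trapezoid(
                Aseg=np.asarray(Acodes)[ab + ca : ab + ca + L],
                Bseg=np.asarray(Bcodes)[bb + cb : bb + cb + L + D],
                Dgaps=D,
                Lspan=L,
            )
            repl = refine_segment(trap)
        else:
            D = int((sub == OP_DEL).sum())
            L = nb
            if na != L + D:
                continue
            trap = Trapezoid(
                Aseg=np.asarray(Bcodes)[bb + cb : bb + cb + L],
                Bseg=np.asarray(Acodes)[ab + ca : ab + ca + L + D],
                Dgaps=D,
                Lspan=L,
                mirrored=True,
            )
            repl = refine_segment(trap)
            repl = np.where(repl == OP_INS, np.uint8(OP_DEL), repl).astype(np.uint8)
        new = np.concatenate([new[:qx], repl, new[qy + 1 :]])
    return new


def count_gaps(path: np.ndarray) -> int:
    """Number of maximal indel runs (gap openings) in a path."""
    if len(path) == 0:
        return 0
    change = np.r_[True, np.diff(path) != 0]
    starts = np.flatnonzero(change)
    return int((path[starts] != OP_DIAG).sum())


def refine_alignment(aln, Acodes: np.ndarray, Bcodes: np.ndarray, R: int = DEFAULT_R):
    """Return a copy of ``aln`` with its path refined to fewer gaps.

    Endpoints are preserved; diffs are recomputed from the revised path (a
    mismatch may have been traded for a gap).  ``aln`` needs fields
    ab/ae/bb/be/diffs/path and optionally tracepoints.
    """
    path = aln.path
    if path is None:
        if aln.tracepoints is None:
            raise ValueError("alignment has neither path nor tracepoints")
        path, _ = decode_tracepoints(
            aln.tracepoints, aln.ab, aln.ae, aln.bb, aln.be, Acodes, Bcodes
        )
    new_path = refine_path(path, aln.ab, aln.bb, Acodes, Bcodes, R)
    out = copy.copy(aln)
    out.path = new_path
    out.diffs, _ = path_stats(new_path, Acodes, Bcodes, aln.ab, aln.bb)
    if aln.tracepoints is not None:
        out.tracepoints = encode_tracepoints(
            new_path, aln.ab, aln.ae, aln.bb, aln.be, aln.tracepoints.delta
        )
    return out


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------


def path_to_cigar(
    path: np.ndarray,
    Acodes: np.ndarray,
    Bcodes: np.ndarray,
    ab: int,
    bb: int,
    dialect: str = "=X",
) -> str:
    """CIGAR string of a path.  A is the query/first sequence (I consumes B:
    the target gains a base relative to A, emitted as 'I' on ... ); dialect
    '=X' distinguishes matches from substitutions, 'M' merges them."""
    if dialect not in ("=X", "M"):
        raise ValueError("dialect must be '=X' or 'M'")
    if len(path) == 0:
        return ""
    ca = np.cumsum(path != OP_INS)
    cb = np.cumsum(path != OP_DEL)
    sym = np.empty(len(path), dtype="<U1")
    diag = path == OP_DIAG
    if dialect == "M":
        sym[diag] = "M"
    else:
        ai = ab + ca[diag] - 1
        bi = bb + cb[diag] - 1
        eq = np.asarray(Acodes)[ai] == np.asarray(Bcodes)[bi]
        sym[diag] = np.where(eq, "=", "X")
    sym[path == OP_INS] = "I"
    sym[path == OP_DEL] = "D"
    out = []
    run = 1
    for t in range(1, len(sym) + 1):
        if t < len(sym) and sym[t] == sym[t - 1]:
            run += 1
        else:
            out.append(f"{run}{sym[t - 1]}")
            run = 1
    return "".join(out)


def cigar_to_path(cigar: str) -> np.ndarray:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch in "M=X":
                ops.extend([OP_DIAG] * n)
            elif ch == "I":
                ops.extend([OP_INS] * n)
            elif ch == "D":
                ops.extend([OP_DEL] * n)
            else:
                raise ValueError(f"unsupported CIGAR op {ch!r}")
    return np.array(ops, dtype=np.uint8)


def alignment_to_cigar(aln, Acodes: np.ndarray, Bcodes: np.ndarray, dialect: str = "=X") -> str:
    """CIGAR of an alignment, decoding from trace points if the path is absent."""
    path = aln.path
    if path is None:
        path, _ = decode_tracepoints(
            aln.tracepoints, aln.ab, aln.ae, aln.bb, aln.be, Acodes, Bcodes
        )
    return path_to_cigar(path, Acodes, Bcodes, aln.ab, aln.bb, dialect)
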