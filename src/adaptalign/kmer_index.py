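"""Genome indices: sorted syncmer-led K-mers with an lcp array.

The index of a genome is the list of all K-mers of the genome *and its
complement strand* whose first ``s`` bases form a closed (s,m) syncmer and
which occur fewer than ``tau`` times in total, sorted by 2-bit packed K-mer
value, together with the length of the longest common prefix (lcp) of each
record with its predecessor.  Sorted list + lcp array behave as a suffix
array truncated at depth K, which is all the downstream adaptamer merge
needs.

The sort is a most-significant-digit radix sort over one-byte digits of the
packed K-mer, refined in three ways: a sub-array whose current digit takes a
single value is advanced to the next digit without any data movement; only
non-empty partitions are visited when permuting; and records already inside
their target partition are never moved.  The lcp array falls out of the sort:
when a sub-array at byte depth ``d`` splits, the first record of each
partition ``p`` differs from its predecessor (last record of the previous
non-empty partition ``q``) exactly at byte ``d``, giving an lcp of
``4d + 3 - floor(log4(p XOR q))`` bases for 2-bit packed DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from numba import njit

from adaptalign.genome_db import (
    GenomeDB,
    codes_to_seq,
    pack_codes,
    rc_codes,
    seq_to_codes,
    unpack_codes,
)

__all__ = [
    "IndexParams",
    "GenomeIndex",
    "phi_value",
    "canonical_value",
    "is_closed_syncmer",
    "syncmer_positions",
    "msd_radix_sort_with_lcp",
    "build_index",
    "write_gix",
    "read_gix",
]


@dataclass(frozen=True)
class IndexParams:
    """K-mer index parameters.

    K is the (maximum) seed length in bases; the first ``s`` bases of a K-mer
    must form a closed (s,m) syncmer for the K-mer to be indexed; K-mers
    occurring ``tau`` or more times in the genome (both strands pooled) are
    dropped as repetitive.
    """

    K: int = 40
    s: int = 12
    m: int = 8
    tau: int = 10

    def __post_init__(self) -> None:
        if not (self.m < self.s <= self.K):
            raise ValueError("require m < s <= K")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    @property
    def kbytes(self) -> int:
        return (self.K + 3) // 4


# ---------------------------------------------------------------------------
# phi / canonical values and closed syncmers
# ---------------------------------------------------------------------------


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return seq_to_codes(seq)
    return np.asarray(seq, dtype=np.uint8)


def phi_value(seq) -> int:
    """Integer value of a DNA string: big-endian base 4 with a<c<g<t.

    Order-isomorphic to lexicographic order on equal-length strings.
    """
    codes = _as_codes(seq)
    v = 0
    for c in codes:
        v = v * 4 + int(c)
    return v


def canonical_value(seq) -> int:
    """Canonical value: min of the phi values of the string and its complement."""
    codes = _as_codes(seq)
    return min(phi_value(codes), phi_value(rc_codes(codes)))


def _canonical_mmer_values(codes: np.ndarray, m: int) -> np.ndarray:
    """Canonical values of every m-mer of ``codes`` (vectorised)."""
    n = len(codes) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    rvals = np.zeros(n, dtype=np.int64)
    c = codes.astype(np.int64)
    for k in range(m):
        vals += c[k : k + n] * 4 ** (m - 1 - k)
        rvals += (3 - c[k : k + n]) * 4**k
    return np.minimum(vals, rvals)


def is_closed_syncmer(kmer, s: int, m: int) -> bool:
    """Is the s-prefix of ``kmer`` a closed (s,m) syncmer?

    True iff the minimum canonical m-mer value over the s-prefix is attained
    by the first or the last m-mer window.
    """
    codes = _as_codes(kmer)
    if not (m < s):
        raise ValueError("require m < s")
    if len(codes) < s:
        raise ValueError(f"k-mer of length {len(codes)} shorter than s={s}")
    canon = _canonical_mmer_values(codes[:s], m)
    return bool(min(canon[0], canon[-1]) == canon.min())


def syncmer_positions(codes: np.ndarray, s: int, m: int, max_start: Optional[int] = None) -> np.ndarray:
    """Start positions p (0 <= p <= max_start) whose s-mer is a closed syncmer.

    ``max_start`` defaults to ``len(codes) - s``; the index builder passes
    ``len(codes) - K`` so that the full K-mer fits.
    """
    if max_start is None:
        max_start = len(codes) - s
    if max_start < 0:
        return np.empty(0, dtype=np.int64)
    canon = _canonical_mmer_values(codes, m)
    win = s - m + 1  # number of m-mer windows inside an s-mer
    sw = np.lib.stride_tricks.sliding_window_view(canon, win)
    winmin = sw.min(axis=1)
    closed = np.minimum(canon[: len(winmin)], canon[win - 1 : win - 1 + len(winmin)]) == winmin
    pos = np.flatnonzero(closed[: max_start + 1])
    return pos.astype(np.int64)


# ---------------------------------------------------------------------------
# MSD radix sort with lcp side-computation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _msd_sort_kernel(a, key_w, lcp_d, lcp_p, lcp_q, stats):  # pragma: no cover
    """In-place MSD radix sort of the rows of ``a`` on the first key_w bytes.

    lcp_d[i] receives the byte depth at which row i first differs from its
    predecessor (left at key_w when they are equal on the key), and
    lcp_p/lcp_q the differing byte values.  stats[0] counts row moves,
    stats[1] partitioning passes.
    """
    N = a.shape[0]
    W = a.shape[1]
    if N < 2:
        return
    cap = (key_w + 2) * 257 + 64
    stack = np.empty((cap, 3), np.int64)
    top = 0
    stack[0, 0] = 0
    stack[0, 1] = N
    stack[0, 2] = 0
    top = 1
    count = np.zeros(256, np.int64)
    start = np.empty(256, np.int64)
    fing = np.empty(256, np.int64)
    tmp = np.empty(W, np.uint8)
    while top > 0:
        top -= 1
        lo = stack[top, 0]
        hi = stack[top, 1]
        d = stack[top, 2]
        while hi - lo >= 2 and d < key_w:
            for x in range(256):
                count[x] = 0
            for i in range(lo, hi):
                count[a[i, d]] += 1
            stats[1] += 1
            nonempty = 0
            for x in range(256):
                if count[x] > 0:
                    nonempty += 1
            if nonempty == 1:
                # all records share this digit: advance depth, move nothing
                d += 1
                continue
            off = lo
            for x in range(256):
                start[x] = off
                fing[x] = off
                off += count[x]
            for x in range(256):
                if count[x] == 0:
                    continue
                end_x = start[x] + count[x]
                while fing[x] < end_x:
                    y = a[fing[x], d]
                    if y == x:
                        fing[x] += 1  # already in its partition: no move
                    else:
                        i = fing[x]
                        j = fing[y]
                        for w in range(W):
                            tmp[w] = a[i, w]
                            a[i, w] = a[j, w]
                            a[j, w] = tmp[w]
                        fing[y] += 1
                        stats[0] += 1
            # lcp at each boundary between consecutive non-empty partitions
            prev = -1
            for x in range(256):
                if count[x] > 0:
                    if prev >= 0:
                        b = start[x]
                        lcp_d[b] = d
                        lcp_p[b] = x
                        lcp_q[b] = prev
                    prev = x
            # recurse into partitions of size >= 2
            for x in range(256):
                if count[x] >= 2 and d + 1 < key_w:
                    stack[top, 0] = start[x]
                    stack[top, 1] = start[x] + count[x]
                    stack[top, 2] = d + 1
                    top += 1
            break


def _boundary_lcp_bases(lcp_d, lcp_p, lcp_q, kbases: int) -> np.ndarray:
    """Convert byte-depth boundaries to base-resolution lcps.

    At a boundary at byte depth d between partition bytes q < p, the packed
    2-bit strings share ``4d + 3 - floor(log4(p XOR q))`` bases.
    """
    x = (lcp_p ^ lcp_q).astype(np.int64)
    log4 = np.zeros_like(x)
    nz = x > 0
    log4[nz] = (np.int64(np.floor(np.log2(x[nz]))) // 2).astype(np.int64)
    lcp = 4 * lcp_d.astype(np.int64) + 3 - log4
    boundary = lcp_d < np.iinfo(lcp_d.dtype).max
    out = np.where(boundary, lcp, kbases)
    return np.minimum(out, kbases)


def msd_radix_sort_with_lcp(
    items: Union[np.ndarray, List[bytes]],
    key_width: Optional[int] = None,
    unit: str = "bytes",
    kbases: Optional[int] = None,
    stats: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sort fixed-width byte strings and return the lcp-with-predecessor array.

    Parameters
    ----------
    items : (N, W) uint8 array or list of equal-length byte strings.
        Rows are sorted on their first ``key_width`` bytes (default: all W).
    unit : "bytes" or "bases".
        "bases" interprets the key as 2-bit packed DNA and reports lcps in
        bases (capped at ``kbases``); "bytes" reports whole common bytes.
    stats : optional int64[2] array; receives (rows moved, partition passes).

    Returns (sorted array, lcp) where ``lcp[0] == 0`` and ``lcp[i]`` is the
    common-prefix length of rows i-1 and i.
    """
    if isinstance(items, (list, tuple)):
        widths = {len(b) for b in items}
        if len(widths) > 1:
            raise ValueError("ragged item widths")
        arr = np.frombuffer(b"".join(items), dtype=np.uint8).reshape(len(items), -1).copy() \
            if items else np.empty((0, 0), dtype=np.uint8)
    else:
        arr = np.ascontiguousarray(items, dtype=np.uint8).copy()
    n, w = arr.shape if arr.ndim == 2 else (0, 0)
    kw = w if key_width is None else key_width
    if kw > w:
        raise ValueError("key_width exceeds item width")
    lcp_d = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
    lcp_p = np.zeros(n, dtype=np.uint8)
    lcp_q = np.zeros(n, dtype=np.uint8)
    if stats is None:
        stats = np.zeros(2, dtype=np.int64)
    if n >= 2:
        _msd_sort_kernel(arr, kw, lcp_d, lcp_p, lcp_q, stats)
    if unit == "bytes":
        lcp = np.where(lcp_d < np.iinfo(np.int32).max, lcp_d, kw).astype(np.int64)
    elif unit == "bases":
        kb = 4 * kw if kbases is None else kbases
        lcp = _boundary_lcp_bases(lcp_d, lcp_p, lcp_q, kb)
    else:
        raise ValueError(f"unknown lcp unit {unit!r}")
    if n:
        lcp[0] = 0
    return arr, lcp


# ---------------------------------------------------------------------------
# index construction
# ---------------------------------------------------------------------------


@dataclass
class GenomeIndex:
    """Sorted K-mer records (both strands) with lcp array.

    ``kmers[i]`` is the 2-bit packed K-mer; ``pos[i]`` is the 0-based start of
    the K-mer *on its own strand* (for strand -1 that is a position in the
    reverse-complemented contig); ``lcp[i]`` is the common prefix, in bases,
    with record i-1.
    """

    params: IndexParams
    kmers: np.ndarray  # (N, kbytes) uint8
    contig: np.ndarray  # (N,) int32
    pos: np.ndarray  # (N,) int32
    strand: np.ndarray  # (N,) int8, +1 forward / -1 complement
    lcp: np.ndarray  # (N,) int16
    contig_lengths: np.ndarray  # per-contig lengths of the source genome

    @property
    def n(self) -> int:
        return len(self.pos)

    def kmer_codes(self, i: int) -> np.ndarray:
        return unpack_codes(self.kmers[i], self.params.K)

    def kmer_string(self, i: int) -> str:
        return codes_to_seq(self.kmer_codes(i))

    def forward_subset(self) -> Tuple[np.ndarray, np.ndarray]:
        """Indices of forward-strand records and their lcp relative to the
        previous *forward* record (the running minimum over skipped records)."""
        idx = np.flatnonzero(self.strand > 0).astype(np.int64)
        adj = _forward_lcp(self.lcp.astype(np.int64), self.strand.astype(np.int8))
        return idx, adj


@njit(cache=True)
def _forward_lcp(lcp, strand):  # pragma: no cover
    n = len(lcp)
    nf = 0
    for i in range(n):
        if strand[i] > 0:
            nf += 1
    out = np.empty(nf, np.int64)
    k = 0
    run = 1 << 30
    seen = False
    for i in range(n):
        run = min(run, lcp[i])
        if strand[i] > 0:
            out[k] = run if seen else 0
            k += 1
            seen = True
            run = 1 << 30
    return out


def _pack_kmer_rows(codes: np.ndarray, positions: np.ndarray, K: int) -> np.ndarray:
    """Pack the K-mers starting at ``positions`` into (n, kbytes) uint8 rows."""
    kb = (K + 3) // 4
    npos = len(positions)
    out = np.zeros((npos, kb), dtype=np.uint8)
    if npos == 0:
        return out
    win = np.lib.stride_tricks.sliding_window_view(codes, K)[positions]
    for j in range(kb):
        for q in range(4):
            b = 4 * j + q
            if b < K:
                out[:, j] |= (win[:, b] << (6 - 2 * q)).astype(np.uint8)
    return out


@njit(cache=True)
def _refilter_lcp(lcp, keep):  # pragma: no cover
    """lcp of each kept record relative to the previous kept record."""
    n = len(lcp)
    nk = 0
    for i in range(n):
        if keep[i]:
            nk += 1
    out = np.empty(nk, np.int64)
    k = 0
    run = 1 << 30
    seen = False
    for i in range(n):
        run = min(run, lcp[i])
        if keep[i]:
            out[k] = run if seen else 0
            k += 1
            seen = True
            run = 1 << 30
    return out


def build_index(gdb: GenomeDB, params: IndexParams = IndexParams()) -> GenomeIndex:
    """Build the genome index of every syncmer-led K-mer on both strands.

    A K-mer is indexed iff its first ``s`` bases are a closed (s,m) syncmer;
    K-mers occurring ``tau`` or more times in the pooled two-strand record
    list are removed as repetitive (the merge applies the occurrence cap on
    the other genome separately).  Contigs shorter than K are skipped with a
    warning.
    """
    K, kb = params.K, params.kbytes
    blocks = []
    meta = []
    for cid, contig in enumerate(gdb.contigs):
        if contig.length < K:
            warnings.warn(
                f"contig {contig.scaffold_id}.{contig.contig_ordinal} shorter than K={K}: skipped"
            )
            continue
        codes = contig.codes()
        for strand, strand_codes in ((1, codes), (-1, rc_codes(codes))):
            pos = syncmer_positions(strand_codes, params.s, params.m, max_start=contig.length - K)
            blocks.append(_pack_kmer_rows(strand_codes, pos, K))
            meta.append((cid, strand, pos))
    ntot = sum(len(b) for b in blocks)
    rec = np.zeros((ntot, kb + 9), dtype=np.uint8)
    contig_arr = np.empty(ntot, dtype=np.int32)
    pos_arr = np.empty(ntot, dtype=np.int32)
    strand_arr = np.empty(ntot, dtype=np.int8)
    at = 0
    for block, (cid, strand, pos) in zip(blocks, meta):
        nb = len(block)
        rec[at : at + nb, :kb] = block
        contig_arr[at : at + nb] = cid
        pos_arr[at : at + nb] = pos
        strand_arr[at : at + nb] = strand
        at += nb
    # payload bytes: contig (4, big-endian), pos (4), strand flag (1)
    payload = rec[:, kb:]
    payload[:, 0:4] = (
        contig_arr.astype(np.uint32).byteswap().view(np.uint8).reshape(-1, 4)
    )
    payload[:, 4:8] = pos_arr.astype(np.uint32).byteswap().view(np.uint8).reshape(-1, 4)
    payload[:, 8] = (strand_arr < 0).astype(np.uint8)
    sorted_rec, lcp = msd_radix_sort_with_lcp(rec, key_width=kb, unit="bases", kbases=K)
    contig_arr = (
        sorted_rec[:, kb : kb + 4].copy().view(np.uint32).byteswap().reshape(-1).astype(np.int32)
    )
    pos_arr = (
        sorted_rec[:, kb + 4 : kb + 8].copy().view(np.uint32).byteswap().reshape(-1).astype(np.int32)
    )
    strand_arr = np.where(sorted_rec[:, kb + 8] > 0, -1, 1).astype(np.int8)
    kmers = np.ascontiguousarray(sorted_rec[:, :kb])
    # repetitive-K-mer filter: drop runs occurring >= tau times
    if ntot:
        run_id = np.cumsum(lcp < K)  # lcp == K <=> identical to predecessor
        run_sizes = np.bincount(run_id)
        keep = run_sizes[run_id] < params.tau
        new_lcp = _refilter_lcp(lcp.astype(np.int64), keep)
        kmers = np.ascontiguousarray(kmers[keep])
        contig_arr = contig_arr[keep]
        pos_arr = pos_arr[keep]
        strand_arr = strand_arr[keep]
        lcp = new_lcp
    return GenomeIndex(
        params=params,
        kmers=kmers,
        contig=contig_arr,
        pos=pos_arr,
        strand=strand_arr,
        lcp=lcp.astype(np.int16),
        contig_lengths=gdb.contig_lengths,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_gix(index: GenomeIndex, path, command: str = "gixmake") -> None:
    from adaptalign.onecode import OneDocument, write_one

    doc = OneDocument(
        filetype="gix",
        schema={
            "P": "int:K int:s int:m int:tau",
            "C": "intlist:contig_lengths",
            "R": "str:kmer int:contig int:pos int:strand int:lcp",
        },
    )
    doc.stamp(command)
    doc.add("P", index.params.K, index.params.s, index.params.m, index.params.tau)
    doc.add("C", [int(x) for x in index.contig_lengths])
    for i in range(index.n):
        doc.add(
            "R",
            index.kmer_string(i),
            int(index.contig[i]),
            int(index.pos[i]),
            int(index.strand[i]),
            int(index.lcp[i]),
        )
    write_one(doc, path)


def read_gix(path) -> GenomeIndex:
    from adaptalign.onecode import read_one

    doc = read_one(path, list_codes={"C": 0})
    K = s = m = tau = None
    clens: List[int] = []
    rows = []
    for code, vals in doc.lines:
        if code == "P":
            K, s, m, tau = (int(v) for v in vals)
        elif code == "C":
            clens = list(vals[0])
        elif code == "R":
            rows.append(vals)
    params = IndexParams(K=K, s=s, m=m, tau=tau)
    n = len(rows)
    kmers = np.zeros((n, params.kbytes), dtype=np.uint8)
    contig = np.empty(n, dtype=np.int32)
    pos = np.empty(n, dtype=np.int32)
    strand = np.empty(n, dtype=np.int8)
    lcp = np.empty(n, dtype=np.int16)
    for i, (kstr, c, p, st, l) in enumerate(rows):
        kmers[i] = pack_codes(seq_to_codes(kstr))[: params.kbytes]
        contig[i], pos[i], strand[i], lcp[i] = int(c), int(p), int(st), int(l)
    return GenomeIndex(
        params=params,
        kmers=kmers,
        contig=contig,
        pos=pos,
        strand=strand,
        lcp=lcp,
        contig_lengths=np.array(clens, dtype=np.int64),
    )
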