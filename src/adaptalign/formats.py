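"""Alignment output: PAF, PSL and the ASCII ALN document.

PAF rows carry the 12 mandatory columns (query = first genome, forward;
target intervals always in forward coordinates, strand '-' when the match is
to the reverse complement) plus ``NM:i`` (differences) and optionally a
``cg:Z`` CIGAR in either the 'M' or the '=X' dialect.  PSL is the classic
21-column format with per-block coordinates (for strand '-' the tStarts are
in reverse-complement frame, as BLAT emits them).  The ALN document keeps
the space-efficient trace-point encoding -- each list stored as its first
value followed by forward differences -- so its size is essentially one byte
per delta of alignment, independent of divergence, where a CIGAR grows with
the difference count.  Gap refinement (fewest-gaps form of the same
unit-cost alignment) is applied when paths are materialised for CIGAR/PSL
output, matching how alignments are reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from adaptalign.align import Alignment
from adaptalign.genome_db import GenomeDB
from adaptalign.onecode import OneDocument, read_one, write_one
from adaptalign.tracepoint import (
    TracePointArray,
    decode_tracepoints,
    path_to_cigar,
    refine_path,
)
from adaptalign.wavefront import OP_DEL, OP_DIAG, OP_INS, path_stats

__all__ = ["AlnRecord", "to_records", "write_paf", "write_psl", "write_aln", "read_aln"]


@dataclass
class AlnRecord:
    """A reported alignment in scaffold coordinates (all forward)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str  # '+' or '-'
    tname: str
    tlen: int
    tstart: int
    tend: int
    diffs: int
    matches: int
    blocklen: int
    tracepoints: Optional[TracePointArray] = None
    path: Optional[np.ndarray] = None  # contig-frame path (A fwd vs oriented B)


def _materialise_path(aln: Alignment, gdbG: GenomeDB, gdbH: GenomeDB, refine: bool):
    from adaptalign.genome_db import rc_codes

    A = gdbG.contigs[aln.contig_g].codes()
    B = gdbH.contigs[aln.contig_h].codes()
    if aln.strand < 0:
        B = rc_codes(B)
    path = aln.path
    if path is None:
        if aln.tracepoints is None:
            return None, A, B
        path, _ = decode_tracepoints(aln.tracepoints, aln.ab, aln.ae, aln.bb, aln.be, A, B)
    if refine:
        path = refine_path(path, aln.ab, aln.bb, A, B)
    return path, A, B


def to_records(
    alignments: Iterable[Alignment],
    gdbG: GenomeDB,
    gdbH: GenomeDB,
    refine: bool = True,
) -> List[AlnRecord]:
    """Convert contig-frame alignments to scaffold-frame records."""
    out = []
    for aln in alignments:
        cg = gdbG.contigs[aln.contig_g]
        ch = gdbH.contigs[aln.contig_h]
        sg = gdbG.scaffold_of(aln.contig_g)
        sh = gdbH.scaffold_of(aln.contig_h)
        qstart = cg.offset_in_scaffold + aln.ab
        qend = cg.offset_in_scaffold + aln.ae
        if aln.strand > 0:
            tstart = ch.offset_in_scaffold + aln.bb
            tend = ch.offset_in_scaffold + aln.be
        else:
            tstart = ch.offset_in_scaffold + ch.length - aln.be
            tend = ch.offset_in_scaffold + ch.length - aln.bb
        path, A, B = _materialise_path(aln, gdbG, gdbH, refine)
        if path is not None:
            diffs, matches = path_stats(path, A, B, aln.ab, aln.bb)
            blocklen = len(path)
        else:
            diffs = aln.diffs
            blocklen = max(aln.ae - aln.ab, aln.be - aln.bb)
            matches = blocklen - diffs
        out.append(
            AlnRecord(
                qname=sg.name,
                qlen=sg.length,
                qstart=qstart,
                qend=qend,
                strand="+" if aln.strand > 0 else "-",
                tname=sh.name,
                tlen=sh.length,
                tstart=tstart,
                tend=tend,
                diffs=diffs,
                matches=matches,
                blocklen=blocklen,
                tracepoints=aln.tracepoints,
                path=path,
            )
        )
    return out


def write_paf(
    alignments: Sequence[Alignment],
    gdbG: GenomeDB,
    gdbH: GenomeDB,
    out: TextIO,
    cigar: Optional[str] = "=X",
    refine: bool = True,
) -> None:
    """Stream alignments as PAF.  ``cigar`` is '=X', 'M', or None."""
    from adaptalign.genome_db import rc_codes

    for aln, rec in zip(alignments, to_records(alignments, gdbG, gdbH, refine=refine)):
        cols = [
            rec.qname,
            rec.qlen,
            rec.qstart,
            rec.qend,
            rec.strand,
            rec.tname,
            rec.tlen,
            rec.tstart,
            rec.tend,
            rec.matches,
            rec.blocklen,
            255,
        ]
        tags = [f"NM:i:{rec.diffs}"]
        if cigar is not None and rec.path is not None:
            A = gdbG.contigs[aln.contig_g].codes()
            B = gdbH.contigs[aln.contig_h].codes()
            if aln.strand < 0:
                B = rc_codes(B)
            tags.append("cg:Z:" + path_to_cigar(rec.path, A, B, aln.ab, aln.bb, cigar))
        out.write("\t".join(str(c) for c in cols + tags) + "\n")


def _blocks(path: np.ndarray, ab: int, bb: int) -> List[Tuple[int, int, int]]:
    """Gap-free blocks of a path as (size, a_start, b_start), contig frame."""
    blocks = []
    i, j = ab, bb
    run = 0
    ra, rb = i, j
    for op in path:
        if op == OP_DIAG:
            if run == 0:
                ra, rb = i, j
            run += 1
            i += 1
            j += 1
        else:
            if run:
                blocks.append((run, ra, rb))
                run = 0
            if op == OP_INS:
                j += 1
            else:
                i += 1
    if run:
        blocks.append((run, ra, rb))
    return blocks


def write_psl(
    alignments: Sequence[Alignment],
    gdbG: GenomeDB,
    gdbH: GenomeDB,
    out: TextIO,
    refine: bool = True,
) -> None:
    """Stream alignments as 21-column PSL (block-resolved)."""
    for aln, rec in zip(alignments, to_records(alignments, gdbG, gdbH, refine=refine)):
        if rec.path is None:
            raise ValueError("PSL output requires decoded paths")
        path = rec.path
        mism = rec.blocklen - rec.matches - int((path != OP_DIAG).sum())
        q_ins_runs = t_ins_runs = q_ins_bases = t_ins_bases = 0
        prev = OP_DIAG
        for op in path:
            if op == OP_INS:  # target has extra bases
                t_ins_bases += 1
                if prev != OP_INS:
                    t_ins_runs += 1
            elif op == OP_DEL:  # query has extra bases
                q_ins_bases += 1
                if prev != OP_DEL:
                    q_ins_runs += 1
            prev = op
        cg = gdbG.contigs[aln.contig_g]
        ch = gdbH.contigs[aln.contig_h]
        blocks = _blocks(path, cg.offset_in_scaffold + aln.ab, ch.offset_in_scaffold + aln.bb)
        sizes = ",".join(str(b[0]) for b in blocks) + ","
        qstarts = ",".join(str(b[1]) for b in blocks) + ","
        tstarts = ",".join(str(b[2]) for b in blocks) + ","
        cols = [
            rec.matches,
            mism,
            0,
            0,
            q_ins_runs,
            q_ins_bases,
            t_ins_runs,
            t_ins_bases,
            rec.strand,
            rec.qname,
            rec.qlen,
            rec.qstart,
            rec.qend,
            rec.tname,
            rec.tlen,
            rec.tstart,
            rec.tend,
            len(blocks),
            sizes,
            qstarts,
            tstarts,
        ]
        out.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# ALN document
# ---------------------------------------------------------------------------

_ALN_SCHEMA = {
    "X": "int:tracepoint_spacing",
    "A": "str:qname int:qlen int:qstart int:qend str:strand str:tname int:tlen int:tstart int:tend",
    "D": "int:diffs int:matches int:blocklen",
    "T": "intlist:tracepoints_first_forward_diff",
}


def write_aln(
    records: Sequence[AlnRecord], path, delta: int = 100, command: str = "adaptalign"
) -> None:
    """Write alignment records as an ASCII ALN document.

    Trace-point lists are stored as the first value followed by forward
    differences.  All records must share the document's delta.
    """
    doc = OneDocument(filetype="aln", schema=dict(_ALN_SCHEMA))
    doc.stamp(command)
    doc.add("X", int(delta))
    for rec in records:
        doc.add(
            "A",
            rec.qname,
            rec.qlen,
            rec.qstart,
            rec.qend,
            rec.strand,
            rec.tname,
            rec.tlen,
            rec.tstart,
            rec.tend,
        )
        doc.add("D", rec.diffs, rec.matches, rec.blocklen)
        if rec.tracepoints is not None:
            if rec.tracepoints.delta != delta:
                raise ValueError(
                    f"record delta {rec.tracepoints.delta} != document delta {delta}"
                )
            b = rec.tracepoints.b.astype(np.int64)
            ff = np.r_[b[:1], np.diff(b)] if len(b) else b
            doc.add("T", [int(x) for x in ff])
    write_one(doc, path)


def read_aln(path) -> Tuple[List[AlnRecord], int]:
    """Read an ALN document back into records (field-for-field)."""
    doc = read_one(path, list_codes={"T": 0})
    if doc.filetype != "aln":
        raise ValueError(f"not an aln document: {doc.filetype!r}")
    delta = 100
    records: List[AlnRecord] = []
    cur: Optional[AlnRecord] = None
    for code, vals in doc.lines:
        if code == "X":
            delta = int(vals[0])
        elif code == "A":
            cur = AlnRecord(
                qname=str(vals[0]),
                qlen=int(vals[1]),
                qstart=int(vals[2]),
                qend=int(vals[3]),
                strand=str(vals[4]),
                tname=str(vals[5]),
                tlen=int(vals[6]),
                tstart=int(vals[7]),
                tend=int(vals[8]),
                diffs=0,
                matches=0,
                blocklen=0,
            )
            records.append(cur)
        elif code == "D":
            cur.diffs, cur.matches, cur.blocklen = (int(v) for v in vals)
        elif code == "T":
            ff = np.array(vals[0], dtype=np.int64)
            b = np.cumsum(ff) if len(ff) else ff
            cur.tracepoints = TracePointArray(delta=delta, b=b.astype(np.int32))
    return records, delta
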