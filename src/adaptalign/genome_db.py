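"""Genome databases: scaffolds split into contigs at runs of N.

A genome enters the pipeline as a (possibly gzip-compressed) FASTA file in
which each entry is a *scaffold*: runs of ``N`` separate the assembled
*contigs*.  Only contig sequence (pure ``acgt``) is ever indexed or aligned;
the gap lengths are retained so that alignment coordinates can be reported in
scaffold space.  Contig sequence is stored 2 bits per base.

Coordinates are 0-based and half-open throughout: position ``i`` is the
boundary *between* characters ``i`` and ``i+1``, so the substring ``A[i, j]``
has length ``j - i``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Contig",
    "Scaffold",
    "GenomeDB",
    "fasta_to_gdb",
    "gdb_to_fasta",
    "reverse_complement",
    "pack_codes",
    "unpack_codes",
    "codes_to_seq",
    "seq_to_codes",
    "rc_codes",
]

# a=0, c=1, g=2, t=3 -- the base-4 digit order used by the phi value
_BASES = "acgt"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.upper())] = _i
_COMPLEMENT = {"a": "t", "c": "g", "g": "c", "t": "a"}


def seq_to_codes(seq: str) -> np.ndarray:
    """Convert an ``acgt`` string (case-insensitive) to a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid base {seq[bad]!r} at offset {bad}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"acgt", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def rc_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space: complement is ``3 - code``."""
    return (3 - codes[::-1]).astype(np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over ``{a,c,g,t}`` (case kept lower).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return codes_to_seq(rc_codes(seq_to_codes(seq)))


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack base codes 2 bits each into bytes, first base in the top 2 bits.

    The packed order is big-endian within each byte so that byte-wise
    lexicographic order of packed k-mers equals base-wise lexicographic order.
    """
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4)
    return (
        (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
    ).astype(np.uint8)


def unpack_codes(packed: np.ndarray, n: int) -> np.ndarray:
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = (packed >> 6) & 3
    out[1::4] = (packed >> 4) & 3
    out[2::4] = (packed >> 2) & 3
    out[3::4] = packed & 3
    return out[:n]


@dataclass
class Contig:
    """A gap-free stretch of scaffold sequence, 2-bit packed."""

    scaffold_id: str
    contig_ordinal: int
    offset_in_scaffold: int
    packed: np.ndarray
    length: int
    #: half-open soft-mask (lowercase) runs, relative to the contig start
    mask_runs: List[Tuple[int, int]] = field(default_factory=list)

    def codes(self) -> np.ndarray:
        return unpack_codes(self.packed, self.length)

    @property
    def sequence(self) -> str:
        return codes_to_seq(self.codes())


@dataclass
class Scaffold:
    name: str
    length: int
    contigs: List[Contig]
    #: ``len(contigs) + 1`` N-run lengths: leading, between contigs, trailing
    gaps: List[int]

    def validate(self) -> None:
        total = sum(c.length for c in self.contigs) + sum(self.gaps)
        if total != self.length:
            raise ValueError(
                f"scaffold {self.name}: contigs+gaps={total} != length={self.length}"
            )


@dataclass
class GenomeDB:
    """Scaffolds decomposed into contigs, with a flat global contig numbering."""

    scaffolds: List[Scaffold]

    def __post_init__(self) -> None:
        self.contigs: List[Contig] = [c for s in self.scaffolds for c in s.contigs]
        self._scaffold_of: List[int] = []
        for si, s in enumerate(self.scaffolds):
            self._scaffold_of.extend([si] * len(s.contigs))

    @property
    def total_contig_bases(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def contig_lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.contigs], dtype=np.int64)

    def scaffold_of(self, contig_id: int) -> Scaffold:
        return self.scaffolds[self._scaffold_of[contig_id]]

    def contig_id(self, scaffold_id: str, ordinal: int) -> int:
        for i, c in enumerate(self.contigs):
            if c.scaffold_id == scaffold_id and c.contig_ordinal == ordinal:
                return i
        raise KeyError((scaffold_id, ordinal))

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fasta(path) -> Iterator[Tuple[str, str]]:
    from Bio import SeqIO

    n = 0
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            n += 1
            yield rec.id, str(rec.seq)
    if n == 0:
        raise ValueError(f"no FASTA records in {path}")


def _mask_runs(seq: str, start: int, end: int) -> List[Tuple[int, int]]:
    """Half-open lowercase runs of seq[start:end], relative to start."""
    sub = np.frombuffer(seq[start:end].encode("ascii"), dtype=np.uint8)
    low = (sub >= ord("a")) & (sub <= ord("z"))
    if not low.any():
        return []
    edges = np.flatnonzero(np.diff(low.astype(np.int8)))
    starts = list(edges[~low[edges]] + 1)
    ends = list(edges[low[edges]] + 1)
    if low[0]:
        starts = [0] + starts
    if low[-1]:
        ends = ends + [len(sub)]
    return list(zip(starts, ends))


def fasta_to_gdb(path, min_gap: int = 1) -> GenomeDB:
    """Read a FASTA (or gzip FASTA) file into a :class:`GenomeDB`.

    Scaffolds are split into contigs at runs of at least ``min_gap`` ``N``
    characters.  Contigs never contain ``N``, so with the default
    ``min_gap=1`` every N-run separates contigs; the run lengths are recorded
    as gaps either way.  Lowercase (soft-masked) sequence is recorded per
    contig but is not used by the seeder.

    Raises ``ValueError`` for any character outside ``{A,C,G,T,N}``
    (case-insensitive), naming the scaffold and offset.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    scaffolds: List[Scaffold] = []
    for name, seq in _iter_fasta(path):
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_n = raw == ord("N")
        bad = (_CODE[raw] == 255) & ~is_n
        if bad.any():
            off = int(np.argmax(bad))
            raise ValueError(
                f"non-IUPAC character {seq[off]!r} in scaffold {name} at offset {off}"
            )
        # contig intervals = maximal non-N runs
        contigs: List[Contig] = []
        gaps: List[int] = []
        boundaries = np.flatnonzero(np.diff(is_n.astype(np.int8)))
        starts = [0] if (len(raw) and not is_n[0]) else []
        starts += list(boundaries[is_n[boundaries]] + 1)
        ends = list(boundaries[~is_n[boundaries]] + 1)
        if len(raw) and not is_n[-1]:
            ends += [len(raw)]
        prev_end = 0
        for ordinal, (cs, ce) in enumerate(zip(starts, ends)):
            gaps.append(cs - prev_end)
            codes = _CODE[raw[cs:ce]]
            contigs.append(
                Contig(
                    scaffold_id=name,
                    contig_ordinal=ordinal,
                    offset_in_scaffold=int(cs),
                    packed=pack_codes(codes),
                    length=int(ce - cs),
                    mask_runs=_mask_runs(seq, cs, ce),
                )
            )
            prev_end = ce
        gaps.append(len(raw) - prev_end)
        sc = Scaffold(name=name, length=len(raw), contigs=contigs, gaps=gaps)
        sc.validate()
        scaffolds.append(sc)
    return GenomeDB(scaffolds)


def write_gdb(gdb: GenomeDB, path, command: str = "adaptalign") -> None:
    """Persist a GenomeDB: an ASCII document describing scaffolds/contigs
    plus a packed 2-bit sequence sidecar file (``<path>.seq``)."""
    from adaptalign.onecode import OneDocument, write_one

    doc = OneDocument(
        filetype="gdb",
        schema={
            "S": "str:name int:length",
            "C": "int:offset int:length int:packed_bytes",
            "G": "int:gap_length",
            "M": "intlist:softmask_run_edges",
        },
    )
    doc.stamp(command)
    chunks = []
    for sc in gdb.scaffolds:
        doc.add("S", sc.name, sc.length)
        for i, contig in enumerate(sc.contigs):
            doc.add("G", sc.gaps[i])
            doc.add("C", contig.offset_in_scaffold, contig.length, len(contig.packed))
            if contig.mask_runs:
                doc.add("M", [x for run in contig.mask_runs for x in run])
            chunks.append(contig.packed)
        doc.add("G", sc.gaps[len(sc.contigs)])
    write_one(doc, path)
    with open(str(path) + ".seq", "wb") as fh:
        for ch in chunks:
            fh.write(ch.tobytes())


def read_gdb(path) -> GenomeDB:
    from adaptalign.onecode import read_one

    doc = read_one(path, list_codes={"M": 0})
    packed = np.fromfile(str(path) + ".seq", dtype=np.uint8)
    scaffolds: List[Scaffold] = []
    at = 0
    cur: Scaffold | None = None
    for code, vals in doc.lines:
        if code == "S":
            cur = Scaffold(name=str(vals[0]), length=int(vals[1]), contigs=[], gaps=[])
            scaffolds.append(cur)
        elif code == "G":
            cur.gaps.append(int(vals[0]))
        elif code == "C":
            off, length, nbytes = (int(v) for v in vals)
            cur.contigs.append(
                Contig(
                    scaffold_id=cur.name,
                    contig_ordinal=len(cur.contigs),
                    offset_in_scaffold=off,
                    packed=packed[at : at + nbytes].copy(),
                    length=length,
                )
            )
            at += nbytes
        elif code == "M":
            edges = list(vals[0])
            cur.contigs[-1].mask_runs = list(zip(edges[0::2], edges[1::2]))
    for sc in scaffolds:
        sc.validate()
    return GenomeDB(scaffolds)


def gdb_to_fasta(gdb: GenomeDB, path, width: int = 80) -> None:
    """Write a GenomeDB back to FASTA.

    Round-trips the input sequence exactly, up to the case of N-runs (which
    are emitted as uppercase ``N``); contig soft-masking is restored.
    """
    with open(path, "w") as fh:
        for sc in gdb.scaffolds:
            fh.write(f">{sc.name}\n")
            parts: List[str] = []
            for i, contig in enumerate(sc.contigs):
                parts.append("N" * sc.gaps[i])
                seq = contig.sequence
                chars = list(seq.upper())
                for ms, me in contig.mask_runs:
                    for k in range(ms, me):
                        chars[k] = chars[k].lower()
                parts.append("".join(chars))
            parts.append("N" * sc.gaps[len(sc.contigs)])
            seq = "".join(parts)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
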