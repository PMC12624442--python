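"""Minimal ASCII documents in the spirit of ONEcode.

Every persisted artifact (genome database, genome index, alignment file) is a
sequence of strongly-typed lines.  Each line begins with a one-character code;
the header carries provenance (``!`` lines), a schema declaring every data
line code (``~`` lines), and per-code counts (``#`` lines) plus maximum list
lengths (``@`` lines), so a document is self-describing and checkable.

This is deliberately the ASCII side only: binary encodings, per-item
compression and random-access indexing are out of scope.  One list-valued
field is permitted per line type and is written as a count followed by the
items.
"""

from __future__ import annotations

import datetime as _dt
import numbers as _numbers
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

Value = Union[int, float, str, Sequence[int]]

__all__ = ["OneDocument", "read_one", "write_one"]


@dataclass
class OneDocument:
    filetype: str
    provenance: List[str] = field(default_factory=list)
    #: code -> whitespace-separated field description (documentation only)
    schema: Dict[str, str] = field(default_factory=dict)
    #: data lines in order: (code, values)
    lines: List[Tuple[str, List[Value]]] = field(default_factory=list)

    def add(self, code: str, *values: Value) -> None:
        if code not in self.schema:
            raise ValueError(f"line code {code!r} not declared in schema")
        self.lines.append((code, list(values)))

    def count(self, code: str) -> int:
        return sum(1 for c, _ in self.lines if c == code)

    def stamp(self, command: str, version: str = "0.1.0") -> None:
        date = _dt.date.today().isoformat()
        self.provenance.append(f"adaptalign {version} {date} {command}")


def _fmt(v: Value) -> str:
    if isinstance(v, bool):
        raise TypeError("bool is not a ONEcode value")
    if isinstance(v, _numbers.Integral):
        return str(int(v))
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        if any(ch.isspace() for ch in v):
            raise ValueError(f"string value may not contain whitespace: {v!r}")
        return v
    # list of ints: count then items
    items = [int(x) for x in v]
    return " ".join([str(len(items))] + [str(x) for x in items])


def write_one(doc: OneDocument, path) -> None:
    counts: Dict[str, int] = {}
    maxlist: Dict[str, int] = {}
    for code, values in doc.lines:
        counts[code] = counts.get(code, 0) + 1
        for v in values:
            if isinstance(v, (list, tuple)) or (
                hasattr(v, "__len__") and not isinstance(v, str)
            ):
                maxlist[code] = max(maxlist.get(code, 0), len(v))
    with open(path, "w") as fh:
        fh.write(f"1 {doc.filetype} 1 0\n")
        for p in doc.provenance:
            fh.write(f"! {p}\n")
        for code, desc in doc.schema.items():
            fh.write(f"~ {code} {desc}\n")
        for code in doc.schema:
            if code in counts:
                fh.write(f"# {code} {counts[code]}\n")
            if code in maxlist:
                fh.write(f"@ {code} {maxlist[code]}\n")
        for code, values in doc.lines:
            fh.write(code)
            for v in values:
                fh.write(" " + _fmt(v))
            fh.write("\n")


def _parse_token(tok: str) -> Value:
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        return tok


def read_one(path, list_codes: Dict[str, int] | None = None) -> OneDocument:
    """Read an ASCII document back, checking header counts against the data.

    ``list_codes`` maps a line code to the 0-based field index at which its
    (single) integer list starts; list fields are re-assembled from the
    ``count item...`` encoding.
    """
    list_codes = list_codes or {}
    doc = OneDocument(filetype="")
    counts: Dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            code, _, rest = raw.partition(" ")
            if code == "1":
                doc.filetype = rest.split()[0]
            elif code == "!":
                doc.provenance.append(rest)
            elif code == "~":
                c, _, desc = rest.partition(" ")
                doc.schema[c] = desc
            elif code == "#":
                c, n = rest.split()
                counts[c] = int(n)
            elif code == "@":
                pass  # max list length: informational
            else:
                toks = rest.split() if rest else []
                if code in list_codes:
                    at = list_codes[code]
                    head = [_parse_token(t) for t in toks[:at]]
                    nitems = int(toks[at])
                    items = [int(t) for t in toks[at + 1 : at + 1 + nitems]]
                    if len(items) != nitems:
                        raise ValueError(f"list length mismatch on {code!r} line")
                    values: List[Value] = head + [items]
                else:
                    values = [_parse_token(t) for t in toks]
                doc.lines.append((code, values))
    for c, n in counts.items():
        have = doc.count(c)
        if have != n:
            raise ValueError(f"header declares {n} {c!r} lines, found {have}")
    return doc
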