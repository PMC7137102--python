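"""STAR (RELION dialect) and delimited-text serialization of tables.

A STAR document is an ordered mapping of ``data_<name>`` blocks to tables.
Loop blocks become multi-row tables whose column order follows the ``#N``
ordinal suffixes when present; bare key-value blocks become single-row
tables.  Column types are inferred deterministically from the token set
(int if every token parses as an integer, else float if every token parses
as a float, else string; quoted tokens force string).  The tokens ``.`` and
``?`` read as MISSING; MISSING writes as ``.``.

Floats serialize with the shortest decimal representation that round-trips,
so read(write(doc)) reproduces the document exactly.
"""

from __future__ import annotations

import csv
import os
import re
import tempfile
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import FormatError, TableError
from .table import Column, MISSING, Table

_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(
    r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$"
)


class StarDocument:
    """Ordered mapping of block name -> Table."""

    def __init__(self, blocks: Optional[Dict[str, Table]] = None) -> None:
        self._blocks: Dict[str, Table] = {}
        for name, tab in (blocks or {}).items():
            self[name] = tab

    def __setitem__(self, name: str, tab: Table) -> None:
        if not isinstance(tab, Table):
            raise TableError("StarDocument blocks must be Table instances")
        self._blocks[name] = tab

    def __getitem__(self, name: str) -> Table:
        try:
            return self._blocks[name]
        except KeyError:
            raise TableError(f"unknown block {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._blocks

    def __len__(self) -> int:
        return len(self._blocks)

    @property
    def block_names(self) -> Tuple[str, ...]:
        return tuple(self._blocks)

    def first(self) -> Table:
        if not self._blocks:
            raise TableError("document has no blocks")
        return next(iter(self._blocks.values()))

    def __eq__(self, other) -> bool:
        return (isinstance(other, StarDocument)
                and list(self._blocks) == list(other._blocks)
                and all(self._blocks[k] == other._blocks[k]
                        for k in self._blocks))


# ---------------------------------------------------------------------------
# type inference shared by STAR and TSV readers
# ---------------------------------------------------------------------------

def _is_missing(tok: str) -> bool:
    return tok in (".", "?")


def infer_column(name: str, tokens: Sequence[Tuple[str, bool]]) -> Column:
    """Choose a ctype from raw (token, quoted) pairs."""
    present = [(t, q) for t, q in tokens if not (not q and _is_missing(t))]
    if any(q for _, q in present):
        return Column(name, "string")
    vals = [t for t, _ in present]
    if vals and all(_INT_RE.match(t) for t in vals):
        return Column(name, "int")
    if vals and all(_FLOAT_RE.match(t) for t in vals):
        return Column(name, "float")
    return Column(name, "string")


def _convert(tok: str, quoted: bool, ctype: str):
    if not quoted and _is_missing(tok):
        return MISSING
    if ctype == "int":
        return int(tok)
    if ctype == "float":
        return float(tok)
    return tok


# ---------------------------------------------------------------------------
# STAR reading
# ---------------------------------------------------------------------------

def _tokenize_star_line(line: str, lineno: int) -> List[Tuple[str, bool]]:
    """Split one STAR data line into (token, was_quoted) pairs."""
    out: List[Tuple[str, bool]] = []
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c.isspace():
            i += 1
            continue
        if c == "#":  # comment to end of line
            break
        if c in ("'", '"'):
            j = line.find(c, i + 1)
            if j < 0:
                raise FormatError(f"line {lineno}: unterminated quote")
            out.append((line[i + 1:j], True))
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            out.append((line[i:j], False))
            i = j
    return out


_LABEL_RE = re.compile(r"^_(\S+?)(?:\s+#(\d+))?\s*(?:#.*)?$")


def read_star(path) -> StarDocument:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        # split on real newlines only: splitlines() would also break on
        # \x0b/\x0c, which may legitimately occur inside quoted values
        lines = fh.read().split("\n")

    doc = StarDocument()
    i, n = 0, len(lines)
    block_name: Optional[str] = None
    # accumulated state of the current block
    kv_pairs: List[Tuple[str, Tuple[str, bool]]] = []

    def flush_kv():
        nonlocal kv_pairs
        if block_name is None or not kv_pairs:
            kv_pairs = []
            return
        names = [k for k, _ in kv_pairs]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate labels in block {block_name!r}")
        cols = [infer_column(k, [tokq]) for k, tokq in kv_pairs]
        row = [_convert(tq[0], tq[1], c.ctype)
               for (_, tq), c in zip(kv_pairs, cols)]
        _add_block(doc, block_name, Table(cols, [row]))
        kv_pairs = []

    while i < n:
        raw = lines[i]
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            i += 1
            continue
        if stripped.startswith("data_"):
            flush_kv()
            block_name = stripped[5:]
            i += 1
            continue
        if stripped == "loop_":
            if block_name is None:
                raise FormatError(f"line {i + 1}: loop_ outside a data block")
            flush_kv()
            i += 1
            labels: List[Tuple[str, Optional[int]]] = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith("#"):
                    i += 1
                    continue
                m = _LABEL_RE.match(s)
                if not m:
                    break
                labels.append((m.group(1),
                               int(m.group(2)) if m.group(2) else None))
                i += 1
            if not labels:
                raise FormatError(f"line {i + 1}: loop_ with no labels")
            # honour explicit #N ordinals for column order (stable)
            order = sorted(range(len(labels)),
                           key=lambda j: (labels[j][1] is None,
                                          labels[j][1] or 0, j))
            names = [labels[j][0] for j in order]
            if len(set(names)) != len(names):
                raise FormatError(f"duplicate labels in block {block_name!r}")
            tokens: List[Tuple[str, bool]] = []
            while i < n:
                s = lines[i].strip()
                if (s.startswith("data_") or s == "loop_"
                        or s.startswith("_")):
                    break
                if s == "" or s.startswith("#"):
                    i += 1
                    continue
                if s.startswith(";"):
                    # multi-line text field: read until closing ';'
                    text_lines = [s[1:]]
                    i += 1
                    while i < n and not lines[i].startswith(";"):
                        text_lines.append(lines[i])
                        i += 1
                    if i >= n:
                        raise FormatError("unterminated ';' text field")
                    i += 1
                    tokens.append(("\n".join(text_lines).strip("\n"), True))
                    continue
                tokens.extend(_tokenize_star_line(lines[i], i + 1))
                i += 1
            ncols = len(names)
            if tokens and len(tokens) % ncols != 0:
                raise FormatError(
                    f"block {block_name!r}: {len(tokens)} values are not a "
                    f"multiple of {ncols} columns"
                )
            per_col = [[tokens[r * ncols + j] for r in
                        range(len(tokens) // ncols)] for j in range(ncols)]
            # inference sees columns in file order; reorder already applied
            cols = [infer_column(nm, per_col[j]) for j, nm in enumerate(names)]
            rows = []
            for r in range(len(tokens) // ncols):
                rows.append([_convert(*tokens[r * ncols + j], cols[j].ctype)
                             for j in range(ncols)])
            _add_block(doc, block_name, Table(cols, rows))
            continue
        if stripped.startswith("_") and block_name is not None:
            toks = _tokenize_star_line(stripped, i + 1)
            if len(toks) != 2 or toks[0][1]:
                raise FormatError(
                    f"line {i + 1}: key-value pair needs exactly one value"
                )
            kv_pairs.append((toks[0][0][1:], toks[1]))
            i += 1
            continue
        raise FormatError(f"line {i + 1}: unexpected content {stripped!r}")

    flush_kv()
    return doc


def _add_block(doc: StarDocument, name: str, tab: Table) -> None:
    if name in doc:
        raise FormatError(f"duplicate block name {name!r}")
    doc[name] = tab


# ---------------------------------------------------------------------------
# STAR writing
# ---------------------------------------------------------------------------

def _format_value(v, ctype: str) -> str:
    if v is MISSING:
        return "."
    if ctype == "int":
        return str(v)
    if ctype == "float":
        return repr(float(v))  # shortest round-trip decimal
    if ctype == "bool":
        return "1" if v else "0"
    s = str(v)
    # quote anything that would not read back as this exact string: embedded
    # whitespace, missing markers, reserved prefixes, numeric look-alikes
    if s == "" or any(c.isspace() for c in s) or _is_missing(s) \
            or s[0] in "_#;'\"" or s.startswith(("data_", "loop_")) \
            or _INT_RE.match(s) or _FLOAT_RE.match(s):
        q = "'" if "'" not in s else '"'
        if "'" in s and '"' in s or "\n" in s:
            raise FormatError(
                f"string {s!r} cannot be quoted on a single STAR line"
            )
        return f"{q}{s}{q}"
    return s


def write_star(doc: StarDocument, path) -> None:
    lines: List[str] = []
    for name in doc.block_names:
        tab = doc[name]
        lines.append(f"data_{name}")
        lines.append("")
        if tab.n_rows == 1:
            # single-row tables serialize as key-value blocks
            for col, v in zip(tab.columns, tab.rows[0]):
                lines.append(f"_{col.name}  {_format_value(v, col.ctype)}")
        else:
            lines.append("loop_")
            for j, col in enumerate(tab.columns, start=1):
                lines.append(f"_{col.name} #{j}")
            for row in tab.rows:
                lines.append(" ".join(
                    _format_value(v, c.ctype)
                    for c, v in zip(tab.columns, row)))
        lines.append("")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def _atomic_write_text(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(str(path))) or "."
    fd, tmp = tempfile.mkstemp(prefix=".emkit-", dir=d)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, str(path))
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def read_tsv(path, delimiter: str = "\t") -> Table:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if not rows:
        raise FormatError("delimited file has no header row")
    header = rows[0]
    body = rows[1:]
    for k, r in enumerate(body):
        if len(r) != len(header):
            raise FormatError(
                f"ragged row {k + 2}: {len(r)} fields, expected {len(header)}"
            )
    per_col = [[(r[j], False) for r in body] for j in range(len(header))]
    cols = []
    for j, name in enumerate(header):
        toks = [("." if t == "" else t, False) for t, _ in per_col[j]]
        cols.append(infer_column(name, toks))
    out_rows = []
    for r in body:
        out_rows.append([
            _convert("." if tok == "" else tok, False, c.ctype)
            for tok, c in zip(r, cols)
        ])
    return Table(cols, out_rows)


def write_tsv(tab: Table, path, delimiter: str = "\t") -> None:
    d = os.path.dirname(os.path.abspath(str(path))) or "."
    fd, tmp = tempfile.mkstemp(prefix=".emkit-", dir=d)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            writer.writerow(tab.column_names)
            for row in tab.rows:
                writer.writerow([
                    _format_tsv_value(v, c.ctype)
                    for c, v in zip(tab.columns, row)
                ])
        os.replace(tmp, str(path))
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _format_tsv_value(v, ctype: str) -> str:
    if v is MISSING:
        return "."
    if ctype == "float":
        return repr(float(v))
    if ctype == "bool":
        return "1" if v else "0"
    return str(v)
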