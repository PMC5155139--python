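"""Morphological character matrices and NEXUS / TNT xread I/O.

A cell holds a set of integer states: a singleton for an observed state,
a multi-state set for polymorphism ('[01]', '{01}' or '(01)'), and
``None`` for missing ('?').  Inapplicable ('-') is treated as missing.
Characters are unordered (non-additive) by default; ordered (additive)
characters are flagged per character, read from a NEXUS ASSUMPTIONS
TYPESET or a TNT ``ccode`` statement when present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["CharacterMatrix", "read_matrix", "write_nexus", "write_tnt"]

Cell = frozenset | None  # None == missing

MAX_STATE = 9


@dataclass
class CharacterMatrix:
    taxa: list[str]
    cells: list[list[Cell]]  # taxa x characters
    ordered_flags: list[bool] = field(default_factory=list)
    character_labels: list[str] | None = None

    def __post_init__(self):
        if len(self.cells) != len(self.taxa):
            raise ValueError("one row of cells per taxon required")
        ncols = {len(r) for r in self.cells}
        if len(ncols) > 1:
            raise ValueError("ragged matrix: rows differ in character count")
        if not self.ordered_flags:
            self.ordered_flags = [False] * self.n_char
        if len(self.ordered_flags) != self.n_char:
            raise ValueError("one ordered flag per character required")
        for row in self.cells:
            for cell in row:
                if cell is None:
                    continue
                if not cell or any(not (0 <= s <= MAX_STATE) for s in cell):
                    raise ValueError(f"states must lie in [0, {MAX_STATE}]")
        for j in range(self.n_char):
            if all(row[j] is None for row in self.cells):
                raise ValueError(f"character {j} has no non-missing cell")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> list[Cell]:
        return self.cells[self.taxa.index(taxon)]

    def column(self, j: int) -> list[Cell]:
        return [row[j] for row in self.cells]


_TOKEN = re.compile(r"\[([0-9]+)\]|\{([0-9]+)\}|\(([0-9]+)\)|([0-9?\-])")


def _parse_state_string(s: str, line_no: int) -> list[Cell]:
    cells: list[Cell] = []
    pos = 0
    s = s.strip()
    while pos < len(s):
        if s[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(s, pos)
        if not m:
            raise ValueError(f"line {line_no}: cannot parse state at {s[pos:]!r}")
        poly = m.group(1) or m.group(2) or m.group(3)
        if poly is not None:
            cells.append(frozenset(int(ch) for ch in poly))
        else:
            ch = m.group(4)
            cells.append(None if ch in "?-" else frozenset([int(ch)]))
        pos = m.end()
    return cells


def _parse_index_list(expr: str, n_char: int, base: int) -> list[int]:
    """Expand '1 3-5 8.' style index lists to 0-based indices."""
    idx: list[int] = []
    for tok in expr.replace(",", " ").split():
        tok = tok.rstrip(".")
        if not tok:
            continue
        if tok == "all":
            return list(range(n_char))
        if "-" in tok:
            a, b = tok.split("-")
            idx.extend(range(int(a) - base, int(b) - base + 1))
        else:
            idx.append(int(tok) - base)
    return [i for i in idx if 0 <= i < n_char]


def _strip_nexus_comments(text: str) -> str:
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _read_nexus(text: str) -> CharacterMatrix:
    # keep bracketed polymorphism inside the MATRIX command; strip comments
    # elsewhere by working command-wise
    lower = text.lower()
    m = re.search(r"\bdimensions\b([^;]*);", lower)
    if not m:
        raise ValueError("NEXUS file lacks a DIMENSIONS command")
    dims = m.group(1)
    ntax = int(re.search(r"ntax\s*=\s*(\d+)", dims).group(1))
    nchar = int(re.search(r"nchar\s*=\s*(\d+)", dims).group(1))

    mm = re.search(r"\bmatrix\b(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not mm:
        raise ValueError("NEXUS file lacks a MATRIX command")
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    for ln, raw in enumerate(mm.group(1).splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("'"):
            k = line.index("'", 1)
            while k + 1 < len(line) and line[k + 1] == "'":
                k = line.index("'", k + 2)
            name = line[1:k].replace("''", "'")
            states = line[k + 1:]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 'taxon states'")
            name, states = parts
            name = name.replace("_", " ")
        cells = _parse_state_string(states, ln)
        if name in taxa:  # interleaved continuation
            rows[taxa.index(name)].extend(cells)
        else:
            taxa.append(name)
            rows.append(cells)
    if len(taxa) != ntax:
        raise ValueError(
            f"taxon count mismatch: header says {ntax}, matrix has {len(taxa)}"
        )
    for i, r in enumerate(rows):
        if len(r) != nchar:
            raise ValueError(
                f"taxon {taxa[i]!r}: {len(r)} characters, header says {nchar}"
            )

    ordered = [False] * nchar
    clean = _strip_nexus_comments(text)
    ts = re.search(r"typeset[^=;]*=\s*([^;]*);", clean, re.IGNORECASE)
    if ts:
        for group in ts.group(1).split(","):
            if ":" not in group:
                continue
            kind, members = group.split(":", 1)
            flag = kind.strip().lower() in ("ord", "ordered")
            for i in _parse_index_list(members, nchar, base=1):
                ordered[i] = flag
    return CharacterMatrix(taxa, rows, ordered)


def _read_tnt(text: str) -> CharacterMatrix:
    # drop 'comments' quoted after xread
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);",
                  text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("TNT file lacks an xread block")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    for ln, raw in enumerate(m.group(3).splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("&"):
            continue
        if line.startswith("'"):
            k = line.index("'", 1)
            name, states = line[1:k], line[k + 1:]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 'taxon states'")
            name, states = parts
            name = name.replace("_", " ")
        cells = _parse_state_string(states, ln)
        if name in taxa:
            rows[taxa.index(name)].extend(cells)
        else:
            taxa.append(name)
            rows.append(cells)
    if len(taxa) != ntax:
        raise ValueError(
            f"taxon count mismatch: header says {ntax}, xread has {len(taxa)}"
        )
    for i, r in enumerate(rows):
        if len(r) != nchar:
            raise ValueError(
                f"taxon {taxa[i]!r}: {len(r)} characters, header says {nchar}"
            )

    ordered = [False] * nchar
    for cc in re.finditer(r"ccode\s+([^;]*);", text, re.IGNORECASE):
        body = cc.group(1)
        # '+' starts an additive group, '-' a non-additive group
        for sign, members in re.findall(r"([+\-])\s*([0-9\s.\-]*)", body):
            for i in _parse_index_list(members, nchar, base=0):
                ordered[i] = sign == "+"
    return CharacterMatrix(taxa, rows, ordered)


def read_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Read a morphological matrix from a NEXUS or TNT xread file.

    The format is sniffed from the content (``#NEXUS`` header vs
    ``xread``) unless given explicitly.
    """
    text = Path(path).read_text()
    if format is None:
        format = "nexus" if text.lstrip().lower().startswith("#nexus") else "tnt"
    if format == "nexus":
        return _read_nexus(text)
    if format == "tnt":
        return _read_tnt(text)
    raise ValueError(f"unknown matrix format {format!r}")


def _cell_str(cell: Cell, poly_open: str = "[", poly_close: str = "]") -> str:
    if cell is None:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return poly_open + "".join(str(s) for s in sorted(cell)) + poly_close


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        "  FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456789\" MISSING=? GAP=-;",
        "  MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        name = "'" + taxon.replace("'", "''") + "'" if " " in taxon or "'" in taxon \
            else taxon
        lines.append(f"    {name:<{width}} " + "".join(_cell_str(c, "{", "}")
                                                       for c in row))
    lines.append("  ;")
    lines.append("END;")
    if any(matrix.ordered_flags):
        ords = " ".join(str(i + 1) for i, f in enumerate(matrix.ordered_flags) if f)
        lines += ["BEGIN ASSUMPTIONS;",
                  f"  TYPESET * default = ord: {ords};",
                  "END;"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tnt(matrix: CharacterMatrix, path: str | Path) -> None:
    lines = [f"xread {matrix.n_char} {matrix.n_taxa}"]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        name = taxon.replace(" ", "_")
        lines.append(f"{name}  " + "".join(_cell_str(c) for c in row))
    lines.append(";")
    if any(matrix.ordered_flags):
        ords = " ".join(str(i) for i, f in enumerate(matrix.ordered_flags) if f)
        lines.append(f"ccode + {ords};")
    lines.append("proc /;")
    Path(path).write_text("\n".join(lines) + "\n")
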