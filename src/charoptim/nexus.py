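"""Reading and writing NEXUS character matrices and assumptions.

Supports the dialect used by morphological data sets: a ``DATA`` or
``CHARACTERS`` block with ``DIMENSIONS``, ``FORMAT`` (symbols, missing, gap,
interleave) and ``MATRIX`` commands, plus an ``ASSUMPTIONS`` block whose
``TYPESET`` command marks characters as ordered (``ord``) or unordered
(``unord``).  Both ``{..}`` and ``(..)`` polymorphism delimiters are
accepted; the default symbol list is ``0123456789``.

Character indices are 1-based in files (NEXUS convention) and 0-based in
:class:`~charoptim.matrix.CharacterMatrix`.

Interleaved matrices are read (each matrix line must begin with its taxon
name) but always written in non-interleaved form.
"""

from __future__ import annotations

import re

from .matrix import CharacterDef, CharacterMatrix, INAPPLICABLE, MISSING, is_scored

DEFAULT_SYMBOLS = "0123456789"
_EXTENDED_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"


class NexusParseError(ValueError):
    """Base class for NEXUS parse failures; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MalformedBlockError(NexusParseError):
    """Missing or structurally invalid block/command."""


class DuplicateTaxonError(NexusParseError):
    """The same taxon name appears twice in a non-interleaved matrix."""


class RowLengthError(NexusParseError):
    """A taxon's row does not contain exactly nchar cells."""


class SymbolError(NexusParseError):
    """A matrix cell uses a symbol outside the declared symbol list."""


class AssumptionsError(NexusParseError):
    """Bad ordered/unordered character assignment."""


# ---------------------------------------------------------------------------
# low-level helpers


def _strip_comments(text: str) -> str:
    """Replace NEXUS [comments] with spaces, preserving line structure."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
            out.append(" ")
        elif ch == "]" and depth:
            depth -= 1
            out.append(" ")
        elif depth and ch != "\n":
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def _find_block(lines: list[str], names: tuple[str, ...]) -> tuple[int, int] | None:
    """Return (start, end) line indices of the first BEGIN <name> ... END block."""
    begin_re = re.compile(
        r"^\s*begin\s+(" + "|".join(names) + r")\s*;", re.IGNORECASE
    )
    end_re = re.compile(r"^\s*end\s*;", re.IGNORECASE)
    start = None
    for i, line in enumerate(lines):
        if start is None:
            if begin_re.match(line):
                start = i
        elif end_re.match(line):
            return start, i
    if start is not None:
        raise MalformedBlockError("block opened but never closed with END;", start + 1)
    return None


def _commands(lines: list[str], start: int, end: int):
    """Yield (command_text, first_line_number) for ';'-terminated commands."""
    buf: list[str] = []
    first = None
    for i in range(start + 1, end):
        line = lines[i]
        if buf == [] and not line.strip():
            continue
        if first is None:
            first = i + 1
        buf.append(line)
        if ";" in line:
            yield "\n".join(buf), first
            buf = []
            first = None
    if buf and "".join(buf).strip():
        yield "\n".join(buf), first


def _parse_name(token_line: str):
    """Split a matrix line into (taxon name, remainder).

    Quoted names may contain spaces; unquoted underscores become spaces.
    """
    s = token_line.lstrip()
    if s.startswith("'"):
        m = re.match(r"'((?:[^']|'')*)'", s)
        if m is None:
            return None, s
        name = m.group(1).replace("''", "'")
        return name, s[m.end():]
    m = re.match(r"[^\s(){}]+", s)
    if m is None:
        return None, s
    return m.group(0).replace("_", " "), s[m.end():]


# ---------------------------------------------------------------------------
# matrix parsing


def parse_nexus_matrix(text: str) -> CharacterMatrix:
    """Parse the first DATA or CHARACTERS block of a NEXUS document.

    Polymorphism tokens ``{01}`` / ``(01)`` become multi-state sets, the
    declared missing symbol becomes :data:`MISSING` and the gap symbol
    becomes :data:`INAPPLICABLE`.  Taxon order is preserved.  If the
    document also contains an ASSUMPTIONS block its ordering typeset is
    applied before returning.

    Raises
    ------
    MalformedBlockError, DuplicateTaxonError, RowLengthError, SymbolError
        Each with the offending 1-based line number in the message.
    """
    clean = _strip_comments(text)
    lines = clean.split("\n")
    span = _find_block(lines, ("data", "characters"))
    if span is None:
        raise MalformedBlockError("no DATA or CHARACTERS block found")
    start, end = span

    ntax = nchar = None
    symbols = DEFAULT_SYMBOLS
    missing_sym, gap_sym = "?", "-"
    interleave = False
    matrix_cmd = None

    for cmd, lineno in _commands(lines, start, end):
        head = cmd.split(None, 1)[0].lower().rstrip(";")
        if head == "dimensions":
            m = re.search(r"ntax\s*=\s*(\d+)", cmd, re.IGNORECASE)
            if m:
                ntax = int(m.group(1))
            m = re.search(r"nchar\s*=\s*(\d+)", cmd, re.IGNORECASE)
            if m:
                nchar = int(m.group(1))
            if nchar is None:
                raise MalformedBlockError("DIMENSIONS lacks NCHAR", lineno)
        elif head == "format":
            m = re.search(r"symbols\s*=\s*\"([^\"]*)\"", cmd, re.IGNORECASE)
            if m:
                symbols = m.group(1).replace(" ", "")
            m = re.search(r"missing\s*=\s*(\S)", cmd, re.IGNORECASE)
            if m:
                missing_sym = m.group(1)
            m = re.search(r"gap\s*=\s*(\S)", cmd, re.IGNORECASE)
            if m:
                gap_sym = m.group(1)
            if re.search(r"interleave(\s*=\s*yes)?", cmd, re.IGNORECASE):
                interleave = not re.search(r"interleave\s*=\s*no", cmd, re.IGNORECASE)
        elif head == "matrix":
            matrix_cmd = (cmd, lineno)

    if nchar is None or matrix_cmd is None:
        raise MalformedBlockError(
            "block lacks a DIMENSIONS or MATRIX command", start + 1
        )

    cmd, lineno = matrix_cmd
    code_of = {sym: i for i, sym in enumerate(symbols)}
    taxa: list[str] = []
    cells: dict[str, list] = {}

    body_lines = cmd.split("\n")
    # drop the 'MATRIX' keyword from the first line
    body_lines[0] = re.sub(r"^\s*matrix", "", body_lines[0], flags=re.IGNORECASE)
    for off, raw in enumerate(body_lines):
        cur = lineno + off
        line = raw.strip().rstrip(";").strip()
        if not line:
            continue
        name, rest = _parse_name(line)
        if name is None:
            raise MalformedBlockError("matrix line lacks a taxon name", cur)
        if name in cells and not interleave:
            raise DuplicateTaxonError(f"duplicate taxon {name!r}", cur)
        if name not in cells:
            taxa.append(name)
            cells[name] = []
        row = cells[name]
        i, n = 0, len(rest)
        while i < n:
            ch = rest[i]
            if ch.isspace():
                i += 1
            elif ch in "{(":
                closer = "}" if ch == "{" else ")"
                j = rest.find(closer, i)
                if j < 0:
                    raise MalformedBlockError(
                        f"unclosed polymorphism token starting with {ch!r}", cur
                    )
                states = set()
                for sym in rest[i + 1:j]:
                    if sym.isspace():
                        continue
                    if sym not in code_of:
                        raise SymbolError(
                            f"taxon {name!r}: symbol {sym!r} not in declared "
                            f"symbols {symbols!r}",
                            cur,
                        )
                    states.add(code_of[sym])
                if not states:
                    raise MalformedBlockError("empty polymorphism token", cur)
                row.append(frozenset(states))
                i = j + 1
            elif ch == missing_sym:
                row.append(MISSING)
                i += 1
            elif ch == gap_sym:
                row.append(INAPPLICABLE)
                i += 1
            elif ch in code_of:
                row.append(frozenset([code_of[ch]]))
                i += 1
            else:
                raise SymbolError(
                    f"taxon {name!r}: symbol {ch!r} not in declared symbols "
                    f"{symbols!r}",
                    cur,
                )
        if not interleave and len(row) != nchar:
            raise RowLengthError(
                f"taxon {name!r}: row has {len(row)} cells, expected {nchar}", cur
            )

    for name in taxa:
        if len(cells[name]) != nchar:
            raise RowLengthError(
                f"taxon {name!r}: row has {len(cells[name])} cells, "
                f"expected {nchar}",
                lineno,
            )
    if ntax is not None and len(taxa) != ntax:
        raise MalformedBlockError(
            f"matrix has {len(taxa)} taxa but DIMENSIONS declares ntax={ntax}",
            lineno,
        )

    characters = []
    for j in range(nchar):
        observed = set()
        for name in taxa:
            c = cells[name][j]
            if is_scored(c):
                observed |= c
        n_states = max(2, (max(observed) + 1) if observed else 2)
        characters.append(CharacterDef(index=j, n_states=n_states))

    matrix = CharacterMatrix(
        taxa=taxa, characters=characters, rows=[cells[t] for t in taxa]
    )
    if _find_block(lines, ("assumptions",)) is not None:
        matrix = parse_assumptions(clean, matrix, _already_clean=True)
    return matrix


# ---------------------------------------------------------------------------
# assumptions


def _expand_charset(spec: str, nchar: int, lineno: int | None) -> set[int]:
    """Expand a NEXUS character-set string ("2-4 7 9-.") to 0-based indices."""
    out: set[int] = set()
    for tok in spec.replace(",", " ").split():
        if tok.lower() == "all":
            out |= set(range(nchar))
            continue
        m = re.fullmatch(r"(\d+)(?:\s*-\s*(\d+|\.))?", tok)
        if m is None:
            raise AssumptionsError(f"cannot parse character set token {tok!r}", lineno)
        lo = int(m.group(1))
        hi = nchar if m.group(2) in (".",) else int(m.group(2) or lo)
        if not (1 <= lo <= hi <= nchar):
            raise AssumptionsError(
                f"character range {tok!r} outside 1..{nchar}", lineno
            )
        out |= set(range(lo - 1, hi))
    return out


def parse_assumptions(
    text: str, matrix: CharacterMatrix, *, _already_clean: bool = False
) -> CharacterMatrix:
    """Apply an ordered/unordered typeset to a matrix.

    Accepts either a full NEXUS document containing an ASSUMPTIONS block
    with a ``TYPESET`` command, or a bare fragment such as ``"ord: 2-4 7"``.
    Characters named ``ord`` are flagged ordered; all others default to
    unordered.  Naming a character as both ``ord`` and ``unord`` is an
    error, as is any 1-based index outside the matrix.
    """
    clean = text if _already_clean else _strip_comments(text)
    lines = clean.split("\n")
    span = _find_block(lines, ("assumptions",))
    assignments: list[tuple[str, str, int | None]] = []  # (kind, charset, line)

    def _split_typeset(body: str, lineno):
        # body: "ord: 2-4 7, unord: 1 5" — comma-separated kind:charset pairs
        for part in body.split(","):
            if not part.strip():
                continue
            if ":" not in part:
                raise AssumptionsError(
                    f"expected 'ord:' or 'unord:' assignment, got {part.strip()!r}",
                    lineno,
                )
            kind, charset = part.split(":", 1)
            kind = kind.strip().lower()
            if kind not in ("ord", "unord"):
                raise AssumptionsError(f"unknown character type {kind!r}", lineno)
            assignments.append((kind, charset.strip(), lineno))

    if span is not None:
        for cmd, lineno in _commands(lines, *span):
            head = cmd.split(None, 1)[0].lower().rstrip(";")
            if head != "typeset":
                continue
            body = cmd.strip().rstrip(";")
            m = re.search(r"=", body)
            if m is None:
                raise AssumptionsError("TYPESET lacks '='", lineno)
            _split_typeset(body[m.end():], lineno)
    else:
        # bare fragment mode
        frag = clean.strip().rstrip(";")
        if frag:
            _split_typeset(frag, None)

    nchar = matrix.n_characters
    ordered: set[int] = set()
    unordered: set[int] = set()
    for kind, charset, lineno in assignments:
        idx = _expand_charset(charset, nchar, lineno)
        (ordered if kind == "ord" else unordered).add
        if kind == "ord":
            ordered |= idx
        else:
            unordered |= idx
    clash = ordered & unordered
    if clash:
        pretty = " ".join(str(j + 1) for j in sorted(clash))
        raise AssumptionsError(
            f"characters assigned both ord and unord: {pretty}"
        )
    return matrix.with_ordering(ordered)


# ---------------------------------------------------------------------------
# writing


def _format_name(name: str) -> str:
    if re.fullmatch(r"[\w.\-]+", name.replace(" ", "_")):
        return name.replace(" ", "_")
    return "'" + name.replace("'", "''") + "'"


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialise a matrix (and its ordering assumptions) as a NEXUS document.

    The output round-trips through :func:`parse_nexus_matrix` to a
    cell-identical matrix with identical ordering flags.
    """
    max_state = 0
    for row in matrix.rows:
        for cell in row:
            if is_scored(cell):
                max_state = max(max_state, max(cell))
    if max_state >= len(_EXTENDED_SYMBOLS):
        raise ValueError(f"state code {max_state} exceeds writable symbol range")
    symbols = _EXTENDED_SYMBOLS[: max(max_state + 1, 2)]

    name_w = max((len(_format_name(t)) for t in matrix.taxa), default=1) + 2
    out = ["#NEXUS", "", "BEGIN CHARACTERS;"]
    out.append(
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};"
    )
    out.append(
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;'
    )
    out.append("    MATRIX")
    for taxon, row in zip(matrix.taxa, matrix.rows):
        toks = []
        for cell in row:
            if cell is MISSING:
                toks.append("?")
            elif cell is INAPPLICABLE:
                toks.append("-")
            elif len(cell) == 1:
                toks.append(symbols[next(iter(cell))])
            else:
                toks.append("{" + "".join(symbols[s] for s in sorted(cell)) + "}")
        out.append(f"    {_format_name(taxon):<{name_w}}{''.join(toks)}")
    out.append("    ;")
    out.append("END;")

    ordered = [c.index for c in matrix.characters if c.ordered]
    if ordered:
        ord_list = " ".join(str(j + 1) for j in ordered)
        out += [
            "",
            "BEGIN ASSUMPTIONS;",
            f"    TYPESET * default = ord: {ord_list};",
            "END;",
        ]
    return "\n".join(out) + "\n"
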