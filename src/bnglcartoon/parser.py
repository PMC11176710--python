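"""Parsing and serialization of BioNetGen language (BNGL) model files.

BNGL is a block-structured plain-text language for rule-based models: a
``begin molecule types`` block declares molecules with their sites and
allowed internal states, ``begin seed species`` lists initial species,
``begin observables`` names tracked pattern collections, and ``begin
reaction rules`` holds the rules themselves.  Species and patterns are
site-graphs written inline, e.g.::

    egf(r!1).egfr(ecd!1,tmd!+,Y1068~u,Y1148!?)

where ``.`` joins molecules into one connected species, ``!n`` is a shared
bond label pairing two sites, ``!+`` means bound to an unspecified partner,
``!?`` means binding status unknown, no bond token means unbound, and
``~s`` fixes a site's internal state.

This module parses such files into a :class:`ModelDocument` (preserving
comments and 1-based source line numbers) and serializes documents back to
canonical BNGL.  The VCell compartment dialect (``@COMP:`` pattern
prefixes) is supported; cBNGL site-level compartments are detected and
flagged as an unsupported dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

__all__ = [
    "BondSpec",
    "StateSpec",
    "SitePattern",
    "MoleculePattern",
    "SpeciesPattern",
    "SiteDef",
    "MoleculeTypeDef",
    "SeedSpecies",
    "Observable",
    "ReactionRule",
    "CompartmentDef",
    "Parameter",
    "Diagnostic",
    "ModelDocument",
    "BnglParseError",
    "parse_model",
    "parse_pattern",
    "parse_rule",
    "serialize_model",
    "serialize_pattern",
    "serialize_rule",
]


# ---------------------------------------------------------------------------
# Errors and diagnostics
# ---------------------------------------------------------------------------


class BnglParseError(ValueError):
    """Raised for unrecoverable syntax errors; carries line/column when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.message = message
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line})"
            if column is not None:
                where = f" (line {line}, column {column})"
        super().__init__(message + where)


@dataclass(frozen=True)
class Diagnostic:
    """A single lint/parse finding.

    ``severity`` is one of ``error``, ``warning``, ``info``.  Errors prevent
    rendering only in strict mode; the renderer otherwise draws the model as
    written.
    """

    severity: str
    code: str
    message: str
    line: int

    def as_tsv(self) -> str:
        return f"{self.severity}\t{self.code}\t{self.line}\t{self.message}"


# ---------------------------------------------------------------------------
# Pattern-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BondSpec:
    """Bond status of one site: unbound, ``!n`` labeled, ``!+`` or ``!?``."""

    kind: str  # "unbound" | "labeled" | "bound_any" | "unknown"
    label: int | None = None

    def token(self) -> str:
        if self.kind == "labeled":
            return f"!{self.label}"
        return {"unbound": "", "bound_any": "!+", "unknown": "!?"}[self.kind]


UNBOUND = BondSpec("unbound")
BOUND_ANY = BondSpec("bound_any")
BOND_UNKNOWN = BondSpec("unknown")


@dataclass(frozen=True)
class StateSpec:
    """Internal state of one site: unspecified, or named via ``~state``."""

    kind: str  # "unspecified" | "named"
    state: str | None = None

    def token(self) -> str:
        return "" if self.kind == "unspecified" else f"~{self.state}"


UNSPECIFIED = StateSpec("unspecified")


@dataclass(frozen=True)
class SitePattern:
    name: str
    state: StateSpec = UNSPECIFIED
    bond: BondSpec = UNBOUND


@dataclass(frozen=True)
class MoleculePattern:
    name: str
    sites: tuple[SitePattern, ...] = ()


@dataclass(frozen=True)
class SpeciesPattern:
    """A connected site-graph of molecules, optionally compartment-tagged.

    ``molecules`` is empty for the null species ``0`` used in synthesis and
    degradation rules.
    """

    molecules: tuple[MoleculePattern, ...] = ()
    compartment: str | None = None

    def bond_label_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for mol in self.molecules:
            for site in mol.sites:
                if site.bond.kind == "labeled":
                    counts[site.bond.label] = counts.get(site.bond.label, 0) + 1
        return counts

    def unpaired_bond_labels(self) -> list[int]:
        return sorted(l for l, c in self.bond_label_counts().items() if c != 2)


# ---------------------------------------------------------------------------
# Block-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteDef:
    name: str
    allowed_states: tuple[str, ...] = ()


@dataclass
class MoleculeTypeDef:
    name: str
    sites: tuple[SiteDef, ...] = ()
    line: int = field(default=0, compare=False)


@dataclass
class SeedSpecies:
    pattern: SpeciesPattern
    initial_amount: str = ""
    line: int = field(default=0, compare=False)


@dataclass
class Observable:
    """``obs_type`` is ``molecules``, ``species``, or ``missing`` when the
    type keyword is absent in source (a lint warning, not a parse failure)."""

    obs_type: str
    name: str
    patterns: tuple[SpeciesPattern, ...] = ()
    line: int = field(default=0, compare=False)


@dataclass
class ReactionRule:
    label: str | None
    reactants: tuple[SpeciesPattern, ...]
    products: tuple[SpeciesPattern, ...]
    reversible: bool
    rates: tuple[str, ...]
    line: int = field(default=0, compare=False)

    @property
    def reactant_compartments(self) -> tuple[str | None, ...]:
        return tuple(p.compartment for p in self.reactants)

    @property
    def product_compartments(self) -> tuple[str | None, ...]:
        return tuple(p.compartment for p in self.products)


@dataclass
class CompartmentDef:
    """``dimension`` 3 is a volume, 2 a membrane; a membrane's named parent
    should itself be volumetric."""

    name: str
    dimension: int
    size: str = "1"
    parent: str | None = None
    line: int = field(default=0, compare=False)


@dataclass
class Parameter:
    name: str
    expression: str
    line: int = field(default=0, compare=False)


# canonical block keys used for comment identities and page sections
VISUAL_BLOCKS = ("molecule_types", "species", "observables", "rules")


@dataclass
class ModelDocument:
    """A parsed BNGL file.

    Comments are keyed by ``(block_key, element_index)``; parameters and
    actions are retained but non-visual (omitted from rendered pages).
    ``dialect`` is ``plain``, ``vcell_compartmental`` when per-pattern
    ``@COMP:`` prefixes occur, or ``cbngl_detected`` when site-level
    compartment syntax is seen (unsupported).
    """

    molecule_types: list[MoleculeTypeDef] = field(default_factory=list)
    species: list[SeedSpecies] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    rules: list[ReactionRule] = field(default_factory=list)
    compartments: list[CompartmentDef] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)
    raw_blocks: list[tuple[str, str]] = field(default_factory=list)
    comments: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)
    dialect: str = "plain"
    parse_diagnostics: list[Diagnostic] = field(default_factory=list, compare=False)

    def comments_for(self, block_key: str, index: int) -> tuple[str, ...]:
        return self.comments.get((block_key, index), ())


# ---------------------------------------------------------------------------
# Low-level scanning helpers
# ---------------------------------------------------------------------------

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_COMPARTMENT_PREFIX_RE = re.compile(r"^@([A-Za-z_][A-Za-z0-9_]*)\s*:\s*")


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` (single char) at parenthesis depth zero."""
    parts: list[str] = []
    depth = 0
    cur: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _split_top_ws(text: str) -> list[str]:
    """Split on whitespace runs at depth zero (keeps parenthesised groups)."""
    parts: list[str] = []
    depth = 0
    cur: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch.isspace() and depth == 0:
            if cur:
                parts.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur))
    return parts


def _split_plus(text: str) -> list[str]:
    """Split a rule side on ``+`` at depth zero with whitespace on both sides
    (the separator between sibling patterns; ``+`` inside rate expressions is
    not whitespace-delimited in canonical BNGL)."""
    parts: list[str] = []
    depth = 0
    cur: list[str] = []
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if (
            ch == "+"
            and depth == 0
            and i > 0
            and text[i - 1].isspace()
            and i + 1 < len(text)
            and text[i + 1].isspace()
        ):
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


class _CbnglDetected(Exception):
    """Internal signal: site-level/per-molecule compartment syntax seen."""

    def __init__(self, column: int):
        self.column = column


# ---------------------------------------------------------------------------
# Pattern parsing
# ---------------------------------------------------------------------------


def _parse_site_pattern(text: str, line: int | None, col0: int) -> SitePattern:
    m = _IDENT_RE.match(text)
    if not m:
        raise BnglParseError(f"expected site name, got {text!r}", line, col0 + 1)
    name = m.group(0)
    state = UNSPECIFIED
    bond = UNBOUND
    have_state = have_bond = False
    i = m.end()
    while i < len(text):
        ch = text[i]
        col = col0 + i + 1
        if ch == "~":
            sm = _IDENT_RE.match(text, i + 1) or re.compile(r"[0-9]+").match(text, i + 1)
            if not sm:
                raise BnglParseError("'~' must be followed by a state name", line, col)
            if have_state:
                raise BnglParseError(f"site {name!r} carries more than one state token", line, col)
            state = StateSpec("named", sm.group(0))
            have_state = True
            i = sm.end()
        elif ch == "!":
            if i + 1 >= len(text):
                raise BnglParseError("'!' must be followed by a bond target", line, col)
            if have_bond:
                raise BnglParseError(f"site {name!r} carries more than one bond token", line, col)
            nxt = text[i + 1]
            if nxt == "+":
                bond = BOUND_ANY
                i += 2
            elif nxt == "?":
                bond = BOND_UNKNOWN
                i += 2
            elif nxt.isdigit():
                j = i + 1
                while j < len(text) and text[j].isdigit():
                    j += 1
                bond = BondSpec("labeled", int(text[i + 1 : j]))
                i = j
            else:
                raise BnglParseError(
                    f"'!' must be followed by a label, '+' or '?', got {nxt!r}", line, col
                )
            have_bond = True
        elif ch == "@":
            raise _CbnglDetected(col)
        elif ch == "%":
            # pattern component label (rare BNG extension); skip tag
            tm = _IDENT_RE.match(text, i + 1) or re.compile(r"[0-9]+").match(text, i + 1)
            i = tm.end() if tm else i + 1
        else:
            raise BnglParseError(f"unexpected character {ch!r} in site {name!r}", line, col)
    return SitePattern(name, state, bond)


def _parse_molecule_pattern(text: str, line: int | None, col0: int) -> MoleculePattern:
    text = text.strip()
    m = _IDENT_RE.match(text)
    if not m:
        raise BnglParseError(f"expected molecule name, got {text!r}", line, col0 + 1)
    name = m.group(0)
    rest = text[m.end() :]
    if not rest:
        return MoleculePattern(name)
    if rest.startswith("@"):
        raise _CbnglDetected(col0 + m.end() + 1)
    if not (rest.startswith("(") and rest.endswith(")")):
        if rest.startswith("(") and ")@" in rest:
            raise _CbnglDetected(col0 + m.end() + rest.index(")@") + 2)
        raise BnglParseError(f"malformed molecule {text!r}", line, col0 + 1)
    inner = rest[1:-1]
    if "@" in inner:
        raise _CbnglDetected(col0 + m.end() + 2 + inner.index("@"))
    if inner.strip() == "":
        return MoleculePattern(name)
    sites = []
    offset = m.end() + 1
    for piece in _split_top(inner, ","):
        sites.append(_parse_site_pattern(piece.strip(), line, col0 + offset))
        offset += len(piece) + 1
    return MoleculePattern(name, tuple(sites))


def parse_pattern(
    text: str,
    *,
    line: int | None = None,
    require_paired_bonds: bool = True,
    _signal_cbngl: bool = False,
) -> SpeciesPattern:
    """Parse one species pattern, optionally ``@COMP:``-prefixed.

    Molecules are split on ``.`` at top level, sites on ``,`` inside the
    parentheses; bond/state tokens are decoded per BNGL surface syntax.
    With ``require_paired_bonds`` (the default), a numeric bond label
    occurring once or more than twice raises a :class:`BnglParseError`
    naming the label; ``parse_model`` disables this and defers the check to
    lint so faulty models can still be displayed.
    """
    stripped = text.strip()
    compartment = None
    cm = _COMPARTMENT_PREFIX_RE.match(stripped)
    col0 = len(text) - len(text.lstrip())
    if cm:
        compartment = cm.group(1)
        col0 += cm.end()
        stripped = stripped[cm.end() :]
    if stripped == "0":
        return SpeciesPattern((), compartment)
    if not stripped:
        raise BnglParseError("empty pattern", line, col0 + 1)
    molecules = []
    offset = 0
    try:
        for piece in _split_top(stripped, "."):
            molecules.append(_parse_molecule_pattern(piece, line, col0 + offset))
            offset += len(piece) + 1
    except _CbnglDetected as exc:
        if _signal_cbngl:
            raise
        raise BnglParseError(
            "cBNGL site-level compartment syntax is not supported", line, exc.column
        ) from None
    pattern = SpeciesPattern(tuple(molecules), compartment)
    if require_paired_bonds:
        bad = pattern.unpaired_bond_labels()
        if bad:
            raise BnglParseError(
                f"bond label {bad[0]} must appear exactly twice in a pattern "
                f"(unpaired labels: {', '.join(map(str, bad))})",
                line,
            )
    return pattern


# ---------------------------------------------------------------------------
# Rule parsing
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\s*:\s*")
_SIDE_COMPARTMENT_RE = re.compile(r"^@([A-Za-z_][A-Za-z0-9_]*)\s*:\s+")


def _find_arrow(text: str) -> tuple[int, int, bool] | None:
    """Locate the first top-level ``->`` or ``<->``; returns (start, end,
    reversible) or None."""
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0:
            if text.startswith("<->", i):
                return i, i + 3, True
            if text.startswith("->", i):
                return i, i + 2, False
        i += 1
    return None


def _parse_rule_side(
    text: str, line: int | None, with_rates: bool, _signal_cbngl: bool = False
) -> tuple[list[SpeciesPattern], list[str]]:
    """Parse one rule side into patterns (and trailing rates on the product
    side).  A side-level ``@C: `` prefix is normalized onto every pattern of
    the side that lacks its own compartment tag."""
    side_comp = None
    text = text.strip()
    sm = _SIDE_COMPARTMENT_RE.match(text)
    if sm:
        side_comp = sm.group(1)
        text = text[sm.end() :]
    chunks = _split_plus(text)
    patterns: list[SpeciesPattern] = []
    rates: list[str] = []
    for idx, chunk in enumerate(chunks):
        chunk = chunk.strip()
        last = idx == len(chunks) - 1
        if with_rates and last:
            toks = _split_top_ws(chunk)
            if not toks:
                raise BnglParseError("empty pattern on rule side", line)
            pattern_text = toks[0]
            rate_text = chunk[chunk.index(pattern_text) + len(pattern_text) :].strip()
            if rate_text:
                rates = [r.strip() for r in _split_top(rate_text, ",") if r.strip()]
        else:
            if _split_top_ws(chunk) != [chunk] and chunk:
                raise BnglParseError(f"unexpected whitespace in pattern {chunk!r}", line)
            pattern_text = chunk
        if not pattern_text:
            raise BnglParseError("empty pattern on rule side", line)
        pat = parse_pattern(
            pattern_text, line=line, require_paired_bonds=False, _signal_cbngl=_signal_cbngl
        )
        if side_comp is not None and pat.compartment is None:
            pat = SpeciesPattern(pat.molecules, side_comp)
        patterns.append(pat)
    return patterns, rates


def parse_rule(
    text: str,
    *,
    line: int | None = None,
    require_rates: bool = True,
    _signal_cbngl: bool = False,
) -> ReactionRule:
    """Parse one logical reaction-rule line (continuations already joined).

    Reactants/products are split on top-level ``+``; ``<->`` marks a
    reversible rule, which must carry two comma-separated rate expressions
    (one for an irreversible rule).  With ``require_rates`` unset the rate
    count is not enforced (lint reports it instead).
    """
    text = text.strip()
    label = None
    lm = _LABEL_RE.match(text)
    if lm:
        label = lm.group(1)
        text = text[lm.end() :]
    arrow = _find_arrow(text)
    if arrow is None:
        raise BnglParseError("reaction rule has no '->' or '<->' arrow", line)
    start, end, reversible = arrow
    reactants, _ = _parse_rule_side(text[:start], line, False, _signal_cbngl)
    products, rates = _parse_rule_side(text[end:], line, True, _signal_cbngl)
    if require_rates:
        want = 2 if reversible else 1
        if len(rates) != want:
            kind = "reversible" if reversible else "irreversible"
            raise BnglParseError(
                f"{kind} rule requires {want} rate expression(s), found {len(rates)}", line
            )
    return ReactionRule(label, tuple(reactants), tuple(products), reversible, tuple(rates), line or 0)


# ---------------------------------------------------------------------------
# Molecule-type parsing
# ---------------------------------------------------------------------------


def _parse_site_def(text: str, line: int | None) -> SiteDef:
    m = _IDENT_RE.match(text)
    if not m:
        raise BnglParseError(f"expected site name, got {text!r}", line)
    states: list[str] = []
    i = m.end()
    while i < len(text):
        if text[i] != "~":
            raise BnglParseError(f"unexpected character {text[i]!r} in site definition", line)
        sm = _IDENT_RE.match(text, i + 1) or re.compile(r"[0-9]+").match(text, i + 1)
        if not sm:
            raise BnglParseError("'~' must be followed by a state name", line)
        states.append(sm.group(0))
        i = sm.end()
    return SiteDef(m.group(0), tuple(states))


def _parse_molecule_type(text: str, line: int | None) -> MoleculeTypeDef:
    text = text.strip()
    m = _IDENT_RE.match(text)
    if not m:
        raise BnglParseError(f"expected molecule name, got {text!r}", line)
    rest = text[m.end() :]
    if not rest:
        return MoleculeTypeDef(m.group(0), (), line or 0)
    if not (rest.startswith("(") and rest.endswith(")")):
        raise BnglParseError(f"malformed molecule type {text!r}", line)
    inner = rest[1:-1].strip()
    sites: list[SiteDef] = []
    if inner:
        for piece in _split_top(inner, ","):
            sd = _parse_site_def(piece.strip(), line)
            if len(set(sd.allowed_states)) != len(sd.allowed_states):
                raise BnglParseError(
                    f"duplicate allowed state on site {sd.name!r}", line
                )
            sites.append(sd)
    return MoleculeTypeDef(m.group(0), tuple(sites), line or 0)


# ---------------------------------------------------------------------------
# Model parsing
# ---------------------------------------------------------------------------

_BLOCK_ALIASES = {
    "molecule types": "molecule_types",
    "molecule type": "molecule_types",
    "species": "species",
    "seed species": "species",
    "observables": "observables",
    "reaction rules": "rules",
    "compartments": "compartments",
    "parameters": "parameters",
    "actions": "actions",
}

_BEGIN_RE = re.compile(r"^begin\s+(.+)$", re.IGNORECASE)
_END_RE = re.compile(r"^end\s+(.+)$", re.IGNORECASE)
_ACTION_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*\s*\(")


def _logical_lines(text: str) -> Iterator[tuple[int, str, list[str]]]:
    """Yield (first-line-number, joined statement, comments) with ``\\``
    continuations folded and ``#`` comments stripped and collected."""
    physical = text.splitlines()
    i = 0
    while i < len(physical):
        lineno = i + 1
        comments: list[str] = []
        parts: list[str] = []
        while True:
            raw = physical[i]
            if "#" in raw:
                code, _, comment = raw.partition("#")
                comments.append(comment.strip())
            else:
                code = raw
            code = code.rstrip()
            if code.endswith("\\"):
                parts.append(code[:-1])
                i += 1
                if i >= len(physical):
                    break
                continue
            parts.append(code)
            break
        i += 1
        yield lineno, " ".join(p.strip() for p in parts).strip(), comments


def parse_model(text: str) -> ModelDocument:
    """Parse BNGL source into a :class:`ModelDocument`.

    A ``begin model`` / ``end model`` wrapper is optional; block keywords
    are case-insensitive and ``begin species`` / ``begin seed species`` are
    synonyms.  Comments (``#`` to end of line) attach to the element on the
    same line, or to the next element when on a line of their own.
    Unrecognized blocks are retained as raw text with a warning; cBNGL
    site-level compartments set ``dialect=cbngl_detected`` with an
    error-severity diagnostic (fatal only in strict mode downstream).
    Unbalanced ``begin``/``end`` raises :class:`BnglParseError`.
    """
    doc = ModelDocument()
    comments: dict[tuple[str, int], list[str]] = {}
    pending: list[str] = []  # own-line comments awaiting the next element
    current: str | None = None  # canonical block key or raw block name
    current_raw: list[str] | None = None
    block_line = 0
    in_model_wrapper = False
    saw_vcell = False
    saw_cbngl = False

    def attach(block_key: str, index: int, texts: list[str]) -> None:
        if texts:
            comments.setdefault((block_key, index), []).extend(texts)

    def flush_pending_to(block_key: str, index: int) -> None:
        nonlocal pending
        if pending:
            attach(block_key, index, pending)
            pending = []

    def element_index(block_key: str) -> int:
        return len(getattr(doc, block_key))

    def note(severity: str, code: str, message: str, line: int) -> None:
        doc.parse_diagnostics.append(Diagnostic(severity, code, message, line))

    def parse_visual_pattern(text: str, line: int) -> SpeciesPattern | None:
        nonlocal saw_vcell, saw_cbngl
        try:
            pat = parse_pattern(text, line=line, require_paired_bonds=False, _signal_cbngl=True)
        except _CbnglDetected:
            saw_cbngl = True
            note(
                "error",
                "cbngl-unsupported",
                "cBNGL site-level compartments are not supported; "
                "use the VCell per-pattern '@COMP:' dialect",
                line,
            )
            return None
        if pat.compartment is not None:
            saw_vcell = True
        return pat

    for lineno, stmt, line_comments in _logical_lines(text):
        in_visual = current in VISUAL_BLOCKS
        if not stmt:
            if line_comments and in_visual:
                pending.extend(line_comments)
            continue

        bm = _BEGIN_RE.match(stmt)
        em = _END_RE.match(stmt)
        normalized = re.sub(r"\s+", " ", (bm or em).group(1).strip().lower()) if (bm or em) else ""

        if bm:
            if normalized == "model":
                if in_model_wrapper:
                    raise BnglParseError("nested 'begin model'", lineno)
                in_model_wrapper = True
                continue
            if current is not None:
                raise BnglParseError(
                    f"'begin {normalized}' inside unclosed block started at line {block_line}",
                    lineno,
                )
            block_line = lineno
            pending = []
            if normalized in _BLOCK_ALIASES:
                current = _BLOCK_ALIASES[normalized]
                current_raw = None
            else:
                current = normalized
                current_raw = []
                note("warning", "unrecognized-block", f"unrecognized block {normalized!r} retained as raw text", lineno)
            continue

        if em:
            if normalized == "model":
                if not in_model_wrapper:
                    raise BnglParseError("'end model' without 'begin model'", lineno)
                if current is not None:
                    raise BnglParseError(
                        f"'end model' inside unclosed block started at line {block_line}", lineno
                    )
                in_model_wrapper = False
                continue
            if current is None:
                raise BnglParseError(f"'end {normalized}' without matching 'begin'", lineno)
            expected = _BLOCK_ALIASES.get(normalized, normalized)
            if expected != current:
                raise BnglParseError(
                    f"'end {normalized}' does not match block started at line {block_line}",
                    lineno,
                )
            # trailing own-line comments attach to the block's last element
            if pending and current in VISUAL_BLOCKS:
                attach(current, max(0, element_index(current) - 1), pending)
                pending = []
            if current_raw is not None:
                doc.raw_blocks.append((current, "\n".join(current_raw)))
            current = None
            current_raw = None
            continue

        if current is None:
            # outside any block: treat calls as actions, ignore stray text
            if _ACTION_RE.match(stmt):
                doc.actions.append(stmt)
            else:
                note("warning", "stray-statement", f"statement outside any block: {stmt!r}", lineno)
            continue

        if current_raw is not None:
            current_raw.append(stmt)
            continue

        if current == "parameters":
            toks = stmt.split(None, 1)
            name = toks[0].rstrip("=")
            expr = toks[1].lstrip("= ").strip() if len(toks) > 1 else ""
            doc.parameters.append(Parameter(name, expr, lineno))
            continue

        if current == "actions":
            doc.actions.append(stmt)
            continue

        if current == "compartments":
            toks = _split_top_ws(stmt)
            if len(toks) < 2 or toks[1] not in ("2", "3"):
                raise BnglParseError(f"malformed compartment definition {stmt!r}", lineno)
            doc.compartments.append(
                CompartmentDef(
                    toks[0],
                    int(toks[1]),
                    toks[2] if len(toks) > 2 else "1",
                    toks[3] if len(toks) > 3 else None,
                    lineno,
                )
            )
            continue

        # visual blocks from here on
        idx = element_index(current)
        flush_pending_to(current, idx)
        attach(current, idx, line_comments)

        if current == "molecule_types":
            doc.molecule_types.append(_parse_molecule_type(stmt, lineno))
        elif current == "species":
            toks = _split_top_ws(stmt)
            # leading numeric index (VCell export style) is dropped
            if toks and toks[0].isdigit() and len(toks) > 1:
                toks = toks[1:]
            pat = parse_visual_pattern(toks[0], lineno)
            if pat is None:
                pat = SpeciesPattern()
            doc.species.append(SeedSpecies(pat, " ".join(toks[1:]), lineno))
        elif current == "observables":
            toks = _split_top_ws(stmt)
            obs_type = "missing"
            if toks and toks[0].lower() in ("molecules", "species"):
                obs_type = toks[0].lower()
                toks = toks[1:]
            if not toks:
                raise BnglParseError("observable without a name", lineno)
            name, pattern_toks = toks[0], toks[1:]
            pats: list[SpeciesPattern] = []
            for tok in pattern_toks:
                for piece in _split_top(tok, ","):
                    piece = piece.strip()
                    if not piece:
                        continue
                    pat = parse_visual_pattern(piece, lineno)
                    if pat is not None:
                        pats.append(pat)
            doc.observables.append(Observable(obs_type, name, tuple(pats), lineno))
        elif current == "rules":
            try:
                rule = parse_rule(stmt, line=lineno, require_rates=False, _signal_cbngl=True)
            except _CbnglDetected:
                saw_cbngl = True
                note(
                    "error",
                    "cbngl-unsupported",
                    "cBNGL site-level compartments are not supported; "
                    "use the VCell per-pattern '@COMP:' dialect",
                    lineno,
                )
                continue
            if any(c is not None for c in rule.reactant_compartments + rule.product_compartments):
                saw_vcell = True
            doc.rules.append(rule)

    if current is not None:
        raise BnglParseError("unclosed block at end of input", block_line)
    if in_model_wrapper:
        raise BnglParseError("'begin model' without 'end model'", 1)

    doc.comments = {k: tuple(v) for k, v in comments.items()}
    if saw_cbngl:
        doc.dialect = "cbngl_detected"
    elif saw_vcell:
        doc.dialect = "vcell_compartmental"
    return doc


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def serialize_pattern(pattern: SpeciesPattern) -> str:
    if not pattern.molecules:
        body = "0"
    else:
        body = ".".join(
            mol.name
            + "("
            + ",".join(s.name + s.state.token() + s.bond.token() for s in mol.sites)
            + ")"
            for mol in pattern.molecules
        )
    if pattern.compartment:
        return f"@{pattern.compartment}:{body}"
    return body


def serialize_rule(rule: ReactionRule) -> str:
    arrow = "<->" if rule.reversible else "->"
    lhs = " + ".join(serialize_pattern(p) for p in rule.reactants)
    rhs = " + ".join(serialize_pattern(p) for p in rule.products)
    parts = []
    if rule.label:
        parts.append(f"{rule.label}:")
    parts.append(f"{lhs} {arrow} {rhs}")
    if rule.rates:
        parts.append(", ".join(rule.rates))
    return " ".join(parts)


def _serialize_molecule_type(mt: MoleculeTypeDef) -> str:
    return (
        mt.name
        + "("
        + ",".join(s.name + "".join(f"~{st}" for st in s.allowed_states) for s in mt.sites)
        + ")"
    )


def serialize_model(doc: ModelDocument) -> str:
    """Emit canonical BNGL that re-parses to an equal :class:`ModelDocument`.

    Block order is normalized (parameters, compartments, molecule types,
    seed species, observables, reaction rules, raw blocks, actions);
    comments are written as own-line comments immediately before their
    element, which re-attaches them to the same element on re-parse.
    """
    out: list[str] = []

    def emit_block(name: str, lines: Iterable[str]) -> None:
        lines = list(lines)
        if not lines:
            return
        out.append(f"begin {name}")
        out.extend(f"  {ln}" for ln in lines)
        out.append(f"end {name}")
        out.append("")

    def with_comments(block_key: str, i: int, body: str) -> list[str]:
        return [f"# {c}" if c else "#" for c in doc.comments_for(block_key, i)] + [body]

    emit_block("parameters", (f"{p.name} {p.expression}".rstrip() for p in doc.parameters))
    emit_block(
        "compartments",
        (
            " ".join(filter(None, (c.name, str(c.dimension), c.size, c.parent)))
            for c in doc.compartments
        ),
    )
    emit_block(
        "molecule types",
        (
            ln
            for i, mt in enumerate(doc.molecule_types)
            for ln in with_comments("molecule_types", i, _serialize_molecule_type(mt))
        ),
    )
    emit_block(
        "seed species",
        (
            ln
            for i, sp in enumerate(doc.species)
            for ln in with_comments(
                "species", i, f"{serialize_pattern(sp.pattern)} {sp.initial_amount}".rstrip()
            )
        ),
    )

    def obs_line(o: Observable) -> str:
        head = {"molecules": "Molecules ", "species": "Species ", "missing": ""}[o.obs_type]
        pats = " ".join(serialize_pattern(p) for p in o.patterns)
        return f"{head}{o.name} {pats}".rstrip()

    emit_block(
        "observables",
        (
            ln
            for i, o in enumerate(doc.observables)
            for ln in with_comments("observables", i, obs_line(o))
        ),
    )
    emit_block(
        "reaction rules",
        (
            ln
            for i, r in enumerate(doc.rules)
            for ln in with_comments("rules", i, serialize_rule(r))
        ),
    )
    for name, raw in doc.raw_blocks:
        out.append(f"begin {name}")
        out.extend(f"  {ln}" for ln in raw.splitlines())
        out.append(f"end {name}")
        out.append("")
    out.extend(doc.actions)
    return "\n".join(out).rstrip("\n") + ("\n" if out else "")
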