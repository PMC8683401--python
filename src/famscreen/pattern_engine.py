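"""PROSITE-dialect motif patterns: parsing, representation and sequence scanning.

The dialect covers the notation used for plant CNGC consensus keys and for the
standard post-translational-modification (PTM) site patterns:

* tokens separated by ``-`` (en/em dashes and whitespace are tolerated, since
  printed keys mix them freely);
* a plain letter matches that residue; ``X``/``x`` is a wildcard;
* ``[ST]`` is a residue class, ``{P}`` an excluded class (any standard residue
  except those listed);
* ``X(2)``, ``X(1,2)``, ``X(7,14)`` are bounded repeats; a count list such as
  ``X(0,1,2)`` is read as min..max of the listed values;
* ``<`` / ``>`` anchor a pattern to the sequence start / end;
* a trailing ``.`` (PROSITE terminator) is ignored.

Matching semantics: every start position is tested independently, so
overlapping matches at distinct starts are all reported.  At a given start,
variable-length elements take the shortest satisfying expansion, which makes
match coordinates deterministic and, for fixed-length patterns, reproduces
classic PROSITE/ScanProsite behaviour exactly.  Non-standard sequence letters
(X, B, Z, U, ...) match wildcards only — never fixed residues, classes or
excluded classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "STANDARD_AA",
    "ElementKind",
    "PatternElement",
    "MotifPattern",
    "Match",
    "PatternParseError",
    "parse_pattern",
    "scan",
    "count_matches",
    "ptm_patterns",
    "ptm_scan",
    "read_pattern_file",
    "write_pattern_file",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ElementKind(str, Enum):
    FIXED = "fixed-residue"
    CLASS = "residue-class"
    EXCLUDED = "excluded-class"
    WILDCARD = "wildcard"


class PatternParseError(ValueError):
    """Raised for malformed pattern text; the message names the offending token."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern token: a residue matcher plus a bounded repeat count."""

    kind: ElementKind
    residues: frozenset[str] = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not self.residues <= STANDARD_AA:
            bad = "".join(sorted(self.residues - STANDARD_AA))
            raise PatternParseError(f"non-standard residue letter(s) {bad!r}")
        if self.kind is ElementKind.FIXED and len(self.residues) != 1:
            raise PatternParseError("fixed-residue element needs exactly one residue")
        if self.kind in (ElementKind.CLASS, ElementKind.EXCLUDED) and not self.residues:
            raise PatternParseError("empty residue class")
        if self.kind is ElementKind.WILDCARD and self.residues:
            raise PatternParseError("wildcard element carries no residues")
        if self.min_repeat < 0 or self.max_repeat < self.min_repeat:
            raise PatternParseError(
                f"bad repeat bounds ({self.min_repeat},{self.max_repeat})"
            )
        if self.min_repeat == 0 and self.kind is not ElementKind.WILDCARD:
            raise PatternParseError("zero repeat is only permitted for wildcards")

    def matches_letter(self, ch: str) -> bool:
        if self.kind is ElementKind.WILDCARD:
            return True
        if ch not in STANDARD_AA:  # ambiguity codes never satisfy explicit matchers
            return False
        if self.kind is ElementKind.EXCLUDED:
            return ch not in self.residues
        return ch in self.residues

    def token(self) -> str:
        if self.kind is ElementKind.WILDCARD:
            body = "X"
        elif self.kind is ElementKind.FIXED:
            body = next(iter(self.residues))
        elif self.kind is ElementKind.CLASS:
            body = "[" + "".join(sorted(self.residues)) + "]"
        else:
            body = "{" + "".join(sorted(self.residues)) + "}"
        if self.min_repeat == self.max_repeat:
            return body if self.min_repeat == 1 else f"{body}({self.min_repeat})"
        return f"{body}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of :class:`PatternElement` with optional terminal anchors."""

    elements: tuple[PatternElement, ...]
    name: str = ""
    source: str = ""
    anchored_start: bool = False
    anchored_end: bool = False

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternParseError("empty pattern")
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.min_span < 1:
            raise PatternParseError("pattern must be able to match at least one residue")

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def to_string(self) -> str:
        body = "-".join(e.token() for e in self.elements)
        return ("<" if self.anchored_start else "") + body + (">" if self.anchored_end else "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class Match:
    """Half-open 0-based match interval plus the matched substring."""

    start: int
    end: int
    matched_text: str


_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})
_TOKEN_RE = re.compile(
    r"^(?P<body>[A-Za-z]|\[[A-Za-z]+\]|\{[A-Za-z]+\})"
    r"(?:\((?P<counts>\d+(?:,\d+)*)\))?$"
)


def _strip_outer_brackets(text: str) -> str:
    # Printed consensus keys wrap the whole pattern in one outer bracket pair;
    # strip it only when the interior clearly holds further structure, so that
    # a bare class token like "[ST]" is left alone.
    if not (text.startswith("[") and text.endswith("]")):
        return text
    depth = 0
    for i, ch in enumerate(text):
        depth += ch == "["
        depth -= ch == "]"
        if depth == 0 and i < len(text) - 1:
            return text  # first bracket closes early: not an outer wrapper
    inner = text[1:-1]
    if any(c in inner for c in "[]{}()-"):
        return inner
    return text


def parse_pattern(text: str, name: str = "", source: str = "") -> MotifPattern:
    """Parse pattern text in the supported PROSITE dialect.

    Raises
    ------
    PatternParseError
        If the text is empty, a token is malformed, or repeat bounds are
        inverted; the message names the offending token.
    """
    raw = text.translate(_DASHES)
    raw = re.sub(r"\s+", "", raw)
    raw = raw.rstrip(".")
    raw = _strip_outer_brackets(raw)
    if not raw:
        raise PatternParseError("empty pattern")

    anchored_start = raw.startswith("<")
    anchored_end = raw.endswith(">")
    raw = raw.removeprefix("<").removesuffix(">").strip("-")
    if not raw:
        raise PatternParseError("pattern has anchors but no elements")

    elements: list[PatternElement] = []
    for tok in raw.split("-"):
        if not tok:
            raise PatternParseError("empty token (consecutive separators)")
        m = _TOKEN_RE.match(tok)
        if m is None:
            raise PatternParseError(f"malformed token {tok!r}")
        body = m.group("body")
        counts = m.group("counts")
        if counts is None:
            lo = hi = 1
        else:
            vals = [int(v) for v in counts.split(",")]
            if vals != sorted(vals):
                raise PatternParseError(
                    f"token {tok!r}: repeat counts must be non-decreasing"
                )
            lo, hi = vals[0], vals[-1]
        try:
            elements.append(_element_from_body(body, lo, hi))
        except PatternParseError as exc:
            raise PatternParseError(f"token {tok!r}: {exc}") from None
    return MotifPattern(
        tuple(elements),
        name=name,
        source=source,
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def _element_from_body(body: str, lo: int, hi: int) -> PatternElement:
    if body.startswith("["):
        letters = frozenset(body[1:-1].upper())
        if "X" in letters:
            raise PatternParseError("wildcard X not permitted inside a class")
        kind = ElementKind.FIXED if len(letters) == 1 else ElementKind.CLASS
        return PatternElement(kind, letters, lo, hi)
    if body.startswith("{"):
        return PatternElement(ElementKind.EXCLUDED, frozenset(body[1:-1].upper()), lo, hi)
    letter = body.upper()
    if letter == "X":
        return PatternElement(ElementKind.WILDCARD, frozenset(), lo, hi)
    return PatternElement(ElementKind.FIXED, frozenset(letter), lo, hi)


def _match_at(pattern: MotifPattern, seq: str, start: int) -> int | None:
    """Shortest match end for ``pattern`` anchored at ``start``, or None."""
    elements = pattern.elements
    n = len(seq)

    def walk(i: int, pos: int) -> int | None:
        if i == len(elements):
            if pattern.anchored_end and pos != n:
                return None
            return pos
        el = elements[i]
        # verify the mandatory prefix, then extend one letter at a time
        limit = min(el.max_repeat, n - pos)
        if el.min_repeat > limit:
            return None
        for k in range(el.min_repeat):
            if not el.matches_letter(seq[pos + k]):
                return None
        r = el.min_repeat
        while True:
            end = walk(i + 1, pos + r)
            if end is not None:
                return end
            if r == limit or not el.matches_letter(seq[pos + r]):
                return None
            r += 1

    return walk(0, start)


def scan(pattern: MotifPattern, seq: str) -> list[Match]:
    """All matches of ``pattern`` in ``seq`` (one per matching start position).

    The empty sequence yields an empty list.  Sequence letters are handled
    case-insensitively.
    """
    seq = seq.upper()
    matches: list[Match] = []
    starts: Iterable[int]
    if pattern.anchored_start:
        starts = (0,) if len(seq) >= pattern.min_span else ()
    else:
        starts = range(len(seq) - pattern.min_span + 1)
    for s in starts:
        end = _match_at(pattern, seq, s)
        if end is not None:
            matches.append(Match(s, end, seq[s:end]))
    return matches


def count_matches(pattern: MotifPattern, seq: str) -> int:
    """Number of matching start positions (the reporting convention here)."""
    return len(scan(pattern, seq))


# ---------------------------------------------------------------------------
# pattern files and the bundled PTM set


def read_pattern_file(path) -> list[MotifPattern]:
    """Read a ``NAME<TAB>PATTERN[<TAB>SOURCE]`` file; '#' lines are comments."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PatternParseError(f"bad pattern-file line: {line!r}")
            name, text = parts[0], parts[1]
            source = parts[2] if len(parts) > 2 else ""
            patterns.append(parse_pattern(text, name=name, source=source))
    return patterns


def write_pattern_file(patterns: Iterable[MotifPattern], path) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(f"{p.name}\t{p.to_string()}\t{p.source}\n")


def ptm_patterns() -> list[MotifPattern]:
    """The bundled PTM/phosphorylation site patterns (PROSITE entries)."""
    ref = resources.files("famscreen").joinpath("data/ptm_patterns.tsv")
    with resources.as_file(ref) as path:
        return read_pattern_file(path)


def ptm_scan(seq: str, patterns: list[MotifPattern] | None = None) -> pd.DataFrame:
    """Scan a protein for all bundled PTM site classes.

    Returns a table with one row per site class: ``site_class``, ``pattern``,
    ``count`` and ``positions`` (1-based match start positions, for reporting).
    """
    if patterns is None:
        patterns = ptm_patterns()
    rows = []
    for p in patterns:
        hits = scan(p, seq)
        rows.append(
            {
                "site_class": p.name,
                "pattern": p.to_string(),
                "count": len(hits),
                "positions": [m.start + 1 for m in hits],
            }
        )
    return pd.DataFrame(rows, columns=["site_class", "pattern", "count", "positions"])
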