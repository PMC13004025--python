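"""Motif pattern grammar and sequence scanning.

The grammar covers short linear motif (SLiM) consensus patterns of the
kind used for endosomal recycling motifs:

* a literal residue (``L``) matches exactly that amino acid;
* ``@`` matches any residue;
* a bracketed class (``[FYW]``) matches any listed residue;
* an optional C-terminal anchor restricts matches to those ending at the
  final residue of the protein (used for PDZ-binding motifs, which must
  terminate the chain).

There is deliberately no repetition, alternation or negation: the five
published recycling-motif consensi (``L@@L``, ``N@@Y``, ``[FYW]@[LMV]``,
``[GAVCPLIMWF]@[FYV]@[FY]``, ``[DE][ST]@[GAVCPLIMWF]``) need none of it.

Coordinates are 1-based and inclusive throughout, so a match prints in
the field's usual ``start-MOTIF`` notation (e.g. ``500-LEYL``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "STANDARD_RESIDUES",
    "PatternElement",
    "MotifPattern",
    "RawMatch",
    "PatternParseError",
    "parse_pattern",
    "find_matches",
    "pattern_as_regular_expression",
]


class PatternParseError(ValueError):
    """Raised for malformed pattern text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


@dataclass(frozen=True)
class PatternElement:
    """One position of a motif pattern.

    ``allowed_residues`` is a frozenset of 1-letter codes, or empty with
    ``is_any`` set, meaning the wildcard ``@`` position.  The wildcard
    matches any letter (including nonstandard codes such as X or U);
    explicit sets match only their listed residues, so an ambiguous
    residue never satisfies a specific class.
    """

    allowed_residues: frozenset[str] = frozenset()
    is_any: bool = False

    def __post_init__(self) -> None:
        if self.is_any:
            if self.allowed_residues:
                raise ValueError("wildcard element must not list residues")
        else:
            if not self.allowed_residues:
                raise ValueError("element residue set is empty")
            bad = set(self.allowed_residues) - STANDARD_RESIDUES
            if bad:
                raise ValueError(f"nonstandard residues in element: {sorted(bad)}")

    def accepts(self, residue: str) -> bool:
        if self.is_any:
            return residue.isalpha()
        return residue in self.allowed_residues

    def render(self) -> str:
        if self.is_any:
            return "@"
        if len(self.allowed_residues) == 1:
            return next(iter(self.allowed_residues))
        return "[" + "".join(sorted(self.allowed_residues)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif pattern.

    ``anchor_cterm`` requires the match to end at the protein's final
    residue (the PDZ-motif convention).
    """

    source_text: str
    elements: tuple[PatternElement, ...]
    anchor_cterm: bool = False
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Canonical text form (bracket classes in alphabetical order)."""
        return "".join(e.render() for e in self.elements)


@dataclass(frozen=True)
class RawMatch:
    """One pattern occurrence: 1-based inclusive coordinates plus the slice."""

    start: int
    end: int
    matched_seq: str

    def __str__(self) -> str:  # the field's "position-MOTIF" notation
        return f"{self.start}-{self.matched_seq}"


def parse_pattern(text: str, anchor_cterm: bool = False, name: str = "") -> MotifPattern:
    """Compile pattern text into a :class:`MotifPattern`.

    Parameters
    ----------
    text
        Pattern string, e.g. ``"L@@L"`` or ``"[DE][ST]@[GAVCPLIMWF]"``.
        Lowercase input is uppercased.
    anchor_cterm
        If true, matches must end at the final residue of the scanned
        protein.
    name
        Optional label carried through to match output.

    Raises
    ------
    PatternParseError
        On empty input, unbalanced/empty/nested brackets, or characters
        outside the 20 standard residue codes and ``@ [ ]``.
    """
    if not text:
        raise PatternParseError("empty pattern", 0)
    text = text.upper()
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "@":
            elements.append(PatternElement(is_any=True))
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise PatternParseError("unbalanced bracket", i + 1)
            group = text[i + 1 : j]
            if not group:
                raise PatternParseError("empty bracket group", i + 1)
            for k, g in enumerate(group):
                if g == "[":
                    raise PatternParseError("nested bracket", i + 2 + k)
                if g not in STANDARD_RESIDUES:
                    raise PatternParseError(
                        f"invalid residue code {g!r} in bracket group", i + 2 + k
                    )
            elements.append(PatternElement(frozenset(group)))
            i = j + 1
        elif ch == "]":
            raise PatternParseError("unbalanced bracket", i + 1)
        elif ch in STANDARD_RESIDUES:
            elements.append(PatternElement(frozenset(ch)))
            i += 1
        else:
            raise PatternParseError(f"invalid character {ch!r}", i + 1)
    return MotifPattern(
        source_text=text, elements=tuple(elements), anchor_cterm=anchor_cterm, name=name
    )


def find_matches(pattern: MotifPattern, sequence: str, offset: int = 1) -> list[RawMatch]:
    """Enumerate all (overlapping) matches of ``pattern`` in ``sequence``.

    Parameters
    ----------
    pattern
        Compiled pattern; if ``anchor_cterm`` is set, only an occurrence
        ending at the last residue of ``sequence`` is reported.
    sequence
        Amino-acid string (uppercased on ingest).
    offset
        1-based coordinate of the sequence's first residue, so a peptide
        excised from a larger protein reports native numbering.

    Returns
    -------
    list of RawMatch, sorted by start; empty if the sequence is shorter
    than the pattern.
    """
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    sequence = sequence.upper()
    m = pattern.length
    n = len(sequence)
    matches: list[RawMatch] = []
    if n < m:
        return matches
    starts = range(n - m, n - m + 1) if pattern.anchor_cterm else range(n - m + 1)
    for i in starts:
        if all(el.accepts(sequence[i + k]) for k, el in enumerate(pattern.elements)):
            matches.append(
                RawMatch(start=offset + i, end=offset + i + m - 1, matched_seq=sequence[i : i + m])
            )
    return matches


def pattern_as_regular_expression(pattern: MotifPattern) -> str:
    """Equivalent regular-expression text (character classes only).

    Scanning with ``re`` in a lookahead loop yields the same match set as
    :func:`find_matches`; this translation exists to support independent
    cross-checks, not the main scan path.
    """
    parts: list[str] = []
    for el in pattern.elements:
        if el.is_any:
            parts.append("[A-Z]")
        elif len(el.allowed_residues) == 1:
            parts.append(next(iter(el.allowed_residues)))
        else:
            parts.append("[" + "".join(sorted(el.allowed_residues)) + "]")
    body = "".join(parts)
    if pattern.anchor_cterm:
        body += "$"
    return body


def regex_find_matches(pattern: MotifPattern, sequence: str, offset: int = 1) -> list[RawMatch]:
    """Regex-based overlapping scan — the independent route for cross-checks."""
    sequence = sequence.upper()
    rx = re.compile("(?=(" + pattern_as_regular_expression(pattern) + "))")
    out = []
    for m in rx.finditer(sequence):
        s = m.start()
        frag = m.group(1)
        out.append(RawMatch(start=offset + s, end=offset + s + len(frag) - 1, matched_seq=frag))
    return out
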