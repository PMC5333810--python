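"""Consensus-motif pattern language and scanner.

Pax subfamilies carry short diagnostic motifs written in a bracket consensus
notation: uppercase literals, ``[TS]``-style residue classes, and counted
wildcards (``X2`` or, as sometimes typeset, ``X_2_``).  Examples from the
lophotrochozoan Pax repertoire: the Pax1/9 octapeptide ``H[ST]V[ST][DN][IL]LG``,
the Pax2/5/8 octapeptide ``Y[TS]IX2ILG``, the Pax4/6 linker ``MDKL``, and three
long Paxβ motifs.

Matching semantics:

* a wildcard element matches any residue, including the unknown residue ``X``;
* ``X`` in a *sequence* fails literals and classes (an unknown residue is
  never positive evidence);
* mismatches are counted per pattern element — a failed element counts one
  regardless of its repeat count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .seqio import AMINO_ACIDS

__all__ = [
    "PatternElement", "MotifPattern", "MotifHit", "PatternSyntaxError",
    "parse_pattern", "scan", "find_basic_signal", "load_motif_registry",
    "default_max_mismatch",
]

BASIC_RESIDUES = frozenset("KR")


class PatternSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PatternElement:
    """One element of a consensus pattern.

    kind is ``literal`` (one residue), ``class`` (two or more alternative
    residues) or ``wildcard`` (anything).  ``residues`` preserves the order in
    which class members were written, so re-serialization is faithful.
    """

    kind: str                      # literal | class | wildcard
    residues: tuple[str, ...]      # empty for wildcard
    repeat: int = 1

    def __post_init__(self):
        if self.repeat < 1:
            raise PatternSyntaxError(f"zero/negative repeat in element {self!r}")
        if self.kind == "literal" and len(self.residues) != 1:
            raise PatternSyntaxError("literal element needs exactly one residue")
        if self.kind == "class" and len(self.residues) < 2:
            raise PatternSyntaxError("residue class needs at least two residues")
        if self.kind == "wildcard" and self.residues:
            raise PatternSyntaxError("wildcard element carries no residues")

    def matches(self, residue: str) -> bool:
        if self.kind == "wildcard":
            return True
        return residue in self.residues  # 'X' in sequence fails here by design

    def serialize(self) -> str:
        if self.kind == "wildcard":
            return "X" if self.repeat == 1 else f"X{self.repeat}"
        body = self.residues[0] if self.kind == "literal" else "[" + "".join(self.residues) + "]"
        return body * self.repeat


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[PatternElement, ...]
    text: str

    @property
    def expanded_length(self) -> int:
        return sum(e.repeat for e in self.elements)

    def serialize(self) -> str:
        """Canonical form: ``X_2_`` subscripts rendered as ``X2``."""
        return "".join(e.serialize() for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    pattern_text: str
    start: int   # 0-based
    end: int     # exclusive
    mismatches: int


_SUBSCRIPT = re.compile(r"_(\d+)_")


def parse_pattern(text: str) -> MotifPattern:
    """Parse bracket-notation consensus into a :class:`MotifPattern`.

    Accepts both ``X2`` and the subscripted rendering ``X_2_`` for counted
    wildcards.  Raises :class:`PatternSyntaxError` on unbalanced brackets,
    empty classes or a zero repeat count.
    """
    if not text:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced '[' at position {i} in {text!r}")
            members = text[i + 1:j]
            if not members:
                raise PatternSyntaxError(f"empty class at position {i} in {text!r}")
            if any(m not in AMINO_ACIDS for m in members):
                raise PatternSyntaxError(f"non-residue in class {members!r} in {text!r}")
            elements.append(PatternElement("class", tuple(members)))
            i = j + 1
        elif c == "]":
            raise PatternSyntaxError(f"unbalanced ']' at position {i} in {text!r}")
        elif c == "X":
            i += 1
            repeat = 1
            m = _SUBSCRIPT.match(text, i)
            if m:
                repeat = int(m.group(1))
                i = m.end()
            else:
                j = i
                while j < n and text[j].isdigit():
                    j += 1
                if j > i:
                    repeat = int(text[i:j])
                    i = j
            if repeat < 1:
                raise PatternSyntaxError(f"zero repeat in {text!r}")
            elements.append(PatternElement("wildcard", (), repeat))
        elif c in AMINO_ACIDS:
            elements.append(PatternElement("literal", (c,)))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {c!r} at position {i} in {text!r}")
    return MotifPattern(tuple(elements), text)


def default_max_mismatch(pattern: MotifPattern) -> int:
    """0 for short motifs (<10 elements), 2 for long ones (the 31-column Paxβ motif)."""
    return 0 if len(pattern.elements) < 10 else 2


def scan(sequence: str, pattern: MotifPattern, max_mismatch: int = 0) -> list[MotifHit]:
    """All windows matching ``pattern`` with at most ``max_mismatch`` element failures.

    Overlapping hits are all reported, sorted by start; downstream consumers
    take the best-scoring.
    """
    L = pattern.expanded_length
    hits = []
    for start in range(len(sequence) - L + 1):
        mm = 0
        pos = start
        ok = True
        for el in pattern.elements:
            if el.kind != "wildcard":
                if any(not el.matches(sequence[pos + k]) for k in range(el.repeat)):
                    mm += 1
                    if mm > max_mismatch:
                        ok = False
                        break
            pos += el.repeat
        if ok:
            hits.append(MotifHit(pattern.text, start, start + L, mm))
    return hits


def find_basic_signal(sequence: str, window_start: int = 0,
                      window_len: Optional[int] = None,
                      min_basic: int = 4) -> Optional[MotifHit]:
    """Leftmost length-4 run containing at least ``min_basic`` K/R residues.

    Operationalizes the quadribasic (``min_basic=4`` or relaxed 3) and
    tribasic (``min_basic=3``) signals found after the Pax2/5/8 octapeptide,
    after the Paxβ PRD, and in the first helix of the PoxNeuro PRD.
    """
    if window_len is None:
        window_len = len(sequence) - window_start
    if window_start < 0 or window_start + window_len > len(sequence) or window_len < 0:
        raise IndexError(
            f"window [{window_start}, {window_start + window_len}) outside sequence of "
            f"length {len(sequence)}")
    end = window_start + window_len
    for s in range(window_start, end - 3):
        run = sequence[s:s + 4]
        if sum(r in BASIC_RESIDUES for r in run) >= min_basic:
            return MotifHit(f"basic{min_basic}of4", s, s + 4, 0)
    return None


def expand(pattern: MotifPattern, pick: int = 0, wildcard: str = "A") -> str:
    """One concrete instance of a pattern (class member ``pick``, fixed wildcard).

    By construction the result scans against the pattern with 0 mismatches.
    """
    out = []
    for el in pattern.elements:
        if el.kind == "wildcard":
            out.append(wildcard * el.repeat)
        else:
            out.append(el.residues[pick % len(el.residues)] * el.repeat)
    return "".join(out)


def load_motif_registry(path=None) -> dict[str, dict]:
    """Bundled registry of named diagnostic motifs.

    Returns ``{name: {"pattern": MotifPattern, "family": str}}``.
    """
    if path is None:
        text = resources.files("lophopax.data").joinpath("motif_registry.tsv").read_text("utf-8")
    else:
        text = open(path, encoding="utf-8").read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = {}
    for ln in lines[1:]:
        name, pattern, family = ln.split("\t")
        out[name] = {"pattern": parse_pattern(pattern), "family": family}
    return out
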