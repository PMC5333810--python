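"""Sequence and fixture I/O.

Protein sequences are held as :class:`ProteinRecord` (20 canonical residues
plus ``X`` for unknown), alignments as rectangular :class:`AlignmentMatrix`
with ``-`` gaps.  The bundled reclassification fixture reproduces the
published table of previously non- or mis-identified lophotrochozoan Pax
sequences (accession, submitted name, proposed name, species, higher taxon).

Coordinates everywhere in this package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: legal residue alphabet: the 20 canonical amino acids plus 'X' (unknown)
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"

#: canonical family / proposed-name vocabulary used in reports
PROPOSED_NAMES = {
    "Pax", "Pax1/9", "Pax2/5/8", "Pax3/7", "Pax6", "Pax6A", "Pax6B", "Pax9",
    "Paxβ", "Paxβ1", "Paxβ2", "Paxβlike", "PoxN", "eyg",
}

# ASCII aliases for the Greek beta; canonical storage is UTF-8 'β'.
_BETA_ALIASES = ("Paxbeta", "PaxB")


class ParseError(ValueError):
    """Malformed input file (message names the offending line)."""


class AlignmentError(ValueError):
    """Ragged or otherwise invalid alignment."""


def canonical_name(name: str) -> str:
    """Normalize ASCII beta aliases (``PaxB``, ``Paxbeta``) to ``Paxβ``."""
    for alias in _BETA_ALIASES:
        if name.startswith(alias):
            return "Paxβ" + name[len(alias):]
    return name


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with minimal metadata."""

    id: str
    sequence: str
    species: str = ""
    source_annotation: Optional[str] = None
    is_fragment: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = self.sequence.upper().replace("*", "")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)}; "
                f"allowed alphabet is the 20 canonical amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def aligned(cls, id: str, sequence: str, **kw) -> "ProteinRecord":
        """Construct a record whose sequence may contain ``-`` gap characters."""
        sequence = sequence.upper().replace("*", "")
        bad = set(sequence) - ALPHABET - {GAP}
        if bad:
            raise ValueError(f"{id}: illegal residue(s) {sorted(bad)}")
        rec = object.__new__(cls)
        rec.id = id
        rec.sequence = sequence
        rec.species = kw.get("species", "")
        rec.source_annotation = kw.get("source_annotation")
        rec.is_fragment = kw.get("is_fragment")
        return rec


@dataclass
class AlignmentMatrix:
    """A rectangular protein alignment (gap character ``-``)."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        ref_len = len(self.records[0].sequence)
        bad = [r.id for r in self.records if len(r.sequence) != ref_len]
        if bad:
            raise AlignmentError(f"unequal aligned lengths; offending ids: {bad}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate ids in alignment")

    @property
    def columns(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.sequence[j] for r in self.records)


@dataclass
class ReclassRecord:
    """One row of the reclassification table."""

    accession: str
    submitted_name: str
    proposed_name: str
    species: str
    classification: str

    @property
    def fragment_flag(self) -> bool:
        return "(f)" in self.proposed_name

    @property
    def base_name(self) -> str:
        """Proposed name stripped of ``(f)``/``(?)``/``?`` decorations."""
        name = self.proposed_name.replace("(f)", "").replace("(?)", "")
        return name.rstrip("?")


def _validated_record(rid: str, desc: str, seq: str, path, line_of_id) -> ProteinRecord:
    try:
        return ProteinRecord(id=rid, sequence=seq, source_annotation=desc or None)
    except ValueError as exc:
        raise ParseError(f"{path}, entry starting at line {line_of_id}: {exc}") from exc


def read_fasta(path) -> list[ProteinRecord]:
    """Read unaligned protein FASTA.

    Ids are the header token up to the first whitespace; the remainder of the
    header is kept as ``source_annotation``.  Sequences are uppercased and
    ``*`` stop symbols stripped.  Illegal residues or malformed headers raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    # line-number bookkeeping for error messages
    id_lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                rid = s[1:].split()[0] if s[1:].split() else ""
                if not rid:
                    raise ParseError(f"{path}, line {i}: empty FASTA header")
                id_lines.setdefault(rid, i)
            elif not id_lines:
                raise ParseError(f"{path}, line {i}: sequence data before first '>' header")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            _validated_record(rec.id, desc, str(rec.seq), path, id_lines.get(rec.id, "?"))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}"
            if r.source_annotation:
                header += f" {r.source_annotation}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def read_alignment(path) -> AlignmentMatrix:
    """Read an aligned FASTA (gaps as ``-``) into a rectangular matrix."""
    path = Path(path)
    raw = []
    rid, chunks, line_of_id = None, [], 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                if rid is not None:
                    raw.append((rid, "".join(chunks), line_of_id))
                parts = s[1:].split()
                if not parts:
                    raise ParseError(f"{path}, line {i}: empty FASTA header")
                rid, chunks, line_of_id = parts[0], [], i
            else:
                if rid is None:
                    raise ParseError(f"{path}, line {i}: sequence data before first '>' header")
                chunks.append(s)
    if rid is not None:
        raw.append((rid, "".join(chunks), line_of_id))
    records = []
    for rid, seq, ln in raw:
        try:
            records.append(ProteinRecord.aligned(rid, seq))
        except ValueError as exc:
            raise ParseError(f"{path}, entry at line {ln}: {exc}") from exc
    return AlignmentMatrix(records=records)


def write_alignment(alignment: AlignmentMatrix, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in alignment.records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


FIXTURE_COLUMNS = ["Accession", "Submitted name", "Proposed name", "Species", "Classification"]


def load_reclassification_fixture(path=None) -> list[ReclassRecord]:
    """Load the bundled (or a user-supplied) reclassification table.

    The bundled table lists the 56 lophotrochozoan Pax sequences whose
    database annotations were corrected.  Format: TSV with header
    ``Accession / Submitted name / Proposed name / Species / Classification``.
    """
    if path is None:
        src = resources.files("lophopax.data").joinpath("table1_reclassified.tsv")
        text = src.read_text(encoding="utf-8")
        origin = "bundled table1_reclassified.tsv"
    else:
        text = Path(path).read_text(encoding="utf-8")
        origin = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != FIXTURE_COLUMNS:
        raise ParseError(f"{origin}: unexpected header {header}")
    out = []
    for i, ln in enumerate(lines[1:], 2):
        fields = ln.split("\t")
        if len(fields) != 5:
            raise ParseError(f"{origin}, line {i}: expected 5 tab-separated columns, got {len(fields)}")
        acc, sub, prop, sp, cls = fields
        out.append(ReclassRecord(acc, sub, canonical_name(prop), sp, cls))
    return out
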