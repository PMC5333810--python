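"""Synthetic Pax-like protein benchmark generator.

Every pipeline stage in this package is testable offline against datasets
with *planted* domain architectures: a 128-aa paired domain (PRD) made of the
PAI (columns 0-64) and RED (columns 64-128) subdomains, an optional
octapeptide (OM) and homeodomain (HD) downstream at variable linker
distances, family-specific diagnostic motifs, i.i.d. point-mutation noise,
and random truncation to fragments.

The per-family reference PRD consensi are generated once from a fixed seed as
diverged copies of a common ancestor (about 15% pairwise divergence between
families, the divergent eyg copy at 30%) and deterministically curated so
that the PoxNeuro-diagnostic tribasic signal occurs in no other family's
first helix.  They stand in for real curated reference PRDs; real sequences
can be dropped in wherever an :class:`~lophopax.seqio.AlignmentMatrix` is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import AMINO_ACIDS, AlignmentMatrix, ProteinRecord
from .motifs import BASIC_RESIDUES

__all__ = [
    "FAMILIES", "EYG", "FAMILY_TAGS", "SyntheticConfig", "SyntheticTruth",
    "BlueprintElement", "family_template", "generate_dataset",
    "reference_prd_alignment", "reference_hd_alignment", "prd_alignment",
    "write_truth_tsv",
]

#: the six lophotrochozoan Pax families
FAMILIES = ("Pax1/9", "Pax2/5/8", "Pax3/7", "Pax4/6", "Paxβ", "PoxNeuro")
EYG = "eyg"

FAMILY_TAGS = {
    "Pax1/9": "pax19", "Pax2/5/8": "pax258", "Pax3/7": "pax37",
    "Pax4/6": "pax46", "Paxβ": "paxb", "PoxNeuro": "poxn", EYG: "eyg",
}

PRD_LENGTH = 128      # paired domain model length
PAI_LENGTH = 64       # N-terminal half (PAI subdomain)
HD_LENGTH = 60        # paired-type homeodomain model length

#: fixed seed for the bundled reference consensi (independent of dataset seeds)
_REFERENCE_SEED = 20170302

# planted motif instances (each a member of the corresponding consensus class)
OM_PAX19 = "HTVTDILG"
OM_PAX258 = "YSIADILG"
POXN_JUNCTION = "KPKQVAT"
POXN_POSTPRD = "VPGLSYPKIV"
MDKL = "MDKL"
BETA_MOTIF1 = "YDYNLPDRGL"
BETA_MOTIF2 = "PLDLS"
BETA_MOTIF3 = "YERNLLLFGDSEIEIMSVGKAKWIVRNEADL"  # expansion of the 31-column motif
PAX258_SIGNAL = "KRKRDE"     # quadribasic/diacid
BETA_SIGNAL = "KRKHEDED"     # quadribasic/quadriacid
POXN_TRIBASIC = "KRKR"       # planted in the first PRD helix

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA[rng.integers(0, 20, size=length)]).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: Optional[set[int]] = None) -> str:
    if rate <= 0:
        return seq
    arr = bytearray(seq.encode())
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        if protected and int(i) in protected:
            continue
        old = arr[i]
        choices = [a for a in _AA if a != old]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.decode()


def _diverge(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Substitute exactly round(fraction*len) distinct positions."""
    n = int(round(fraction * len(seq)))
    arr = bytearray(seq.encode())
    pos = rng.choice(len(arr), size=n, replace=False)
    for i in pos:
        old = arr[i]
        choices = [a for a in _AA if a != old]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.decode()


def _scrub_basic_runs(seq: str, upto: int = 20) -> str:
    """Remove chance tribasic runs from the first ``upto`` columns.

    Keeps the PoxNeuro helix-1 signal diagnostic: no other family's reference
    consensus may contain a length-4 window with >=3 K/R there.
    """
    arr = list(seq)
    for s in range(0, upto - 3):
        window = arr[s:s + 4]
        while sum(r in BASIC_RESIDUES for r in window) >= 3:
            # deterministically demote the first basic residue
            for k, r in enumerate(window):
                if r in BASIC_RESIDUES:
                    arr[s + k] = "A"
                    break
            window = arr[s:s + 4]
    return "".join(arr)


def _consensi() -> dict[str, str]:
    """Per-family reference PRD consensi (and the divergent eyg copy)."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    ancestor = _random_protein(rng, PRD_LENGTH)
    out = {}
    for fam in FAMILIES:
        prd = _diverge(rng, ancestor, 0.15)
        if fam == "PoxNeuro":
            prd = prd[:2] + POXN_TRIBASIC + prd[2 + len(POXN_TRIBASIC):]
        else:
            prd = _scrub_basic_runs(prd)
        out[fam] = prd
    eyg = _scrub_basic_runs(_diverge(rng, ancestor, 0.30))
    out[EYG] = eyg
    return out


def _hd_consensi() -> dict[str, str]:
    rng = np.random.default_rng(_REFERENCE_SEED + 1)
    ancestor = _random_protein(rng, HD_LENGTH)
    return {
        "Pax3/7": _diverge(rng, ancestor, 0.10),
        "Pax4/6": _diverge(rng, ancestor, 0.10),
    }


_PRD_CONSENSI = _consensi()
_HD_CONSENSI = _hd_consensi()


def reference_prd_alignment() -> AlignmentMatrix:
    """Reference PRD alignment (one consensus row per family, plus eyg)."""
    recs = [ProteinRecord(id=f"ref_{FAMILY_TAGS[f]}", sequence=_PRD_CONSENSI[f], species="reference")
            for f in (*FAMILIES, EYG)]
    return AlignmentMatrix(records=recs)


def reference_hd_alignment() -> AlignmentMatrix:
    recs = [ProteinRecord(id=f"refhd_{FAMILY_TAGS[f]}", sequence=s, species="reference")
            for f, s in _HD_CONSENSI.items()]
    return AlignmentMatrix(records=recs)


@dataclass(frozen=True)
class BlueprintElement:
    """One ordered element of a family architecture blueprint.

    kind ∈ {N_EXT, PRD, LINKER, OM, SIGNAL, MDKL, HD, POXN_POSTPRD,
    BETA_REGION, C_EXT}; payload is a motif string, a (lo, hi) length range
    for random segments, or a family label for PRD/HD elements.
    """

    kind: str
    payload: object = None
    optional: bool = False


def family_template(family: str) -> list[BlueprintElement]:
    """Ordered architecture blueprint for one family.

    Mirrors the published domain compositions: no octapeptide in PoxNeuro and
    Pax4/6, no homeodomain in lophotrochozoan Pax2/5/8 and Pax1/9, a long
    variable Paxβ region carrying three conserved motifs, the MDKL linker
    between PRD and HD in Pax4/6, and the PoxNeuro exon2/exon3 junction
    insertion between PAI and RED.
    """
    B = BlueprintElement
    if family == "Pax1/9":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (10, 30)),
                B("OM", OM_PAX19), B("C_EXT", (20, 60))]
    if family == "Pax2/5/8":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (10, 30)),
                B("OM", OM_PAX258), B("LINKER", (2, 8)), B("SIGNAL", PAX258_SIGNAL),
                B("C_EXT", (20, 60))]
    if family == "Pax3/7":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (10, 30)),
                B("OM", OM_PAX19, optional=True), B("LINKER", (10, 30)),
                B("HD", family), B("C_EXT", (20, 60))]
    if family == "Pax4/6":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (5, 20)),
                B("MDKL", MDKL), B("LINKER", (5, 20)), B("HD", family),
                B("C_EXT", (20, 60))]
    if family == "Paxβ":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (2, 6)),
                B("SIGNAL", BETA_SIGNAL), B("BETA_REGION", (150, 260)),
                B("C_EXT", (10, 40))]
    if family == "PoxNeuro":
        return [B("N_EXT", (10, 40)), B("PRD", family), B("LINKER", (5, 15)),
                B("POXN_POSTPRD", POXN_POSTPRD), B("C_EXT", (20, 60))]
    if family == EYG:
        return [B("N_EXT", (10, 40)), B("PRD", EYG), B("LINKER", (20, 60)),
                B("PRD", EYG), B("C_EXT", (20, 60))]
    raise ValueError(f"unknown family {family!r}")


@dataclass
class SyntheticConfig:
    families: tuple[str, ...] = FAMILIES
    n_per_family: int = 5
    mutation_rate: float = 0.0
    fragment_prob: float = 0.0
    linker_length_range: tuple[int, int] = (10, 30)  # default LINKER range override
    seed: int = 0
    motif_end_guard: int = 2   # residues protected from mutation at motif ends

    def __post_init__(self):
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 <= self.fragment_prob <= 1:
            raise ValueError("fragment_prob must be in [0, 1]")
        for f in self.families:
            if f not in FAMILIES and f != EYG:
                raise ValueError(f"unknown family {f!r}")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Flat ``key=value`` config file."""
        kw: dict = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            key, _, val = ln.partition("=")
            key, val = key.strip(), val.strip()
            if key == "families":
                kw[key] = tuple(v.strip() for v in val.split(","))
            elif key in ("n_per_family", "seed", "motif_end_guard"):
                kw[key] = int(val)
            elif key in ("mutation_rate", "fragment_prob"):
                kw[key] = float(val)
            elif key == "linker_length_range":
                lo, hi = val.split(",")
                kw[key] = (int(lo), int(hi))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kw)


@dataclass
class SyntheticTruth:
    """Planted architecture of one synthetic record (0-based, half-open)."""

    record_id: str
    family: str
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    is_fragment: bool = False


_MOTIF_KINDS = {"OM", "SIGNAL", "MDKL", "POXN_POSTPRD", "JUNCTION",
                "BETA_MOTIF1", "BETA_MOTIF2", "BETA_MOTIF3"}


def _build_record(family: str, rng: np.random.Generator,
                  config: SyntheticConfig) -> tuple[str, dict[str, tuple[int, int]]]:
    parts: list[str] = []
    coords: dict[str, tuple[int, int]] = {}
    pos = 0
    n_prd = 0

    def emit(kind: str, segment: str):
        nonlocal pos
        if kind:
            key = kind if kind not in coords else f"{kind}2"
            coords[key] = (pos, pos + len(segment))
        parts.append(segment)
        pos += len(segment)

    for el in family_template(family):
        if el.optional and rng.random() < 0.5:
            continue
        if el.kind in ("N_EXT", "C_EXT"):
            lo, hi = el.payload
            emit("", _random_protein(rng, int(rng.integers(lo, hi + 1))))
        elif el.kind == "LINKER":
            lo, hi = el.payload
            emit("", _random_protein(rng, int(rng.integers(lo, hi + 1))))
        elif el.kind == "PRD":
            prd = _PRD_CONSENSI[el.payload]
            n_prd += 1
            suffix = "" if n_prd == 1 else "2"
            if family == "PoxNeuro":
                # exon2/exon3 junction insertion between PAI and RED
                coords["PRD" + suffix] = (pos, pos + PRD_LENGTH + len(POXN_JUNCTION))
                coords["PAI" + suffix] = (pos, pos + PAI_LENGTH)
                parts.append(prd[:PAI_LENGTH])
                pos += PAI_LENGTH
                coords["JUNCTION"] = (pos, pos + len(POXN_JUNCTION))
                parts.append(POXN_JUNCTION)
                pos += len(POXN_JUNCTION)
                coords["RED" + suffix] = (pos, pos + PRD_LENGTH - PAI_LENGTH)
                parts.append(prd[PAI_LENGTH:])
                pos += PRD_LENGTH - PAI_LENGTH
            else:
                coords["PRD" + suffix] = (pos, pos + PRD_LENGTH)
                coords["PAI" + suffix] = (pos, pos + PAI_LENGTH)
                coords["RED" + suffix] = (pos + PAI_LENGTH, pos + PRD_LENGTH)
                emit("", prd)
        elif el.kind == "HD":
            emit("HD", _HD_CONSENSI[el.payload])
        elif el.kind == "BETA_REGION":
            lo, hi = el.payload
            total = int(rng.integers(lo, hi + 1))
            motifs = [("BETA_MOTIF1", BETA_MOTIF1), ("BETA_MOTIF2", BETA_MOTIF2),
                      ("BETA_MOTIF3", BETA_MOTIF3)]
            spacer_budget = total - sum(len(m) for _, m in motifs)
            cuts = sorted(rng.integers(0, spacer_budget + 1, size=3))
            spacers = [cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1],
                       spacer_budget - cuts[2]]
            emit("", _random_protein(rng, spacers[0]))
            for (name, m), sp in zip(motifs, spacers[1:]):
                emit(name, m)
                emit("", _random_protein(rng, sp))
        else:  # OM, SIGNAL, MDKL, POXN_POSTPRD: literal planted motif
            emit(el.kind, el.payload)
    return "".join(parts), coords


def _guard_positions(coords: dict[str, tuple[int, int]], guard: int) -> set[int]:
    protected: set[int] = set()
    for kind, (s, e) in coords.items():
        base = kind.rstrip("2")
        if base in _MOTIF_KINDS:
            protected.update(range(s, min(s + guard, e)))
            protected.update(range(max(e - guard, s), e))
    return protected


def generate_dataset(config: SyntheticConfig) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Generate a labeled dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    records, truths = [], []
    for family in config.families:
        tag = FAMILY_TAGS[family]
        for i in range(config.n_per_family):
            seq, coords = _build_record(family, rng, config)
            protected = _guard_positions(coords, config.motif_end_guard)
            seq = _mutate(rng, seq, config.mutation_rate, protected)
            is_fragment = bool(rng.random() < config.fragment_prob)
            if is_fragment:
                ps, pe = coords["PRD"]
                cut = int(rng.integers(ps + 1, pe))
                seq = seq[:cut]
                coords = {k: (s, min(e, cut)) for k, (s, e) in coords.items() if s < cut}
            rid = f"{tag}_{i:03d}"
            records.append(ProteinRecord(id=rid, sequence=seq, species="synthetic",
                                         is_fragment=is_fragment))
            truths.append(SyntheticTruth(rid, family, coords, is_fragment))
    return records, truths


def prd_alignment(records: list[ProteinRecord], truths: list[SyntheticTruth]) -> AlignmentMatrix:
    """Gap-free 128-column alignment of planted PAI+RED regions.

    Uses the planted coordinates (fragments lacking a complete PRD are
    skipped), emulating the PRD-restricted alignments used for tree building.
    """
    by_id = {t.record_id: t for t in truths}
    rows = []
    for rec in records:
        t = by_id[rec.id]
        if "PAI" not in t.domains or "RED" not in t.domains:
            continue
        (ps, pe), (rs, re_) = t.domains["PAI"], t.domains["RED"]
        if pe - ps != PAI_LENGTH or re_ - rs != PRD_LENGTH - PAI_LENGTH:
            continue  # truncated inside the PRD
        rows.append(ProteinRecord(id=rec.id, sequence=rec.sequence[ps:pe] + rec.sequence[rs:re_],
                                  species=rec.species))
    return AlignmentMatrix(records=rows)


def write_truth_tsv(truths: list[SyntheticTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tfamily\tdomain\tstart\tend\tis_fragment\n")
        for t in truths:
            for kind, (s, e) in sorted(t.domains.items(), key=lambda kv: kv[1]):
                fh.write(f"{t.record_id}\t{t.family}\t{kind}\t{s}\t{e}\t{t.is_fragment}\n")
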