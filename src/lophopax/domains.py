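"""Paired-domain / homeodomain detection and PRD-based identities.

The 128-aa paired domain (PRD) is located by ungapped position-profile
scanning.  Because the PoxNeuro subfamily carries an insertion (the
exon2/exon3 junction, KPKQVAT in *Drosophila*) between the two halves of the
PRD, the PRD is detected as a composite of its PAI (columns 0-64) and RED
(columns 64-128) sub-profiles, allowing a short junction insert between them.
The ~60-aa paired-type homeodomain (HD) is detected with its own profile.

Profiles are plain per-column residue frequency tables with a pseudocount;
scores are mean log-odds per aligned column against a uniform background.
No insert/delete states are modelled: the PRD is conserved enough that
ungapped scanning with terminal-truncation handling suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import AMINO_ACIDS, GAP, AlignmentMatrix, ProteinRecord
from .motifs import (MotifHit, MotifPattern, default_max_mismatch,
                     find_basic_signal, load_motif_registry, scan)
from . import synthetic

__all__ = [
    "PositionProfile", "DomainHit", "DomainAnnotation", "ProfileError",
    "build_profile", "detect_domain", "detect_paired_domain",
    "percent_identity", "annotate", "default_profiles",
]

_RES_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BACKGROUND = 1.0 / 20.0


class ProfileError(ValueError):
    pass


@dataclass
class PositionProfile:
    """Per-column residue frequencies (rows sum to 1 after pseudocount)."""

    freqs: np.ndarray            # (length, 20)
    pseudocount: float
    kind: str = ""               # e.g. PRD / PAI / RED / HD
    min_score: Optional[float] = None   # data-driven default acceptance threshold

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        # extra row (index 20) of zeros: 'X' in a sequence scores neutrally
        lo = np.log(self.freqs / _BACKGROUND)
        return np.vstack([lo.T, np.zeros(self.length)]).T

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.freqs.argmax(axis=1))


@dataclass
class DomainHit:
    """A located domain occurrence (0-based half-open sequence coordinates)."""

    kind: str                    # PRD | PAI | RED | OM | HD
    start: int
    end: int
    score: float
    complete: bool
    profile_offset: int = 0      # first profile column covered (for truncated hits)
    label: str = ""              # e.g. octapeptide type

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end


def build_profile(reference: AlignmentMatrix, pseudocount: float = 1.0,
                  kind: str = "") -> PositionProfile:
    """Normalized frequency profile from a reference alignment.

    Gaps and 'X' do not contribute to counts; a column consisting only of
    gaps is an error.  Frequency of residue a in a column with n observed
    residues is (count_a + pseudocount) / (n + 20 * pseudocount).
    """
    if pseudocount <= 0:
        raise ProfileError("pseudocount must be positive")
    L = reference.columns
    counts = np.zeros((L, 20))
    for rec in reference.records:
        for j, c in enumerate(rec.sequence):
            if c in _RES_INDEX:
                counts[j, _RES_INDEX[c]] += 1
    observed = counts.sum(axis=1)
    if (observed == 0).any():
        bad = np.nonzero(observed == 0)[0]
        raise ProfileError(f"gap-only column(s) at {bad.tolist()}")
    freqs = (counts + pseudocount) / (observed + 20 * pseudocount)[:, None]
    profile = PositionProfile(freqs=freqs, pseudocount=pseudocount, kind=kind)
    profile.min_score = _default_min_score(profile, reference)
    return profile


def _self_scores(profile: PositionProfile, reference: AlignmentMatrix) -> np.ndarray:
    lo = profile.log_odds
    scores = []
    for rec in reference.records:
        idx = np.array([_RES_INDEX.get(c, 20) for c in rec.sequence])
        keep = np.array([c != GAP for c in rec.sequence])
        scores.append(lo[np.arange(profile.length)[keep], idx[keep]].mean())
    return np.array(scores)


def _default_min_score(profile: PositionProfile, reference: AlignmentMatrix) -> float:
    """Mean reference self-score minus three standard deviations."""
    s = _self_scores(profile, reference)
    return float(s.mean() - 3 * s.std())


def _encode(sequence: str) -> np.ndarray:
    return np.array([_RES_INDEX.get(c, 20) for c in sequence], dtype=np.intp)


def detect_domain(record: ProteinRecord, profile: PositionProfile,
                  min_score: Optional[float] = None,
                  min_coverage: float = 0.25) -> list[DomainHit]:
    """Best-scoring ungapped profile windows, greedily non-overlapping.

    Windows running off either sequence end are allowed as incomplete hits as
    long as at least ``min_coverage`` of the profile is covered; scores are
    means over covered columns only, so they are invariant to padding outside
    the hit.
    """
    if min_score is None:
        min_score = profile.min_score if profile.min_score is not None else 0.0
    seq = record.sequence
    n, L = len(seq), profile.length
    minc = max(1, math.ceil(min_coverage * L))
    if n < minc:
        return []
    lo = profile.log_odds
    idx = _encode(seq)
    candidates: list[DomainHit] = []
    # complete placements, vectorized
    if n >= L:
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = lo[np.arange(L), windows].mean(axis=1)
        for s in np.nonzero(scores >= min_score)[0]:
            candidates.append(DomainHit(profile.kind, int(s), int(s) + L,
                                        float(scores[s]), True, 0))
    # truncated placements off the N-terminus (profile tail aligned to sequence head)
    for cov in range(minc, min(L, n + 1)):
        off = L - cov
        sc = float(lo[np.arange(off, L), idx[:cov]].mean())
        if sc >= min_score:
            candidates.append(DomainHit(profile.kind, 0, cov, sc, False, off))
    # truncated placements off the C-terminus
    for cov in range(minc, min(L, n + 1)):
        start = n - cov
        sc = float(lo[np.arange(cov), idx[start:]].mean())
        if sc >= min_score:
            candidates.append(DomainHit(profile.kind, start, n, sc, False, 0))
    candidates.sort(key=lambda h: (-h.score, h.start))
    accepted: list[DomainHit] = []
    for h in candidates:
        if not any(h.overlaps(a) for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: h.start)
    return accepted


def _best_window(profile: PositionProfile, idx: np.ndarray,
                 starts: list[int]) -> Optional[DomainHit]:
    """Best complete placement of ``profile`` among candidate start offsets."""
    L = profile.length
    lo = profile.log_odds
    best = None
    for s in starts:
        if s < 0 or s + L > len(idx):
            continue
        sc = float(lo[np.arange(L), idx[s:s + L]].mean())
        if best is None or sc > best.score:
            best = DomainHit(profile.kind, s, s + L, sc, True)
    return best


def detect_paired_domain(record: ProteinRecord, pai: PositionProfile,
                         red: PositionProfile,
                         max_junction: int = 20) -> list[DomainHit]:
    """Composite PRD hits from independent PAI and RED sub-profile scans.

    A PAI hit followed by a RED hit within ``max_junction`` residues (room
    for the PoxNeuro exon-junction insertion) forms a complete PRD.  When
    only one half clears its own de novo threshold, it anchors a local
    search for the sister half at the expected offset; the pair is accepted
    if the composite (mean of both halves) score clears the composite
    threshold.  A lone half with no acceptable sister forms an incomplete
    PRD.  Hits are returned best-score-first.
    """
    pai_hits = detect_domain(record, pai)
    red_hits = detect_domain(record, red)
    idx = _encode(record.sequence)
    composite_min = ((pai.min_score or 0.0) + (red.min_score or 0.0)) / 2
    prd_hits: list[DomainHit] = []
    used_pai, used_red = set(), set()
    for i, ph in enumerate(pai_hits):
        for j, rh in enumerate(red_hits):
            if j in used_red:
                continue
            gap = rh.start - ph.end
            if 0 <= gap <= max_junction:
                prd_hits.append(DomainHit("PRD", ph.start, rh.end,
                                          (ph.score + rh.score) / 2,
                                          ph.complete and rh.complete))
                used_pai.add(i)
                used_red.add(j)
                break
    for i, ph in enumerate(pai_hits):
        if i in used_pai:
            continue
        rescue = None
        if ph.complete:
            rescue = _best_window(red, idx, list(range(ph.end, ph.end + max_junction + 1)))
        if rescue and (ph.score + rescue.score) / 2 >= composite_min:
            prd_hits.append(DomainHit("PRD", ph.start, rescue.end,
                                      (ph.score + rescue.score) / 2, True))
        else:
            prd_hits.append(DomainHit("PRD", ph.start, ph.end, ph.score, False,
                                      label="PAI-only"))
    for j, rh in enumerate(red_hits):
        if j in used_red:
            continue
        rescue = None
        if rh.complete:
            rescue = _best_window(pai, idx, [rh.start - pai.length - g
                                             for g in range(max_junction + 1)])
        if rescue and (rh.score + rescue.score) / 2 >= composite_min:
            prd_hits.append(DomainHit("PRD", rescue.start, rh.end,
                                      (rh.score + rescue.score) / 2, True))
        else:
            prd_hits.append(DomainHit("PRD", rh.start, rh.end, rh.score, False,
                                      label="RED-only"))
    # de-duplicate identical spans that can arise from double rescue
    seen = set()
    unique = []
    for h in prd_hits:
        if (h.start, h.end) not in seen:
            seen.add((h.start, h.end))
            unique.append(h)
    unique.sort(key=lambda h: (-h.score, h.start))
    return unique


_BLOSUM_ALIGNER = None


def _aligner():
    global _BLOSUM_ALIGNER
    if _BLOSUM_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10
        a.extend_gap_score = -0.5
        a.mode = "global"
        _BLOSUM_ALIGNER = a
    return _BLOSUM_ALIGNER


def percent_identity(a: str, b: str) -> int:
    """Percent identity between two sequences, rounded half-up.

    Equal-length inputs are treated as already aligned (gaps allowed);
    unequal-length inputs are globally aligned first (BLOSUM62, gap open -10,
    extend -0.5).  Denominator: aligned columns excluding double-gap columns;
    single-gap columns count as mismatches.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) != len(b):
        aln = _aligner().align(a.replace(GAP, ""), b.replace(GAP, ""))[0]
        a, b = str(aln[0]), str(aln[1])
    matches = cols = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y and x != GAP and x != "X":
            matches += 1
    if cols == 0:
        raise ValueError("no aligned columns")
    return math.floor(100.0 * matches / cols + 0.5)


@dataclass
class DomainAnnotation:
    """Domain and motif evidence collected for one record."""

    record_id: str
    hits: list[DomainHit] = field(default_factory=list)
    prd_subsequence: Optional[str] = None
    fragment: bool = False
    motif_hits: dict[str, list[MotifHit]] = field(default_factory=dict)
    signals: dict[str, Optional[MotifHit]] = field(default_factory=dict)
    n_prd: int = 1

    def best(self, kind: str) -> Optional[DomainHit]:
        hits = [h for h in self.hits if h.kind == kind]
        return max(hits, key=lambda h: h.score) if hits else None


def default_profiles(pseudocount: float = 1.0) -> dict[str, PositionProfile]:
    """PRD/PAI/RED/HD profiles built from the bundled reference set."""
    prd_ref = synthetic.reference_prd_alignment()
    hd_ref = synthetic.reference_hd_alignment()
    pai_ref = AlignmentMatrix(records=[
        ProteinRecord(id=r.id, sequence=r.sequence[:synthetic.PAI_LENGTH])
        for r in prd_ref.records])
    red_ref = AlignmentMatrix(records=[
        ProteinRecord(id=r.id, sequence=r.sequence[synthetic.PAI_LENGTH:])
        for r in prd_ref.records])
    return {
        "PRD": build_profile(prd_ref, pseudocount, kind="PRD"),
        "PAI": build_profile(pai_ref, pseudocount, kind="PAI"),
        "RED": build_profile(red_ref, pseudocount, kind="RED"),
        "HD": build_profile(hd_ref, pseudocount, kind="HD"),
    }


def annotate(record: ProteinRecord, profiles: dict[str, PositionProfile],
             patterns: Optional[dict] = None,
             max_junction: int = 20) -> DomainAnnotation:
    """Locate PRD, octapeptide, HD and diagnostic motifs in one record.

    Search order follows the canonical domain layout: the PRD is chosen
    first (best composite hit); the octapeptide is searched only downstream
    of the PRD; the HD downstream of the octapeptide (or PRD).  ``fragment``
    is set when the PRD is incomplete or the sequence ends inside the HD.
    """
    if patterns is None:
        patterns = load_motif_registry()
    seq = record.sequence
    ann = DomainAnnotation(record_id=record.id)

    prd_hits = detect_paired_domain(record, profiles["PAI"], profiles["RED"],
                                    max_junction)
    # keep the best plus any further non-overlapping hits (duplicated-PRD flag)
    kept: list[DomainHit] = []
    for h in prd_hits:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    ann.n_prd = len(kept)
    prd = kept[0] if kept else None
    ann.hits.extend(kept)
    if prd is None:
        ann.fragment = True
        # Paxβ-like sequences carry the motifs without any PRD: still scan them
        for name in ("beta_motif1", "beta_motif2", "beta_motif3"):
            pat = patterns[name]["pattern"]
            ann.motif_hits[name] = scan(seq, pat, default_max_mismatch(pat))
        return ann
    ann.prd_subsequence = seq[prd.start:prd.end]
    downstream = prd.end

    # octapeptide: searched only downstream of the PRD end
    for name, om_label in (("oct_pax19", "H-type"), ("oct_pax258", "Y-type")):
        pat = patterns[name]["pattern"]
        hits = [h for h in scan(seq, pat, default_max_mismatch(pat)) if h.start >= downstream]
        ann.motif_hits[name] = hits
        if hits:
            best = min(hits, key=lambda h: (h.mismatches, h.start))
            ann.hits.append(DomainHit("OM", best.start, best.end, -best.mismatches,
                                      True, label=om_label))
    om = ann.best("OM")

    # homeodomain: downstream of octapeptide / PRD
    hd_floor = om.end if om else downstream
    hd_hits = [h for h in detect_domain(record, profiles["HD"]) if h.start >= hd_floor - 2]
    if hd_hits:
        best_hd = max(hd_hits, key=lambda h: h.score)
        ann.hits.append(best_hd)

    # remaining diagnostic motifs, searched downstream of the PRD
    for name in ("mdkl_linker", "poxn_postprd", "beta_motif1", "beta_motif2",
                 "beta_motif3"):
        pat = patterns[name]["pattern"]
        ann.motif_hits[name] = [h for h in scan(seq, pat, default_max_mismatch(pat))
                                if h.start >= downstream]
    # exon-junction insertion motif, searched around the PAI/RED boundary
    pai_hit = prd  # composite span; junction zone is the middle ± 10
    mid_lo = max(0, prd.start + synthetic.PAI_LENGTH - 10)
    mid_hi = min(len(seq), prd.end - (synthetic.PRD_LENGTH - synthetic.PAI_LENGTH) + 10)
    jpat = patterns["poxn_junction"]["pattern"]
    ann.motif_hits["poxn_junction"] = [
        h for h in scan(seq, jpat, default_max_mismatch(jpat))
        if mid_lo <= h.start <= max(mid_lo, mid_hi)]

    # basic signals
    try:
        ann.signals["tribasic_helix1"] = find_basic_signal(
            seq, prd.start, min(20, len(seq) - prd.start), min_basic=3)
    except IndexError:
        ann.signals["tribasic_helix1"] = None
    sig_start = om.end if om else downstream
    sig_len = min((40 if om else 120), len(seq) - sig_start)
    ann.signals["post_om_basic"] = (
        find_basic_signal(seq, sig_start, sig_len, min_basic=3) if sig_len >= 4 else None)

    hd = ann.best("HD")
    ann.fragment = (not prd.complete) or bool(hd and not hd.complete and hd.end == len(seq))
    return ann
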