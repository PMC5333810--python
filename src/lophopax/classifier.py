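"""Pax subfamily assignment from domain architecture and diagnostic motifs.

The six lophotrochozoan families are separated by domain composition:

* **Pax1/9** — PRD + H-type octapeptide, no HD;
* **Pax2/5/8** — PRD + Y-type octapeptide followed by a quadribasic/diacid
  signal, no HD (unlike the chordate partial HD);
* **Pax3/7** — PRD + HD, octapeptide optional (obvious only in cephalopods);
* **Pax4/6** — the canonical PRD + HD layout with the characteristic MDKL
  linker between them and no octapeptide;
* **Paxβ** — PRD followed by a long variable region carrying up to three
  conserved motifs (two suffice for assignment);
* **PoxNeuro** — PRD with a tribasic helix-1 signal and the exon2/exon3
  junction insertion between PAI and RED, plus a conserved post-PRD motif;
  no octapeptide, no HD.

A sequence whose required evidence matches no family but that still carries
a PRD is reported as indeterminate "Pax"; the Paxβ motifs without any PRD
give "Paxβlike"; a duplicated PRD configuration is only ever flagged "eyg?"
for manual/tree review, never auto-confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .domains import DomainAnnotation

__all__ = ["ArchitectureProfile", "FamilyCall", "rule_set", "classify",
           "batch_report", "LOPHOTROCHOZOAN_FAMILIES"]

LOPHOTROCHOZOAN_FAMILIES = ("Pax1/9", "Pax2/5/8", "Pax3/7", "Pax4/6", "Paxβ",
                            "PoxNeuro")


@dataclass(frozen=True)
class ArchitectureProfile:
    family: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()
    optional: frozenset[str] = frozenset()
    diagnostic_motifs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.required & self.forbidden:
            raise ValueError(f"{self.family}: required/forbidden overlap")


@dataclass
class FamilyCall:
    """Classifier verdict for one record."""

    record_id: str
    family: str                     # label, "Pax", "Paxβlike", "eyg?", or "" if rejected
    fragment: bool
    confidence: str                 # strong | weak | indeterminate
    evidence: list[tuple[str, bool, Optional[int]]] = field(default_factory=list)
    score: int = 0
    status: str = "ok"              # ok | no-PRD

    @property
    def proposed_name(self) -> str:
        name = self.family
        if self.fragment and name and name not in ("Pax",) and not name.endswith("?"):
            name += "(f)"
        elif self.fragment and name.endswith("?"):
            name += "(f)"
        return name


def rule_set() -> list[ArchitectureProfile]:
    """The six lophotrochozoan family profiles plus the eyg flag profile."""
    P = ArchitectureProfile
    return [
        P("Pax1/9", required=frozenset({"PRD", "OM_H"}), forbidden=frozenset({"HD"}),
          diagnostic_motifs=("oct_pax19",)),
        P("Pax2/5/8", required=frozenset({"PRD", "OM_Y", "BASIC_SIGNAL"}),
          forbidden=frozenset({"HD"}), diagnostic_motifs=("oct_pax258",)),
        P("Pax3/7", required=frozenset({"PRD", "HD"}), optional=frozenset({"OM"})),
        P("Pax4/6", required=frozenset({"PRD", "HD", "MDKL"}),
          forbidden=frozenset({"OM"}), diagnostic_motifs=("mdkl_linker",)),
        P("Paxβ", required=frozenset({"PRD", "BETA_MOTIFS_2OF3"}),
          optional=frozenset({"BASIC_SIGNAL"}),
          diagnostic_motifs=("beta_motif1", "beta_motif2", "beta_motif3")),
        P("PoxNeuro",
          required=frozenset({"PRD", "POXN_TRIBASIC", "POXN_JUNCTION", "POXN_POSTPRD"}),
          forbidden=frozenset({"OM", "HD"}),
          diagnostic_motifs=("poxn_junction", "poxn_postprd")),
        # eyg: divergent/duplicated PRD; never auto-confirmed (flag only)
        P("eyg", required=frozenset({"PRD_DUPLICATED"})),
    ]


def _evidence(ann: DomainAnnotation) -> dict[str, Optional[int]]:
    """Map evidence keys to a hit location (None when absent)."""
    ev: dict[str, Optional[int]] = {}
    prd = ann.best("PRD")
    hd = ann.best("HD")
    om = ann.best("OM")
    ev["PRD"] = prd.start if prd else None
    # forbidden-HD semantics: only complete or partial hits above the profile
    # threshold count (detect_domain already applies the threshold)
    ev["HD"] = hd.start if hd else None
    om_h = [h for h in ann.hits if h.kind == "OM" and h.label == "H-type"]
    om_y = [h for h in ann.hits if h.kind == "OM" and h.label == "Y-type"]
    ev["OM_H"] = om_h[0].start if om_h else None
    ev["OM_Y"] = om_y[0].start if om_y else None
    ev["OM"] = om.start if om else None
    mdkl = [h for h in ann.motif_hits.get("mdkl_linker", [])
            if hd is None or h.end <= hd.start]
    ev["MDKL"] = mdkl[0].start if (mdkl and hd is not None) else None
    sig = ann.signals.get("post_om_basic")
    ev["BASIC_SIGNAL"] = sig.start if sig else None
    tri = ann.signals.get("tribasic_helix1")
    ev["POXN_TRIBASIC"] = tri.start if tri else None
    junc = ann.motif_hits.get("poxn_junction", [])
    ev["POXN_JUNCTION"] = junc[0].start if junc else None
    post = ann.motif_hits.get("poxn_postprd", [])
    ev["POXN_POSTPRD"] = post[0].start if post else None
    beta_found = [name for name in ("beta_motif1", "beta_motif2", "beta_motif3")
                  if ann.motif_hits.get(name)]
    ev["BETA_MOTIF_ANY"] = (ann.motif_hits[beta_found[0]][0].start
                            if beta_found else None)
    ev["BETA_MOTIFS_2OF3"] = ev["BETA_MOTIF_ANY"] if len(beta_found) >= 2 else None
    ev["PRD_DUPLICATED"] = prd.start if (prd and ann.n_prd >= 2) else None
    return ev


def classify(annotation: DomainAnnotation,
             rules: Optional[list[ArchitectureProfile]] = None) -> FamilyCall:
    """Assign a family by required/forbidden evidence; deterministic.

    The family whose required evidence is fully satisfied with no forbidden
    evidence present wins.  Candidates whose required set is a strict subset
    of another candidate's are dropped first (specificity), then remaining
    ties are broken by diagnostic score and decorated "?".  With a PRD but no
    winner the call is indeterminate "Pax"; without a PRD the call is
    rejected ("no-PRD"), except that two or more Paxβ motifs give "Paxβlike".
    """
    if rules is None:
        rules = rule_set()
    ev = _evidence(annotation)
    present = {k for k, v in ev.items() if v is not None}
    evidence_list = [(k, v is not None, v) for k, v in sorted(ev.items())]

    if "PRD" not in present:
        beta_n = sum(bool(annotation.motif_hits.get(n))
                     for n in ("beta_motif1", "beta_motif2", "beta_motif3"))
        if beta_n >= 2:
            return FamilyCall(annotation.record_id, "Paxβlike", annotation.fragment,
                              "weak", evidence_list, beta_n)
        return FamilyCall(annotation.record_id, "", annotation.fragment,
                          "indeterminate", evidence_list, 0, status="no-PRD")

    candidates = []
    for prof in rules:
        if prof.family == "eyg":
            continue  # flag-only, below
        if prof.required <= present and not (prof.forbidden & present):
            score = len((prof.required | prof.optional) & present)
            candidates.append((prof, score))

    # specificity: drop candidates strictly subsumed by another candidate
    keep = []
    for prof, score in candidates:
        if any(prof.required < other.required for other, _ in candidates):
            continue
        keep.append((prof, score))
    candidates = keep

    if not candidates:
        if "PRD_DUPLICATED" in present:
            return FamilyCall(annotation.record_id, "eyg?", annotation.fragment,
                              "indeterminate", evidence_list, 0)
        return FamilyCall(annotation.record_id, "Pax", annotation.fragment,
                          "indeterminate", evidence_list, 0)

    candidates.sort(key=lambda cs: (-cs[1], cs[0].family))
    prof, score = candidates[0]
    family = prof.family
    if len(candidates) > 1 and candidates[1][1] == score:
        family += "?"
        confidence = "weak"
    elif len(candidates) > 1:
        family += "?"
        confidence = "weak"
    else:
        confidence = "weak" if annotation.fragment else "strong"
    return FamilyCall(annotation.record_id, family, annotation.fragment,
                      confidence, evidence_list, score)


REPORT_COLUMNS = ["Accession", "Submitted name", "Proposed name", "Species",
                  "Classification"]


def batch_report(calls: list[FamilyCall], submitted: Optional[dict[str, str]] = None,
                 species: Optional[dict[str, str]] = None,
                 classification: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Reclassification table in the published column order.

    ``(f)`` is appended to fragment calls; metadata columns default to empty
    strings when no lookup is supplied.
    """
    rows = []
    for c in calls:
        rows.append({
            "Accession": c.record_id,
            "Submitted name": (submitted or {}).get(c.record_id, ""),
            "Proposed name": c.proposed_name if c.status == "ok" else "no-PRD",
            "Species": (species or {}).get(c.record_id, ""),
            "Classification": (classification or {}).get(c.record_id, ""),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
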