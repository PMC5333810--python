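"""Alignment curation by conserved-block selection.

Reimplements the published curation settings for removing ambiguously
aligned regions before tree building: minimum block length after gap
cleaning 10, no gap positions in the final alignment, maximal runs of more
than 8 contiguous non-conserved positions rejected, and flank positions
requiring 85% of sequences to agree.

Column classes are identity-based (no amino-acid similarity groups): a
column is *gap* if any sequence has ``-`` there, *highly conserved* if the
modal residue frequency reaches ``flank_fraction``, *conserved* if it
exceeds ``conserved_fraction`` (default 0.5, i.e. more than half the
sequences agree), and *non-conserved* otherwise.

Selection applies, in a fixed documented order: (i) drop gap columns and
non-conserved runs adjacent to them; (ii) reject maximal runs of more than
``max_contig_nonconserved`` consecutive non-conserved columns; (iii) trim
each remaining candidate block to start and end on highly conserved (flank)
columns; (iv) discard blocks shorter than ``min_block_len``.  The result is
idempotent: filtering a filtered alignment changes nothing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .seqio import GAP, AlignmentMatrix, ProteinRecord

__all__ = ["BlockFilterParams", "BlockMask", "classify_columns",
           "select_blocks", "apply_mask", "curate"]

#: column class labels
GAP_COL, NONCONSERVED, CONSERVED, HIGHLY_CONSERVED = "gap", "nonconserved", "conserved", "highly_conserved"


@dataclass(frozen=True)
class BlockFilterParams:
    min_block_len: int = 10
    allow_gaps: bool = False
    max_contig_nonconserved: int = 8
    flank_fraction: float = 0.85
    conserved_fraction: float = 0.5

    def __post_init__(self):
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")
        if not 0 < self.flank_fraction <= 1:
            raise ValueError("flank_fraction must be in (0, 1]")
        if self.max_contig_nonconserved < 0:
            raise ValueError("max_contig_nonconserved must be >= 0")


@dataclass(frozen=True)
class BlockMask:
    kept: tuple[int, ...]                 # ordered 0-based column indices
    blocks: tuple[tuple[int, int], ...]   # [start, end) runs over original columns

    def __post_init__(self):
        flat = [i for s, e in self.blocks for i in range(s, e)]
        if list(self.kept) != flat:
            raise ValueError("blocks do not concatenate to kept")


def classify_columns(alignment: AlignmentMatrix,
                     params: BlockFilterParams = BlockFilterParams()) -> list[str]:
    """Per-column conservation class (see module docstring)."""
    n = len(alignment)
    classes = []
    for j in range(alignment.columns):
        col = alignment.column(j)
        if not params.allow_gaps and GAP in col:
            classes.append(GAP_COL)
            continue
        residues = [c for c in col if c != GAP]
        if not residues:
            classes.append(GAP_COL)
            continue
        modal = Counter(residues).most_common(1)[0][1] / n
        if modal >= params.flank_fraction:
            classes.append(HIGHLY_CONSERVED)
        elif modal > params.conserved_fraction:
            classes.append(CONSERVED)
        else:
            classes.append(NONCONSERVED)
    return classes


def select_blocks(classes: list[str],
                  params: BlockFilterParams = BlockFilterParams()) -> BlockMask:
    """Apply selection rules (i)-(iv); deterministic."""
    n = len(classes)
    removed = [cls == GAP_COL for cls in classes]

    # (i) non-conserved runs adjacent to a gap column go too
    for j in range(n):
        if classes[j] == GAP_COL:
            k = j - 1
            while k >= 0 and classes[k] == NONCONSERVED:
                removed[k] = True
                k -= 1
            k = j + 1
            while k < n and classes[k] == NONCONSERVED:
                removed[k] = True
                k += 1

    # (ii) maximal runs of > max_contig_nonconserved consecutive non-conserved
    j = 0
    while j < n:
        if classes[j] == NONCONSERVED and not removed[j]:
            k = j
            while k < n and classes[k] == NONCONSERVED and not removed[k]:
                k += 1
            if k - j > params.max_contig_nonconserved:
                for m in range(j, k):
                    removed[m] = True
            j = k
        else:
            j += 1

    # candidate blocks = maximal runs of surviving columns
    blocks = []
    j = 0
    while j < n:
        if not removed[j]:
            k = j
            while k < n and not removed[k]:
                k += 1
            blocks.append((j, k))
            j = k
        else:
            j += 1

    # (iii) trim to highly conserved flanks, (iv) length floor
    final = []
    for s, e in blocks:
        while s < e and classes[s] != HIGHLY_CONSERVED:
            s += 1
        while e > s and classes[e - 1] != HIGHLY_CONSERVED:
            e -= 1
        if e - s >= params.min_block_len:
            final.append((s, e))

    kept = tuple(i for s, e in final for i in range(s, e))
    return BlockMask(kept=kept, blocks=tuple(final))


def apply_mask(alignment: AlignmentMatrix, mask: BlockMask) -> AlignmentMatrix:
    """Column-subset alignment, order preserved."""
    if not mask.kept:
        raise ValueError("empty curated alignment")
    if mask.kept[-1] >= alignment.columns:
        raise IndexError(
            f"mask index {mask.kept[-1]} out of range for {alignment.columns} columns")
    records = [ProteinRecord.aligned(r.id, "".join(r.sequence[j] for j in mask.kept),
                                     species=r.species)
               for r in alignment.records]
    return AlignmentMatrix(records=records)


def curate(alignment: AlignmentMatrix,
           params: BlockFilterParams = BlockFilterParams()) -> tuple[AlignmentMatrix, BlockMask]:
    """classify → select → apply, in one call."""
    mask = select_blocks(classify_columns(alignment, params), params)
    return apply_mask(alignment, mask), mask


def block_report(mask: BlockMask) -> str:
    """Human-readable per-block report (1-based inclusive display)."""
    lines = [f"kept {len(mask.kept)} columns in {len(mask.blocks)} block(s)"]
    for s, e in mask.blocks:
        lines.append(f"  block [{s + 1}..{e}]  length {e - s}")
    return "\n".join(lines)
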