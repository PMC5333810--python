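"""Conserved-block curation vs an independent rule-by-rule oracle."""

import numpy as np
import pytest

from lophopax.blocks import (BlockFilterParams, BlockMask, apply_mask,
                             classify_columns, curate, select_blocks,
                             GAP_COL, NONCONSERVED, CONSERVED, HIGHLY_CONSERVED)
from lophopax.seqio import AlignmentMatrix, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(*rows):
    return AlignmentMatrix(records=[ProteinRecord.aligned(f"s{i}", r)
                                    for i, r in enumerate(rows)])


# ---------------------------------------------------------------- oracle --
def oracle_kept(rows, params):
    """Naive independent reimplementation of classification + rules (i)-(iv)."""
    ncol = len(rows[0])
    nseq = len(rows)
    # classify
    classes = []
    for j in range(ncol):
        col = [r[j] for r in rows]
        if "-" in col:
            classes.append("G")
            continue
        top = max(col.count(c) for c in set(col))
        f = top / nseq
        classes.append("H" if f >= params.flank_fraction
                       else ("C" if f > params.conserved_fraction else "N"))
    dead = set(j for j, c in enumerate(classes) if c == "G")
    # (i) nonconserved stretches touching a gap column
    for j in list(dead):
        k = j - 1
        while k >= 0 and classes[k] == "N":
            dead.add(k); k -= 1
        k = j + 1
        while k < ncol and classes[k] == "N":
            dead.add(k); k += 1
    # (ii) long nonconserved runs among survivors
    run = []
    for j in range(ncol + 1):
        if j < ncol and classes[j] == "N" and j not in dead:
            run.append(j)
        else:
            if len(run) > params.max_contig_nonconserved:
                dead.update(run)
            run = []
    # candidate blocks, flank trimming, length floor
    kept = []
    block = []
    for j in range(ncol + 1):
        if j < ncol and j not in dead:
            block.append(j)
        else:
            while block and classes[block[0]] != "H":
                block.pop(0)
            while block and classes[block[-1]] != "H":
                block.pop()
            if len(block) >= params.min_block_len:
                kept.extend(block)
            block = []
    return kept


# --------------------------------------------------------------- classes --
class TestClassifyColumns:
    def test_unanimous_column_highly_conserved(self):
        aln = _aln(*["A"] * 10)
        assert classify_columns(aln) == [HIGHLY_CONSERVED]

    def test_any_gap_makes_gap_column(self):
        aln = _aln("A", "A", "-")
        assert classify_columns(aln) == [GAP_COL]

    def test_sixty_percent_is_conserved_between_thresholds(self):
        aln = _aln(*(["A"] * 6 + ["C"] * 4))
        params = BlockFilterParams(flank_fraction=0.85, conserved_fraction=0.5)
        assert classify_columns(aln, params) == [CONSERVED]

    def test_half_split_is_nonconserved(self):
        aln = _aln(*(["A"] * 5 + ["C"] * 5))
        assert classify_columns(aln) == [NONCONSERVED]


class TestSelectBlocks:
    def test_all_unanimous_single_block(self):
        rows = ["A" * 20] * 5
        mask = select_blocks(classify_columns(_aln(*rows)))
        assert mask.blocks == ((0, 20),)
        assert len(mask.kept) == 20

    def test_gap_column_splits_into_two_minimum_length_blocks(self):
        # 21 columns: 20 unanimous with a gap column inserted at index 10
        rows = ["A" * 10 + g + "A" * 10 for g in ("-", "A", "A")]
        mask = select_blocks(classify_columns(_aln(*rows)))
        assert mask.blocks == ((0, 10), (11, 21))

    def test_long_nonconserved_run_rejected(self):
        # 9 nonconserved columns (alternating halves) inside conserved context
        n = 12
        left = ["A" * 15] * (n // 2) + ["A" * 15] * (n // 2)
        noncons = ["ACDEFGHIK"] * (n // 2) + ["CAEGDHKFL"] * (n // 2)
        right = ["L" * 15] * n
        rows = [l + m + r for l, m, r in zip(left, noncons, right)]
        mask = select_blocks(classify_columns(_aln(*rows)))
        kept = set(mask.kept)
        assert kept == set(range(0, 15)) | set(range(24, 39))

    def test_equivalence_with_oracle_on_random_alignments(self):
        rng = np.random.default_rng(99)
        params = BlockFilterParams()
        for _ in range(100):
            nseq = int(rng.integers(4, 16))
            ncol = int(rng.integers(15, 61))
            rows = []
            # per-column regime: conserved / noisy / gappy
            regime = rng.random(ncol)
            cons = rng.integers(0, 20, size=ncol)
            cols = []
            for j in range(ncol):
                if regime[j] < 0.5:     # mostly one residue
                    col = [AA[cons[j]] if rng.random() > 0.2 else AA[rng.integers(0, 20)]
                           for _ in range(nseq)]
                elif regime[j] < 0.85:  # noisy
                    col = [AA[rng.integers(0, 20)] for _ in range(nseq)]
                else:                   # occasional gap
                    col = [AA[cons[j]] if rng.random() > 0.1 else "-"
                           for _ in range(nseq)]
                cols.append(col)
            rows = ["".join(cols[j][i] for j in range(ncol)) for i in range(nseq)]
            mask = select_blocks(classify_columns(_aln(*rows), params), params)
            assert list(mask.kept) == oracle_kept(rows, params)

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            nseq, ncol = 8, 50
            rows = []
            base = [AA[i] for i in rng.integers(0, 20, size=ncol)]
            for _ in range(nseq):
                rows.append("".join(
                    b if rng.random() > 0.25 else
                    ("-" if rng.random() < 0.1 else AA[rng.integers(0, 20)])
                    for b in base))
            aln = _aln(*rows)
            try:
                curated, _ = curate(aln)
            except ValueError:
                continue    # everything filtered out: idempotence is vacuous
            curated2, mask2 = curate(curated)
            assert [r.sequence for r in curated2.records] == \
                   [r.sequence for r in curated.records]
            assert mask2.blocks == ((0, curated.columns),) or len(mask2.kept) == curated.columns

    def test_monotonicity_in_parameters(self):
        rng = np.random.default_rng(11)
        base = [AA[i] for i in rng.integers(0, 20, size=60)]
        rows = ["".join(b if rng.random() > 0.3 else AA[rng.integers(0, 20)]
                        for b in base) for _ in range(10)]
        aln = _aln(*rows)
        kept_by_max = []
        for mx in (12, 8, 4, 2):
            p = BlockFilterParams(max_contig_nonconserved=mx)
            kept_by_max.append(len(select_blocks(classify_columns(aln, p), p).kept))
        assert kept_by_max == sorted(kept_by_max, reverse=True)
        kept_by_min = []
        for mb in (1, 5, 10, 20):
            p = BlockFilterParams(min_block_len=mb)
            kept_by_min.append(len(select_blocks(classify_columns(aln, p), p).kept))
        assert kept_by_min == sorted(kept_by_min, reverse=True)


class TestApplyMask:
    def test_full_mask_identity(self):
        aln = _aln("ACDE", "ACDF")
        mask = BlockMask(kept=(0, 1, 2, 3), blocks=((0, 4),))
        out = apply_mask(aln, mask)
        assert [r.sequence for r in out.records] == ["ACDE", "ACDF"]

    def test_empty_mask_is_error(self):
        aln = _aln("ACDE", "ACDF")
        with pytest.raises(ValueError, match="empty curated alignment"):
            apply_mask(aln, BlockMask(kept=(), blocks=()))

    def test_subset(self):
        aln = _aln("ACDE", "ACDF")
        out = apply_mask(aln, BlockMask(kept=(0, 1), blocks=((0, 2),)))
        assert out.columns == 2

    def test_out_of_range_is_error(self):
        aln = _aln("ACDE", "ACDF")
        with pytest.raises(IndexError):
            apply_mask(aln, BlockMask(kept=(0, 9), blocks=((0, 1), (9, 10))))
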