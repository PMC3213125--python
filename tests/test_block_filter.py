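"""Conserved-block classification and selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosignal.block_filter import (
    BlockFilterParams,
    ColumnClass,
    classify_columns,
    filter_alignment,
    format_retained_ranges,
    select_blocks,
)
from mitosignal.codon_tools import GeneAlignment

H, C, N = ColumnClass.HIGHLY_CONSERVED, ColumnClass.CONSERVED, ColumnClass.NONCONSERVED

RELAXED = BlockFilterParams()  # IS=9 FS=13 CP=8 BL=10 with_half


def _column_alignment(*columns: str) -> GeneAlignment:
    """Build an alignment from per-column strings (each of equal height)."""
    n = len(columns[0])
    rows = [(f"t{i:02d}", "".join(col[i] for col in columns)) for i in range(n)]
    return GeneAlignment(gene="g", alphabet="dna", rows=rows)


def brute_force_select(classes, params):
    """Direct-scan reference: enumerate runs and candidate blocks naively."""
    n = len(classes)
    rejected = set()
    i = 0
    while i < n:
        if classes[i] is N:
            j = i
            while j < n and classes[j] is N:
                j += 1
            if j - i > params.max_contig_noncons:
                rejected.update(range(i, j))
            i = j
        else:
            i += 1
    kept = []
    segment = []
    for i in range(n + 1):
        if i < n and i not in rejected:
            segment.append(i)
            continue
        if segment:
            while segment and classes[segment[0]] is not H:
                segment.pop(0)
            while segment and classes[segment[-1]] is not H:
                segment.pop()
            if len(segment) >= params.min_block_len:
                kept.extend(segment)
            segment = []
    return kept


class TestClassify:
    def test_threshold_enumeration_17_rows(self):
        """All majority counts m in 0..17 against IS=9 / FS=13."""
        for m in range(18):
            col = "A" * m + "".join("CGT"[i % 3] for i in range(17 - m))
            aln = _column_alignment(col)
            got = classify_columns(aln, RELAXED)[0]
            if m >= 13:
                assert got is H
            elif m >= 9:
                assert got is C
            else:
                assert got is N

    def test_gap_majority_is_nonconserved_under_with_half(self):
        col = "-" * 10 + "A" * 7
        # 10 gaps of 17 rows > half => nonconserved even though m would pass
        aln = _column_alignment(col)
        assert classify_columns(aln, RELAXED)[0] is N

    def test_sixteen_identical_is_highly_conserved(self):
        aln = _column_alignment("A" * 16 + "C")
        assert classify_columns(aln, RELAXED)[0] is H

    def test_ambiguity_codes_count_as_gaps(self):
        col = "N" * 9 + "A" * 8
        aln = _column_alignment(col)
        assert classify_columns(aln, RELAXED)[0] is N

    def test_gap_mode_none_rejects_any_gap(self):
        params = BlockFilterParams(gap_mode="none")
        aln = _column_alignment("A" * 16 + "-")
        assert classify_columns(aln, params)[0] is N

    def test_codon_unit_takes_worst_class(self):
        good = "A" * 17
        bad = "".join("ACGT"[i % 4] for i in range(17))
        aln = _column_alignment(good, good, bad)
        params = BlockFilterParams(unit="codon")
        assert classify_columns(aln, params) == [N]

    def test_codon_unit_frame_violation(self):
        aln = _column_alignment("A" * 17, "A" * 17)
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_columns(aln, BlockFilterParams(unit="codon"))


class TestSelectBlocks:
    def test_all_highly_conserved_retained(self):
        assert select_blocks([H] * 10, RELAXED) == list(range(10))

    def test_worked_fixture_hhcnnnhhh(self):
        """'HHCNNNHHH' with CP=2, BL=3: only the right-hand block survives."""
        classes = [H, H, C, N, N, N, H, H, H]
        params = BlockFilterParams(
            min_conserved=1, min_flank=1, max_contig_noncons=2, min_block_len=3
        )
        assert select_blocks(classes, params) == [6, 7, 8]

    def test_all_nonconserved_empty(self):
        assert select_blocks([N] * 30, RELAXED) == []

    def test_codon_expansion(self):
        params = BlockFilterParams(
            min_conserved=1, min_flank=1, max_contig_noncons=0, min_block_len=2, unit="codon"
        )
        assert select_blocks([H, H, N], params) == [0, 1, 2, 3, 4, 5]

    @settings(deadline=None, max_examples=200)
    @given(
        classes=st.lists(st.sampled_from([H, C, N]), min_size=0, max_size=200),
        cp=st.integers(0, 10),
        bl=st.integers(1, 15),
    )
    def test_matches_brute_force_reference(self, classes, cp, bl):
        params = BlockFilterParams(
            min_conserved=1, min_flank=1, max_contig_noncons=cp, min_block_len=bl
        )
        assert select_blocks(classes, params) == brute_force_select(classes, params)

    @settings(deadline=None, max_examples=100)
    @given(
        classes=st.lists(st.sampled_from([H, C, N]), min_size=1, max_size=120),
        cp=st.integers(0, 8),
        bl=st.integers(2, 12),
    )
    def test_block_structure_invariants(self, classes, cp, bl):
        params = BlockFilterParams(
            min_conserved=1, min_flank=1, max_contig_noncons=cp, min_block_len=bl
        )
        retained = select_blocks(classes, params)
        assert retained == sorted(set(retained))
        # decompose into maximal contiguous retained blocks
        blocks, cur = [], []
        for idx in retained:
            if cur and idx != cur[-1] + 1:
                blocks.append(cur)
                cur = []
            cur.append(idx)
        if cur:
            blocks.append(cur)
        for block in blocks:
            assert classes[block[0]] is H and classes[block[-1]] is H
            assert len(block) >= params.min_block_len
            run = 0
            for idx in block:
                run = run + 1 if classes[idx] is N else 0
                assert run <= params.max_contig_noncons

    @settings(deadline=None, max_examples=60)
    @given(
        classes=st.lists(st.sampled_from([H, C, N]), min_size=1, max_size=120),
        cp=st.integers(0, 6),
        bl=st.integers(2, 10),
    )
    def test_relaxing_parameters_is_monotone(self, classes, cp, bl):
        base = BlockFilterParams(min_conserved=1, min_flank=1, max_contig_noncons=cp, min_block_len=bl)
        laxer_cp = BlockFilterParams(min_conserved=1, min_flank=1, max_contig_noncons=cp + 1, min_block_len=bl)
        laxer_bl = BlockFilterParams(min_conserved=1, min_flank=1, max_contig_noncons=cp, min_block_len=max(bl - 1, 1))
        tight = set(select_blocks(classes, base))
        assert tight <= set(select_blocks(classes, laxer_cp))
        assert tight <= set(select_blocks(classes, laxer_bl))


class TestFilterAlignment:
    def test_identity_on_fully_conserved(self):
        aln = _column_alignment(*["A" * 17] * 12)
        out, cols = filter_alignment(aln, RELAXED)
        assert cols == list(range(12))
        assert out.rows == aln.rows

    def test_equals_composition_of_classify_and_select(self, rng):
        cols = []
        for _ in range(60):
            kind = rng.integers(3)
            if kind == 0:
                cols.append("A" * 17)
            elif kind == 1:
                cols.append("A" * 10 + "CGTCGTC")
            else:
                cols.append("".join(rng.choice(list("ACGT-"), size=17)))
        aln = _column_alignment(*cols)
        out, retained = filter_alignment(aln, RELAXED)
        expected = select_blocks(classify_columns(aln, RELAXED), RELAXED)
        assert retained == expected
        assert out.column_count == len(expected)

    def test_codon_mode_retention_contains_protein_retention(self):
        """When AA and codon classes coincide, DNA columns = 3x protein columns."""
        conserved_aa, variable_aa = "M", "ACDEFGHIKLMNPQRST"
        prot_cols = ["M" * 17] * 14 + [variable_aa] * 3 + ["M" * 17] * 4
        n = len(prot_cols[0])
        prot = GeneAlignment(
            gene="g", alphabet="protein",
            rows=[(f"t{i:02d}", "".join(c[i] for c in prot_cols)) for i in range(n)],
        )
        aa_to_codon = {"M": "ATG"}
        from mitosignal.codon_tools import INVERTEBRATE_MITO
        rev = {}
        for codon, aa in sorted(INVERTEBRATE_MITO.codon_to_aa.items()):
            rev.setdefault(aa, codon)
        dna = GeneAlignment(
            gene="g", alphabet="dna",
            rows=[(t, "".join(rev[aa] for aa in row)) for t, row in prot.rows],
        )
        prot_params = BlockFilterParams(min_block_len=4)
        dna_params = BlockFilterParams(min_block_len=4, unit="codon")
        _, prot_cols_kept = filter_alignment(prot, prot_params)
        _, dna_cols_kept = filter_alignment(dna, dna_params)
        expanded = {3 * c + off for c in prot_cols_kept for off in range(3)}
        assert expanded <= set(dna_cols_kept)


def test_retained_ranges_format():
    assert format_retained_ranges([0, 1, 2, 6, 7]) == "[1  3] [7  8]"
    assert format_retained_ranges([]) == ""
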