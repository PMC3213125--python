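"""Conserved-block selection for alignments (Gblocks-style trimming).

Columns are classified as nonconserved / conserved / highly conserved from
the frequency of their most common unambiguous residue and their gap
content; blocks of columns are then retained only if they are flanked by
highly conserved positions, are long enough, and contain no long run of
nonconserved positions.  This reimplements the published block-selection
procedure at the level of its parameters (conservation thresholds, flank
requirement, contiguous-nonconserved cap, minimum block length, gap
handling, residue vs codon units); byte-parity with any particular binary
is not promised.

Conservation is counted by strict residue identity.  Ambiguity codes count
as gaps, which is conservative and deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

from .codon_tools import GAP, GeneAlignment

__all__ = [
    "ColumnClass",
    "BlockFilterParams",
    "RELAXED_PROTEIN",
    "relaxed_params",
    "classify_columns",
    "select_blocks",
    "filter_alignment",
]

_DNA_UNAMBIG = frozenset("ACGT")
_PROTEIN_UNAMBIG = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ColumnClass(enum.IntEnum):
    """Gblocks column taxonomy; ordering = severity (lower is worse)."""

    NONCONSERVED = 0
    CONSERVED = 1
    HIGHLY_CONSERVED = 2


@dataclass(frozen=True)
class BlockFilterParams:
    """Block-selection parameters.

    min_conserved        IS: minimum sequences for a conserved position
    min_flank            FS: minimum sequences for a flank position
    max_contig_noncons   CP: maximum contiguous nonconserved positions
    min_block_len        BL: minimum length of a block
    gap_mode             'none' | 'with_half' | 'all'
    unit                 'residue' | 'codon' (codon = worst class of triplet)
    """

    min_conserved: int = 9
    min_flank: int = 13
    max_contig_noncons: int = 8
    min_block_len: int = 10
    gap_mode: str = "with_half"
    unit: str = "residue"

    def __post_init__(self) -> None:
        if not 0 < self.min_conserved <= self.min_flank:
            raise ValueError("require 0 < min_conserved <= min_flank")
        if self.max_contig_noncons < 0:
            raise ValueError("max_contig_noncons must be >= 0")
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")
        if self.gap_mode not in ("none", "with_half", "all"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.unit not in ("residue", "codon"):
            raise ValueError(f"unknown unit {self.unit!r}")


#: The relaxed parameter set used for 17-taxon mitogenome alignments
#: (IS=9, FS=13, CP=8, BL=10, gaps allowed with half).
RELAXED_PROTEIN = BlockFilterParams()


def relaxed_params(unit: str = "residue") -> BlockFilterParams:
    """The relaxed parameter set, for residue (protein/RNA) or codon (DNA) units."""
    return replace(RELAXED_PROTEIN, unit=unit)


def _classify_one(column: str, n: int, params: BlockFilterParams, unambig: frozenset[str]) -> ColumnClass:
    gaps = sum(1 for ch in column if ch not in unambig)
    if params.gap_mode == "none" and gaps > 0:
        return ColumnClass.NONCONSERVED
    if params.gap_mode == "with_half" and gaps > n / 2:
        return ColumnClass.NONCONSERVED
    counts: dict[str, int] = {}
    for ch in column:
        if ch in unambig:
            counts[ch] = counts.get(ch, 0) + 1
    m = max(counts.values(), default=0)
    if m < params.min_conserved:
        return ColumnClass.NONCONSERVED
    if m >= params.min_flank:
        return ColumnClass.HIGHLY_CONSERVED
    return ColumnClass.CONSERVED


def classify_columns(aln: GeneAlignment, params: BlockFilterParams) -> list[ColumnClass]:
    """Classify each column (or codon triplet, with unit='codon').

    A codon unit takes the worst class among its three nucleotide columns,
    so a single bad position disqualifies the whole codon.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    if params.min_flank > len(aln.rows):
        raise ValueError("min_flank exceeds the number of sequences")
    unambig = _PROTEIN_UNAMBIG if aln.alphabet == "protein" else _DNA_UNAMBIG
    n = len(aln.rows)
    seqs = [seq.replace("U", "T") if aln.alphabet != "protein" else seq for _, seq in aln.rows]
    per_column = [
        _classify_one("".join(s[c] for s in seqs), n, params, unambig)
        for c in range(aln.column_count)
    ]
    if params.unit == "residue":
        return per_column
    if aln.column_count % 3:
        raise ValueError(f"{aln.gene}: column count {aln.column_count} not divisible by 3 (unit='codon')")
    return [min(per_column[i : i + 3]) for i in range(0, aln.column_count, 3)]


def select_blocks(classes: Sequence[ColumnClass], params: BlockFilterParams) -> list[int]:
    """Select retained column indices (0-based, strictly increasing).

    Procedure: (1) reject every maximal run of nonconserved units longer
    than max_contig_noncons; (2) the remaining segments are candidate
    blocks; (3) trim each candidate from both ends until it starts and ends
    with a highly conserved unit; (4) reject candidates shorter than
    min_block_len; (5) return surviving units, expanded to nucleotide
    columns when unit='codon'.
    """
    n = len(classes)
    rejected = [False] * n
    i = 0
    while i < n:
        if classes[i] == ColumnClass.NONCONSERVED:
            j = i
            while j < n and classes[j] == ColumnClass.NONCONSERVED:
                j += 1
            if j - i > params.max_contig_noncons:
                for k in range(i, j):
                    rejected[k] = True
            i = j
        else:
            i += 1

    retained: list[int] = []
    i = 0
    while i < n:
        if rejected[i]:
            i += 1
            continue
        j = i
        while j < n and not rejected[j]:
            j += 1
        # candidate segment [i, j); trim to highly conserved flanks
        lo, hi = i, j - 1
        while lo <= hi and classes[lo] != ColumnClass.HIGHLY_CONSERVED:
            lo += 1
        while hi >= lo and classes[hi] != ColumnClass.HIGHLY_CONSERVED:
            hi -= 1
        if lo <= hi and hi - lo + 1 >= params.min_block_len:
            retained.extend(range(lo, hi + 1))
        i = j

    if params.unit == "codon":
        return [3 * u + off for u in retained for off in range(3)]
    return retained


def filter_alignment(
    aln: GeneAlignment, params: BlockFilterParams
) -> tuple[GeneAlignment, list[int]]:
    """Restrict an alignment to its retained block columns.

    Returns the trimmed alignment and the retained original column indices
    (0-based), for coordinate back-translation.
    """
    classes = classify_columns(aln, params)
    cols = select_blocks(classes, params)
    return aln.subset_columns(cols), cols


def format_retained_ranges(cols: Sequence[int]) -> str:
    """Render retained columns as 1-based inclusive ranges ('[12  47] [60  81]')."""
    if not cols:
        return ""
    runs: list[tuple[int, int]] = []
    start = prev = cols[0]
    for c in cols[1:]:
        if c == prev + 1:
            prev = c
        else:
            runs.append((start, prev))
            start = prev = c
    runs.append((start, prev))
    return " ".join(f"[{a + 1}  {b + 1}]" for a, b in runs)
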