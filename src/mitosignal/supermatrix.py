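"""Concatenated multi-gene matrices with partition bookkeeping.

Builds a supermatrix from per-gene alignments over a shared taxon set
(missing genes padded with gaps), and provides the matrix-level transforms
used in mitogenomic saturation handling: stripping codon positions, RY
recoding, and binning sites into discrete rate categories with a parsimony
proxy.  Charset coordinates are 0-based half-open internally and 1-based
inclusive in NEXUS output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codon_tools import GAP, GeneAlignment

__all__ = [
    "Supermatrix",
    "concatenate",
    "drop_codon_positions",
    "ry_recode",
    "assign_rate_categories",
    "fitch_score",
    "write_nexus",
    "read_nexus",
    "write_phylip",
    "write_fasta_matrix",
    "write_raxml_partitions",
]

#: molecule class label per GeneAlignment alphabet
_MOLECULE_CLASS = {"dna": "protein-coding", "rna": "RNA", "protein": "protein"}


@dataclass
class Supermatrix:
    """Concatenated matrix: rows keyed by taxon, charsets tiling the columns."""

    rows: dict[str, str]
    charsets: list[tuple[str, int, int]]  # (gene, start, end), half-open
    partition_scheme: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged supermatrix rows: lengths {sorted(lengths)}")
        ncol = lengths.pop() if lengths else 0
        pos = 0
        for gene, start, end in self.charsets:
            if start != pos or end < start:
                raise ValueError(f"charsets do not tile the columns at {gene!r}")
            pos = end
        if self.charsets and pos != ncol:
            raise ValueError(f"charsets cover {pos} of {ncol} columns")
        names = [g for g, _, _ in self.charsets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in charsets")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return sorted(self.rows)

    def gene_columns(self, gene: str) -> tuple[int, int]:
        for name, start, end in self.charsets:
            if name == gene:
                return start, end
        raise KeyError(gene)

    def is_nucleotide(self) -> bool:
        return all(cls != "protein" for cls in self.partition_scheme.values())


def concatenate(
    gene_alns: Sequence[GeneAlignment],
    taxon_universe: Iterable[str] | None = None,
    *,
    pad: str = GAP,
) -> Supermatrix:
    """Concatenate gene alignments; taxa lacking a gene get gap padding.

    Rows are keyed by taxon label, so the result is invariant to the input
    ordering of sequences within each gene.
    """
    names = [a.gene for a in gene_alns]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    all_taxa = {t for a in gene_alns for t in a.taxa}
    universe = set(taxon_universe) if taxon_universe is not None else all_taxa
    stray = all_taxa - universe
    if stray:
        raise ValueError(f"alignment taxa outside the taxon universe: {sorted(stray)}")

    charsets: list[tuple[str, int, int]] = []
    scheme: dict[str, str] = {}
    pos = 0
    parts: dict[str, list[str]] = {t: [] for t in universe}
    for aln in gene_alns:
        by_taxon = dict(aln.rows)
        width = aln.column_count
        for t in universe:
            parts[t].append(by_taxon.get(t, pad * width))
        charsets.append((aln.gene, pos, pos + width))
        scheme[aln.gene] = _MOLECULE_CLASS[aln.alphabet]
        pos += width
    rows = {t: "".join(chunks) for t, chunks in parts.items()}
    return Supermatrix(rows=rows, charsets=charsets, partition_scheme=scheme)


def drop_codon_positions(sm: Supermatrix, keep: Iterable[int]) -> Supermatrix:
    """Retain only the requested codon positions within protein-coding charsets.

    Non-coding (RNA) charsets are untouched.  Reading frame is assumed to
    start at each coding charset's first column.
    """
    keep_set = frozenset(keep)
    if not keep_set or not keep_set <= {1, 2, 3}:
        raise ValueError("keep must be a nonempty subset of {1, 2, 3}")
    cols: list[int] = []
    charsets: list[tuple[str, int, int]] = []
    pos = 0
    for gene, start, end in sm.charsets:
        coding = sm.partition_scheme.get(gene) == "protein-coding"
        if coding:
            if (end - start) % 3:
                raise ValueError(f"{gene}: length {end - start} violates codon frame")
            gene_cols = [c for c in range(start, end) if (c - start) % 3 + 1 in keep_set]
        else:
            gene_cols = list(range(start, end))
        cols.extend(gene_cols)
        charsets.append((gene, pos, pos + len(gene_cols)))
        pos += len(gene_cols)
    rows = {t: "".join(s[c] for c in cols) for t, s in sm.rows.items()}
    return Supermatrix(rows=rows, charsets=charsets, partition_scheme=dict(sm.partition_scheme))


_RY = {"A": "R", "G": "R", "C": "Y", "T": "Y", "U": "Y", GAP: GAP, "?": "?"}


def ry_recode(sm: Supermatrix) -> Supermatrix:
    """Recode purines as R and pyrimidines as Y (ambiguities become '?')."""
    if not sm.is_nucleotide():
        raise ValueError("RY recoding requires a nucleotide matrix")
    rows = {t: "".join(_RY.get(ch, "?") for ch in s) for t, s in sm.rows.items()}
    return Supermatrix(rows=rows, charsets=list(sm.charsets), partition_scheme=dict(sm.partition_scheme))


# ---------------------------------------------------------------------------
# Parsimony-based site-rate binning

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}
_FULL = 15


def _column_masks(sm: Supermatrix, taxa: Sequence[str]) -> np.ndarray:
    """(n_taxa, n_cols) uint8 bitmasks; gaps/ambiguities = full state set."""
    out = np.full((len(taxa), sm.n_columns), _FULL, dtype=np.uint8)
    for i, t in enumerate(taxa):
        row = sm.rows[t]
        out[i] = [_BASE_BIT.get(ch, _FULL) for ch in row]
    return out


def _parsimony_scores(tree, masks: np.ndarray, taxa: Sequence[str]) -> np.ndarray:
    """Minimum substitutions per column on the tree (Hartigan bottom-up).

    Exact for arbitrary (polytomous) trees under unit costs; gaps and
    ambiguity codes are missing data (full state set, zero cost).
    """
    index = {t: i for i, t in enumerate(taxa)}
    ncol = masks.shape[1]
    cost = np.zeros(ncol, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise ValueError(f"guide tree taxon {label!r} absent from the matrix")
            node_mask[id(node)] = masks[index[label]]
            continue
        children = node.child_nodes()
        counts = np.zeros((4, ncol), dtype=np.int32)
        for ch in children:
            m = node_mask.pop(id(ch))
            for s in range(4):
                counts[s] += (m >> s) & 1
        kmax = counts.max(axis=0)
        mask = np.zeros(ncol, dtype=np.uint8)
        for s in range(4):
            mask |= ((counts[s] == kmax).astype(np.uint8)) << s
        node_mask[id(node)] = mask
        cost += len(children) - kmax
    return cost


def fitch_score(tree, sm: Supermatrix, column: int) -> int:
    """Parsimony score of a single column (exposed for oracle testing)."""
    taxa = sm.taxa
    masks = _column_masks(sm, taxa)[:, [column]]
    return int(_parsimony_scores(tree, masks, taxa)[0])


def assign_rate_categories(sm: Supermatrix, guide_tree, k: int = 6) -> np.ndarray:
    """Bin columns into k rate categories (1 = fastest) by parsimony score.

    The per-column rate proxy is the minimum number of substitutions on the
    guide tree; columns are split at score quantiles, ties going to the
    faster bin, and constant columns always land in the slowest bin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    matrix_taxa = set(sm.rows)
    tree_taxa = {leaf.taxon.label for leaf in guide_tree.leaf_node_iter()}
    if not matrix_taxa <= tree_taxa:
        raise ValueError(f"guide tree lacks taxa {sorted(matrix_taxa - tree_taxa)}")
    taxa = sm.taxa
    scores = _parsimony_scores(guide_tree, _column_masks(sm, taxa), taxa)
    bounds = np.quantile(scores, [j / k for j in range(1, k)])
    cats = 1 + (scores[:, None] < bounds[None, :]).sum(axis=1)
    cats[scores == 0] = k
    return cats.astype(int)


# ---------------------------------------------------------------------------
# Writers / readers


def _needs_quoting(label: str) -> bool:
    return bool(re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>~-]", label))


def _nexus_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(sm: Supermatrix, path: str | Path) -> None:
    """NEXUS with a sets block (1-based inclusive charsets, MrBayes dialect)."""
    datatype = "protein" if not sm.is_nucleotide() else "dna"
    taxa = sm.taxa
    lines = [
        "#NEXUS",
        "begin data;",
        f"    dimensions ntax={len(taxa)} nchar={sm.n_columns};",
        f"    format datatype={datatype} gap=- missing=?;",
        "    matrix",
    ]
    for t in taxa:
        lines.append(f"    {_nexus_label(t)}  {sm.rows[t]}")
    lines += ["    ;", "end;", "", "begin sets;"]
    for gene, start, end in sm.charsets:
        lines.append(f"    charset {gene} = {start + 1}-{end};")
    classes: dict[str, list[str]] = {}
    for gene, _, _ in sm.charsets:
        classes.setdefault(sm.partition_scheme[gene], []).append(gene)
    groups = ", ".join(f"{cls}: {' '.join(genes)}" for cls, genes in classes.items())
    lines.append(f"    charpartition molecule = {groups};")
    lines += ["end;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus(path: str | Path) -> Supermatrix:
    """Re-import a supermatrix written by :func:`write_nexus`."""
    text = Path(path).read_text()
    matrix_m = re.search(r"matrix\s*\n(.*?)\n\s*;", text, re.S | re.I)
    if not matrix_m:
        raise ValueError("no matrix block found")
    rows: dict[str, str] = {}
    for line in matrix_m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            m = re.match(r"'((?:[^']|'')*)'\s+(\S+)", line)
            if not m:
                raise ValueError(f"unparseable matrix line: {line!r}")
            label, seq = m.group(1).replace("''", "'"), m.group(2)
        else:
            label, seq = line.split(None, 1)
            seq = seq.strip()
        rows[label] = seq
    charsets = [
        (m.group(1), int(m.group(2)) - 1, int(m.group(3)))
        for m in re.finditer(r"charset\s+(\S+)\s*=\s*(\d+)-(\d+)\s*;", text)
    ]
    scheme: dict[str, str] = {}
    part_m = re.search(r"charpartition\s+\S+\s*=\s*(.*?);", text, re.S)
    if part_m:
        for group in part_m.group(1).split(","):
            cls, _, genes = group.partition(":")
            for gene in genes.split():
                scheme[gene] = cls.strip()
    return Supermatrix(rows=rows, charsets=charsets, partition_scheme=scheme)


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (whitespace in labels replaced by underscores)."""
    taxa = sm.taxa
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)} {sm.n_columns}\n")
        for t in taxa:
            label = re.sub(r"\s", "_", t)
            fh.write(f"{label}  {sm.rows[t]}\n")


def write_fasta_matrix(sm: Supermatrix, path: str | Path) -> None:
    from .codon_tools import write_fasta

    write_fasta(path, [(t, sm.rows[t]) for t in sm.taxa])


def write_raxml_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file (one line per gene charset, 1-based)."""
    datatype = "WAG" if not sm.is_nucleotide() else "DNA"
    with open(path, "w") as fh:
        for gene, start, end in sm.charsets:
            fh.write(f"{datatype}, {gene} = {start + 1}-{end}\n")
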