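"""Genetic-code-aware translation and protein-guided back-translation.

Mitochondrial protein-coding genes are aligned at the amino-acid level
(indels occur in units of codons), and the nucleotide alignment is then
obtained by transferring the protein-alignment gaps back onto the unaligned
DNA.  This module implements that back-translation step, the underlying
translation, and FASTA I/O for the alignment containers used throughout the
package.

Taxon labels are treated as opaque strings: no whitespace munging, so
FASTA/Newick round trips are safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "AlphabetError",
    "ConsistencyError",
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "GeneAlignment",
    "translate",
    "transfer_gaps",
    "read_fasta",
    "write_fasta",
]

GAP = "-"
_DNA_BASES = frozenset("ACGT")
_DNA_AMBIG = frozenset("RYSWKMBDHVN")
_PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
_PROTEIN_EXTRA = frozenset("XBZJUO*")


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class ConsistencyError(ValueError):
    """Protein and nucleotide inputs disagree (back-translation mismatch)."""


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon -> amino-acid map (stops encoded as ``*``).

    Built from the NCBI translation tables shipped with Biopython; the
    invertebrate mitochondrial code (table 5) is the package default, under
    which AGA/AGG encode serine, ATA methionine and TGA tryptophan.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}")
        if "*" not in self.codon_to_aa.values():
            raise ValueError("genetic code must contain at least one stop codon")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
        )


#: NCBI translation table 5 (invertebrate mitochondrial), the package default.
INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)

_ALPHABETS = {
    "protein": _PROTEIN_RESIDUES | _PROTEIN_EXTRA | {GAP, "?"},
    "dna": _DNA_BASES | _DNA_AMBIG | {GAP, "?", "U"},
    "rna": _DNA_BASES | _DNA_AMBIG | {GAP, "?", "U"},
}


@dataclass
class GeneAlignment:
    """One gene's aligned sequences with taxon labels.

    ``alphabet`` is one of ``protein``, ``dna`` (protein-coding nucleotide)
    or ``rna`` (tRNA/rRNA nucleotide — chemically stored as DNA letters, the
    tag records the molecule class for partitioning).
    """

    gene: str
    alphabet: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.rows = [(label, seq.upper()) for label, seq in self.rows]
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged alignment, row lengths {sorted(lengths)}")
        labels = [label for label, _ in self.rows]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"{self.gene}: duplicate taxon labels {dupes}")
        allowed = _ALPHABETS[self.alphabet]
        for label, seq in self.rows:
            bad = set(seq) - allowed
            if bad:
                raise AlphabetError(f"{self.gene}/{label}: illegal characters {sorted(bad)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return [label for label, _ in self.rows]

    def sequence(self, taxon: str) -> str:
        for label, seq in self.rows:
            if label == taxon:
                return seq
        raise KeyError(taxon)

    def subset_columns(self, columns: Sequence[int]) -> "GeneAlignment":
        cols = list(columns)
        return GeneAlignment(
            gene=self.gene,
            alphabet=self.alphabet,
            rows=[(label, "".join(seq[c] for c in cols)) for label, seq in self.rows],
        )

    def restrict_taxa(self, taxa: Iterable[str]) -> "GeneAlignment":
        keep = set(taxa)
        return GeneAlignment(
            gene=self.gene,
            alphabet=self.alphabet,
            rows=[(label, seq) for label, seq in self.rows if label in keep],
        )


def degap(seq: str) -> str:
    return seq.replace(GAP, "")


def translate(dna: str, code: GeneticCode = INVERTEBRATE_MITO, *, context: str = "") -> str:
    """Translate an ungapped nucleotide string to protein.

    Trailing incomplete codons (truncated stops are common in mitogenomes)
    are trimmed with a warning.  Codons containing ambiguity codes translate
    to ``X``; internal stops translate to ``*`` with a warning rather than an
    error, so downstream column filtering can deal with them.
    """
    seq = dna.upper().replace("U", "T")
    if GAP in seq:
        raise AlphabetError(f"{context}: translate() requires ungapped input")
    bad = set(seq) - _DNA_BASES - _DNA_AMBIG
    if bad:
        raise AlphabetError(f"{context}: non-nucleotide characters {sorted(bad)}")
    if len(seq) % 3:
        warnings.warn(
            f"{context or 'sequence'}: trailing incomplete codon "
            f"({len(seq) % 3} nt) trimmed before translation",
            stacklevel=2,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = code.codon_to_aa.get(codon, "X")
        if aa == "*" and i + 3 < len(seq):
            warnings.warn(
                f"{context or 'sequence'}: internal stop codon {codon} at nt {i}",
                stacklevel=2,
            )
        out.append(aa)
    return "".join(out)


def _aa_compatible(observed: str, expected: str) -> bool:
    # 'X' masks either side (ambiguous codons translate to X)
    return observed == expected or "X" in (observed, expected)


def transfer_gaps(
    prot_aln: GeneAlignment,
    dna_by_taxon: Mapping[str, str],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> GeneAlignment:
    """Transfer protein-alignment gaps onto unaligned nucleotide sequences.

    Each protein gap column becomes ``---``; every other protein column is
    replaced by the taxon's next codon.  The output therefore has exactly
    3x the protein column count, and degapping it recovers the input DNA
    (minus any trimmed trailing stop/incomplete codon).
    """
    if prot_aln.alphabet != "protein":
        raise ValueError("transfer_gaps expects a protein alignment")
    missing = set(prot_aln.taxa) - set(dna_by_taxon)
    if missing:
        raise ConsistencyError(f"{prot_aln.gene}: no nucleotide sequence for {sorted(missing)}")

    out_rows: list[tuple[str, str]] = []
    for taxon, prot_row in prot_aln.rows:
        dna = dna_by_taxon[taxon].upper().replace("U", "T")
        if len(dna) % 3:
            dna = dna[: len(dna) - len(dna) % 3]
        residues = degap(prot_row)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aa = translate(dna, code, context=f"{prot_aln.gene}/{taxon}")
        if len(aa) == len(residues) + 1 and aa[-1] == "*":
            # trailing stop codon present in the DNA but not the protein row
            aa = aa[:-1]
            dna = dna[:-3]
        if len(aa) != len(residues):
            raise ConsistencyError(
                f"{prot_aln.gene}/{taxon}: protein row has {len(residues)} residues "
                f"but DNA translates to {len(aa)}"
            )
        for i, (obs, exp) in enumerate(zip(aa, residues)):
            if not _aa_compatible(obs, exp):
                raise ConsistencyError(
                    f"{prot_aln.gene}/{taxon}: codon {i} ({dna[3*i:3*i+3]}) translates "
                    f"to {obs!r}, protein row has {exp!r}"
                )
        codons = iter(dna[i : i + 3] for i in range(0, len(dna), 3))
        out = "".join("---" if ch == GAP else next(codons) for ch in prot_row)
        out_rows.append((taxon, out))
    return GeneAlignment(gene=prot_aln.gene, alphabet="dna", rows=out_rows)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (label, sequence) pairs.

    The full header line (after ``>``) is the label, kept verbatim.
    """
    rows: list[tuple[str, str]] = []
    label: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if label is not None:
                    rows.append((label, "".join(chunks)))
                label = line[1:].strip()
                chunks = []
            elif line.strip():
                chunks.append(line.strip())
    if label is not None:
        rows.append((label, "".join(chunks)))
    return rows


def write_fasta(path: str | Path, rows: Iterable[tuple[str, str]], wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for label, seq in rows:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_alignment(path: str | Path, gene: str, alphabet: str) -> GeneAlignment:
    return GeneAlignment(gene=gene, alphabet=alphabet, rows=read_fasta(path))
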