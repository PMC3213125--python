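"""End-to-end single-gene reliability assessment.

Orchestrates the full analysis: build the whole-matrix reference tree,
score every gene tree against it (RF distance + branch-length scale
factor), select the k best genes, rebuild a tree from just those genes and
compare it back to the reference — optionally repeating the comparison
after removing long-branch taxa (divergence-to-root screen) and
re-inferring everything from the filtered alignments.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .block_filter import BlockFilterParams, filter_alignment
from .codon_tools import GeneAlignment
from .inference import EngineSpec, infer_tree
from .supermatrix import Supermatrix, concatenate, drop_codon_positions
from .tree_metrics import (
    GeneScore,
    filter_long_branches,
    leaf_labels,
    rf_distance,
    scale_factor,
    write_newick,
)

__all__ = [
    "AssessmentConfig",
    "ComparisonRow",
    "AssessmentReport",
    "build_reference",
    "score_genes",
    "select_top_genes",
    "compare_subset",
    "run_assessment",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AssessmentConfig:
    """Everything one assessment run needs.

    ``keep_positions`` applies to protein-coding genes only (third-position
    stripping is the standard saturation treatment); ``block_params`` is
    applied per gene before concatenation when given.  When
    ``long_branch_threshold`` is set, the comparison is repeated on data
    with the flagged taxa removed, and by default the filtered reference
    tree (re-inferred without those taxa) is the comparison baseline.
    """

    genes: tuple[GeneAlignment, ...]
    taxon_universe: frozenset[str] | None = None
    block_params: BlockFilterParams | None = None
    keep_positions: frozenset[int] = frozenset({1, 2, 3})
    engine: EngineSpec = field(default_factory=EngineSpec)
    outgroup: str | None = None
    long_branch_threshold: float | None = None
    filtered_reference: bool = True
    k: int = 5
    criterion: str = "rf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > len(self.genes):
            raise ValueError(f"k={self.k} exceeds the {len(self.genes)} genes")
        if self.long_branch_threshold is not None and self.long_branch_threshold <= 0:
            raise ValueError("long-branch threshold must be positive")
        if self.criterion not in ("rf", "scale"):
            raise ValueError(f"unknown selection criterion {self.criterion!r}")

    def universe(self) -> frozenset[str]:
        if self.taxon_universe is not None:
            return self.taxon_universe
        return frozenset(t for g in self.genes for t in g.taxa)

    def config_hash(self) -> str:
        parts = [
            repr(self.keep_positions and sorted(self.keep_positions)),
            repr(self.block_params),
            self.engine.describe(),
            repr(self.outgroup),
            repr(self.long_branch_threshold),
            repr(self.filtered_reference),
            repr((self.k, self.criterion, self.seed)),
        ]
        h = hashlib.sha256("\n".join(parts).encode())
        for g in self.genes:
            h.update(g.gene.encode())
            for label, seq in g.rows:
                h.update(label.encode())
                h.update(seq.encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ComparisonRow:
    """One subset-vs-reference comparison (a table row)."""

    dataset: str
    scale_factor: float
    rf: int
    n_taxa: int


@dataclass
class AssessmentReport:
    engine: str
    gene_scores: list[GeneScore]
    selected: list[str]
    comparisons: list[ComparisonRow]
    removed_taxa: list[tuple[str, float]]
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "engine": self.engine,
            "gene_scores": [asdict(s) for s in self.gene_scores],
            "selected": self.selected,
            "comparisons": [asdict(c) for c in self.comparisons],
            "removed_taxa": [{"taxon": t, "divergence": d} for t, d in self.removed_taxa],
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def gene_table_tsv(self, path: str | Path | None = None) -> str:
        lines = ["gene\tscale_factor\trf"]
        lines += [f"{s.gene}\t{s.scale_factor:.4f}\t{s.rf}" for s in self.gene_scores]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def comparison_table_tsv(self, path: str | Path | None = None) -> str:
        lines = ["dataset\tscale_factor\trf"]
        lines += [f"{c.dataset}\t{c.scale_factor:.5f}\t{c.rf}" for c in self.comparisons]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _process_gene(
    aln: GeneAlignment, config: AssessmentConfig, exclude: frozenset[str]
) -> GeneAlignment:
    """Per-gene processing: taxon exclusion, block filtering, position stripping."""
    out = aln.restrict_taxa(set(aln.taxa) - exclude) if exclude else aln
    if config.block_params is not None:
        params = config.block_params
        if aln.alphabet == "dna" and params.unit != "codon":
            from dataclasses import replace

            params = replace(params, unit="codon")
        out, _ = filter_alignment(out, params)
    if out.alphabet == "dna" and config.keep_positions != frozenset({1, 2, 3}):
        sm = concatenate([out])
        sm = drop_codon_positions(sm, config.keep_positions)
        out = GeneAlignment(
            gene=out.gene, alphabet=out.alphabet,
            rows=[(t, sm.rows[t]) for t in out.taxa],
        )
    return out


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def build_reference(
    config: AssessmentConfig, exclude: frozenset[str] = frozenset()
) -> tuple[Supermatrix, dendropy.Tree]:
    """Process and concatenate all genes, then infer the reference tree."""
    universe = config.universe() - exclude
    if len(universe) < 4:
        raise StageError("build_reference: fewer than 4 taxa after processing")
    with _stage("process-genes"):
        processed = [_process_gene(g, config, exclude) for g in config.genes]
    with _stage("concatenate"):
        sm = concatenate(processed, universe)
    with _stage("infer-reference"):
        matrix_aln = GeneAlignment(
            gene="supermatrix", alphabet="dna",
            rows=[(t, sm.rows[t]) for t in sm.taxa],
        )
        tree = infer_tree(matrix_aln, config.engine)
    return sm, tree


def score_genes(
    gene_alns: Sequence[GeneAlignment],
    ref_tree: dendropy.Tree,
    config: AssessmentConfig,
    exclude: frozenset[str] = frozenset(),
) -> list[GeneScore]:
    """Infer a tree per gene and score it against the reference.

    Genes covering fewer than 4 reference taxa are skipped with a warning.
    """
    ref_taxa = leaf_labels(ref_tree)
    scores: list[GeneScore] = []
    for aln in gene_alns:
        processed = _process_gene(aln, config, exclude)
        shared = set(processed.taxa) & ref_taxa
        if len(shared) < 4:
            logger.warning("gene %s covers only %d reference taxa; skipped", aln.gene, len(shared))
            continue
        with _stage(f"infer-{aln.gene}"):
            gtree = infer_tree(processed.restrict_taxa(shared), config.engine)
        scores.append(
            GeneScore(
                gene=aln.gene,
                rf=rf_distance(gtree, ref_tree),
                scale_factor=scale_factor(gtree, ref_tree),
            )
        )
    return scores


def select_top_genes(
    scores: Sequence[GeneScore], k: int, criterion: str = "rf"
) -> list[str]:
    """Pick the k best genes.

    ``rf``: ascending RF distance (topological concordance), ties broken by
    |log scale factor| then gene name.  ``scale``: ascending |log scale
    factor| (global divergence closest to the whole matrix, symmetric in
    faster/slower), ties broken by RF then gene name.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored genes")
    if criterion == "rf":
        key = lambda s: (s.rf, abs(math.log(s.scale_factor)), s.gene)
    elif criterion == "scale":
        key = lambda s: (abs(math.log(s.scale_factor)), s.rf, s.gene)
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return [s.gene for s in sorted(scores, key=key)[:k]]


def compare_subset(
    selected: Sequence[str],
    ref_tree: dendropy.Tree,
    config: AssessmentConfig,
    exclude: frozenset[str] = frozenset(),
) -> tuple[float, int]:
    """Concatenate only the selected genes, infer, and compare to the reference."""
    if not selected:
        raise ValueError("no genes selected")
    chosen = [g for g in config.genes if g.gene in set(selected)]
    universe = config.universe() - exclude
    processed = [_process_gene(g, config, exclude) for g in chosen]
    sm = concatenate(processed, universe)
    subset_aln = GeneAlignment(
        gene="subset", alphabet="dna", rows=[(t, sm.rows[t]) for t in sm.taxa]
    )
    with _stage("infer-subset"):
        tree = infer_tree(subset_aln, config.engine)
    return scale_factor(tree, ref_tree), rf_distance(tree, ref_tree)


def run_assessment(config: AssessmentConfig) -> AssessmentReport:
    """The whole analysis; with a long-branch threshold, both the unfiltered
    and the taxon-filtered comparisons are reported (paired rows)."""
    _, ref_tree = build_reference(config)
    scores = score_genes(config.genes, ref_tree, config)
    selected = select_top_genes(scores, config.k, config.criterion)
    k_full, rf_full = compare_subset(selected, ref_tree, config)
    comparisons = [
        ComparisonRow("full", k_full, rf_full, len(leaf_labels(ref_tree)))
    ]
    removed: list[tuple[str, float]] = []
    if config.long_branch_threshold is not None:
        _, removed = filter_long_branches(
            ref_tree, config.long_branch_threshold, config.outgroup
        )
        if config.outgroup is not None:
            removed = [(t, d) for t, d in removed if t != config.outgroup]
        exclude = frozenset(t for t, _ in removed)
        if exclude:
            ref2 = ref_tree
            if config.filtered_reference:
                _, ref2 = build_reference(config, exclude)
            k_f, rf_f = compare_subset(selected, ref2, config, exclude)
            comparisons.append(
                ComparisonRow(
                    "long-branch taxa excluded", k_f, rf_f, len(leaf_labels(ref2))
                )
            )
        else:
            comparisons.append(
                ComparisonRow("long-branch taxa excluded", k_full, rf_full,
                              len(leaf_labels(ref_tree)))
            )
    report = AssessmentReport(
        engine=config.engine.describe(),
        gene_scores=scores,
        selected=selected,
        comparisons=comparisons,
        removed_taxa=removed,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "engine": config.engine.describe(),
            "reference_newick": write_newick(ref_tree).strip(),
            "filtered_reference": config.filtered_reference,
        },
    )
    return report
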