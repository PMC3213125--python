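"""Seeded desk-scale validation studies.

Each study generates synthetic data with :mod:`mitosignal.synthetic_data`,
runs the pipeline, and measures how well a known quantity is recovered:
per-gene rate multipliers via the scale factor, long-branch taxa via the
root-to-tip screen, topology via neighbor joining on additive distances,
and the adequacy of a best-gene subset relative to the whole matrix.
Problem sizes are chosen so every study runs in seconds to a few minutes
on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import DistanceMatrix, neighbor_joining
from .reliability_pipeline import AssessmentConfig, build_reference, run_assessment, score_genes
from .synthetic_data import (
    GeneSpec,
    LineageAcceleration,
    MITO_GENE_LENGTHS,
    SimulationConfig,
    make_dataset,
    paper_like_config,
    simulate_tree,
)
from .tree_metrics import filter_long_branches, rf_distance

__all__ = [
    "derive_seeds",
    "multiplier_recovery_study",
    "long_branch_screen_study",
    "five_gene_adequacy_study",
    "nj_additive_recovery_study",
]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31, derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class RecoveryResult:
    multipliers: tuple[float, ...]
    mean_estimates: dict[float, float]
    per_replicate: dict[float, list[float]]
    mean_abs_error: float


def multiplier_recovery_study(
    base_seed: int = 0,
    n_replicates: int = 20,
    *,
    gene_length: int = 5001,
    n_taxa: int = 10,
    depth: float = 0.2,
    multipliers: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> RecoveryResult:
    """Recover per-gene rate multipliers through the pipeline scale factor.

    Each replicate simulates 13 equal-length genes: one probe gene per
    multiplier plus background genes whose rate is set so the length-
    weighted mean multiplier is exactly 1 — the whole-matrix reference tree
    is then on the true tree's scale and the expected scale factor of a
    probe equals its multiplier.
    """
    n_background = 13 - len(multipliers)
    bg_rate = (13 - sum(multipliers)) / n_background
    probes = [GeneSpec(f"probe_{m}", gene_length, m) for m in multipliers]
    background = [GeneSpec(f"bg{i}", gene_length, bg_rate) for i in range(n_background)]
    genes = tuple(probes + background)

    estimates: dict[float, list[float]] = {m: [] for m in multipliers}
    for seed in derive_seeds(base_seed, n_replicates):
        cfg = SimulationConfig(
            n_taxa=n_taxa, depth=depth, genes=genes, seed=seed, outgroup=None
        )
        alns, _ = make_dataset(cfg)
        acfg = AssessmentConfig(genes=tuple(alns), k=5, seed=seed)
        _, ref = build_reference(acfg)
        scores = {s.gene: s for s in score_genes(alns, ref, acfg)}
        for m in multipliers:
            estimates[m].append(scores[f"probe_{m}"].scale_factor)
    means = {m: float(np.mean(v)) for m, v in estimates.items()}
    mae = float(np.mean([abs(e - m) for m, v in estimates.items() for e in v]))
    return RecoveryResult(
        multipliers=multipliers,
        mean_estimates=means,
        per_replicate=estimates,
        mean_abs_error=mae,
    )


@dataclass
class ScreenResult:
    n_replicates: int
    n_accelerated_removed: int  # replicates where every accelerated taxon was removed
    n_background_removals: int  # total background taxa wrongly removed
    divergences: list[float]  # estimated divergence of each accelerated taxon


def long_branch_screen_study(
    base_seed: int = 0,
    n_replicates: int = 20,
    *,
    factor: float = 5.0,
    threshold: float = 0.5,
    depth: float = 0.2,
    n_taxa: int = 10,
) -> ScreenResult:
    """Detect a rate-accelerated lineage with the root-to-tip screen.

    Thirteen typical mitochondrial genes are simulated on a tree with one
    lineage accelerated by ``factor``; the screen runs on the inferred
    whole-matrix tree rooted at a background outgroup.
    """
    genes = tuple(GeneSpec(g, L, 1.0) for g, L in MITO_GENE_LENGTHS.items())
    hits = 0
    false_removals = 0
    divs: list[float] = []
    for seed in derive_seeds(base_seed, n_replicates):
        cfg = SimulationConfig(
            n_taxa=n_taxa,
            depth=depth,
            genes=genes,
            accelerations=(LineageAcceleration(factor=factor),),
            seed=seed,
        )
        alns, truth = make_dataset(cfg)
        acfg = AssessmentConfig(genes=tuple(alns), k=5, outgroup="t01", seed=seed)
        _, ref = build_reference(acfg)
        _, removed = filter_long_branches(ref, threshold, outgroup="t01")
        removed_map = dict(removed)
        accel = set(truth.accelerated_taxa)
        hits += accel <= set(removed_map)
        false_removals += len(set(removed_map) - accel)
        divs.extend(removed_map.get(t, 0.0) for t in sorted(accel))
    return ScreenResult(
        n_replicates=n_replicates,
        n_accelerated_removed=hits,
        n_background_removals=false_removals,
        divergences=divs,
    )


@dataclass
class AdequacyResult:
    n_replicates: int
    n_subset_at_most_median: int
    subset_rfs: list[int]
    median_gene_rfs: list[float]


def five_gene_adequacy_study(
    base_seed: int = 0, n_replicates: int = 20
) -> AdequacyResult:
    """Is a best-5-gene tree as close to the whole-matrix tree as a typical
    single gene?  Uses the 17-taxon, 13-gene preset (published relative-rate
    profile, AT-rich composition, no lineage acceleration) and counts the
    replicates where the top-5 concatenated tree's RF to the reference is at
    most the median single-gene RF."""
    wins = 0
    subset_rfs: list[int] = []
    medians: list[float] = []
    for seed in derive_seeds(base_seed, n_replicates):
        cfg = paper_like_config(seed=seed, accelerations=())
        alns, _ = make_dataset(cfg)
        report = run_assessment(AssessmentConfig(genes=tuple(alns), k=5, seed=seed))
        med = float(np.median([s.rf for s in report.gene_scores]))
        sub = report.comparisons[0].rf
        wins += sub <= med
        subset_rfs.append(sub)
        medians.append(med)
    return AdequacyResult(
        n_replicates=n_replicates,
        n_subset_at_most_median=wins,
        subset_rfs=subset_rfs,
        median_gene_rfs=medians,
    )


def nj_additive_recovery_study(base_seed: int = 0, n_matrices: int = 200) -> int:
    """Neighbor joining on noise-free additive matrices: how many random
    trees (4-10 taxa) are recovered with RF = 0 from their path-length
    matrices.  Returns the number recovered (expected: all)."""
    recovered = 0
    rng = np.random.default_rng(base_seed)
    for _ in range(n_matrices):
        n = int(rng.integers(4, 11))
        tree = simulate_tree(n, float(rng.uniform(0.1, 1.0)), rng)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(t.label for t in tree.taxon_namespace)
        ns = tree.taxon_namespace
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    ns.get_taxon(taxa[i]), ns.get_taxon(taxa[j])
                )
        nj = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
        recovered += rf_distance(nj, tree) == 0
    return recovered
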