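"""Tree-comparison statistics for gene-tree reliability scoring.

A gene tree is scored against a whole-matrix reference tree by two numbers:
the Robinson-Foulds distance (symmetric difference of the nontrivial
bipartitions, a pure topology score) and a branch-length scale factor K,
the least-squares multiplier relating the gene tree's branch lengths to the
reference's over matched branches — K > 1 means the gene evolves faster
than the genome-wide average.  A root-to-tip divergence screen flags
long-branch taxa for removal.

Trees are handled as DendroPy trees; all comparisons are unrooted and,
when leaf sets differ, are restricted to the shared leaf set (edges that
become redundant after restriction have their lengths summed, exactly as
if the trees had been pruned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "GeneScore",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "bipartitions",
    "rf_distance",
    "scale_factor",
    "root_to_tip",
    "filter_long_branches",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneScore:
    """Per-gene concordance with the reference tree (one table row)."""

    gene: str
    rf: int
    scale_factor: float


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string.

    Underscores in labels are preserved verbatim (no space substitution).
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    if path is not None:
        Path(path).write_text(out)
    return out


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _split_lengths(tree: dendropy.Tree, shared: frozenset[str]) -> dict[frozenset, float]:
    """Map each split of the tree restricted to `shared` to its total length.

    Splits are canonicalized as the side not containing the smallest shared
    label, so the result is independent of rooting; edges that map to the
    same restricted split (e.g. the two edges at a bifurcating root, or
    edges made redundant by the restriction) have their lengths summed —
    equivalent to pruning with degree-2 suppression.  Singleton sides are
    terminal branches; the trivial empty/full split is dropped.
    """
    anchor = min(shared)
    below: dict[int, frozenset] = {}
    acc: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            side = frozenset((lab,)) if lab in shared else frozenset()
        else:
            side = frozenset().union(*(below.pop(id(ch)) for ch in node.child_nodes()))
        below[id(node)] = side
        if node.parent_node is None:
            continue
        if anchor in side:
            side = shared - side
        if not side or side == shared:
            continue
        length = node.edge.length or 0.0
        acc[side] = acc.get(side, 0.0) + length
    return acc


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial splits (both sides >= 2 leaves), one per internal edge.

    Trees with fewer than 4 leaves have no nontrivial split (empty set).
    """
    leaves = frozenset(leaf_labels(tree))
    if len(leaves) < 4:
        return set()
    splits = _split_lengths(tree, leaves)
    return {s for s in splits if 2 <= len(s) <= len(leaves) - 2}


def _shared_leaves(t1: dendropy.Tree, t2: dendropy.Tree) -> frozenset[str]:
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    shared = frozenset(l1 & l2)
    if l1 != l2:
        logger.info(
            "leaf sets differ (%d vs %d leaves); restricting to %d shared",
            len(l1), len(l2), len(shared),
        )
    return shared


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance on the shared leaf set.

    Counts splits present in exactly one tree.  Zero iff the unrooted
    topologies agree; odd values arise when one tree has polytomies.
    """
    shared = _shared_leaves(t1, t2)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    n = len(shared)
    b1 = {s for s in _split_lengths(t1, shared) if 2 <= len(s) <= n - 2}
    b2 = {s for s in _split_lengths(t2, shared) if 2 <= len(s) <= n - 2}
    return len(b1 ^ b2)


def scale_factor(gene_tree: dendropy.Tree, ref_tree: dendropy.Tree) -> float:
    """Least-squares branch-length factor K of the gene tree vs the reference.

    Branches are matched on the shared leaf set — terminal branches by leaf
    label, internal branches by identical bipartition — and
    K = sum(b_gene * b_ref) / sum(b_ref^2) minimizes
    sum((b_gene - K * b_ref)^2) over the matched pairs.  Unmatched branches
    (splits absent from the other tree) are excluded; topological
    disagreement is reported separately by the RF distance.
    """
    shared = _shared_leaves(gene_tree, ref_tree)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    gsplits = _split_lengths(gene_tree, shared)
    rsplits = _split_lengths(ref_tree, shared)
    matched = gsplits.keys() & rsplits.keys()
    if not matched:
        raise ValueError("no matched branches between the trees")
    num = sum(gsplits[s] * rsplits[s] for s in matched)
    den = sum(rsplits[s] ** 2 for s in matched)
    if den == 0.0:
        raise ValueError("all matched reference branch lengths are zero")
    return num / den


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def root_to_tip(
    tree: dendropy.Tree,
    outgroup: str | Sequence[str] | None = None,
    *,
    midpoint: bool = False,
) -> dict[str, float]:
    """Root-to-leaf path lengths (substitutions/site) under the given rooting.

    With an outgroup, the root is placed at the node where the outgroup
    (or the MRCA of several outgroup taxa) attaches to the rest of the
    tree; otherwise midpoint rooting is used.
    """
    t = _clone(tree)
    t.is_rooted = True
    if outgroup is not None:
        labels = [outgroup] if isinstance(outgroup, str) else list(outgroup)
        missing = set(labels) - leaf_labels(t)
        if missing:
            raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
        node = t.mrca(taxon_labels=labels)
        if node.parent_node is None:
            # outgroup MRCA is already the seed; fall back to first label's leaf
            node = t.find_node_with_taxon_label(labels[0])
        t.reroot_at_node(node.parent_node, update_bipartitions=False)
    elif midpoint:
        t.reroot_at_midpoint(update_bipartitions=False)
    else:
        logger.info("no outgroup given; falling back to midpoint rooting")
        t.reroot_at_midpoint(update_bipartitions=False)
    return {leaf.taxon.label: leaf.distance_from_root() for leaf in t.leaf_node_iter()}


def filter_long_branches(
    tree: dendropy.Tree,
    threshold: float,
    outgroup: str | Sequence[str] | None = None,
    *,
    midpoint: bool = False,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Split taxa into retained and removed by root-to-tip divergence.

    Removed taxa (divergence strictly greater than the threshold) are
    reported with their divergences, most divergent first.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    div = root_to_tip(tree, outgroup, midpoint=midpoint)
    removed = sorted(
        ((t, d) for t, d in div.items() if d > threshold),
        key=lambda td: (-td[1], td[0]),
    )
    removed_set = {t for t, _ in removed}
    retained = sorted(t for t in div if t not in removed_set)
    return retained, removed
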