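"""Distance-based tree inference and the external-engine adapter.

The pipeline needs a deterministic, dependency-free way to turn an
alignment into a tree so the whole reliability analysis runs offline:
pairwise distances (with the usual corrections) followed by
neighbor-joining.  Likelihood and Bayesian engines are deliberately not
reimplemented — they plug in through :class:`EngineSpec` as external
commands that read an alignment and write a Newick tree.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .codon_tools import GeneAlignment, write_fasta
from .tree_metrics import leaf_labels, read_newick

__all__ = [
    "DistanceMatrix",
    "EngineSpec",
    "SATURATION_CAP",
    "pairwise_distances",
    "neighbor_joining",
    "infer_tree",
]

logger = logging.getLogger(__name__)

#: distance assigned to saturated pairs whose correction is undefined
SATURATION_CAP = 5.0

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class EngineSpec:
    """How trees are inferred: built-in NJ or an external command.

    External commands are templates with ``{alignment}`` and ``{outtree}``
    placeholders; the command must write a Newick tree on the input taxa.
    """

    kind: str = "builtin-nj"
    correction: str = "jc"
    command: str | None = None
    alignment_format: str = "fasta"

    def describe(self) -> str:
        if self.kind == "builtin-nj":
            return f"builtin-nj({self.correction})"
        return f"external({self.command})"


def _encode(aln: GeneAlignment) -> np.ndarray:
    index = _AA_INDEX if aln.alphabet == "protein" else _NUC_INDEX
    return np.array(
        [[index.get(ch, -1) for ch in seq] for _, seq in aln.rows], dtype=np.int8
    )


def _capped(value: float, pair: tuple[str, str], why: str) -> float:
    logger.warning("pair %s: %s; capping distance at %.1f", pair, why, SATURATION_CAP)
    return SATURATION_CAP


def pairwise_distances(aln: GeneAlignment, correction: str = "jc") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/ambiguous columns.

    Corrections: ``p`` (raw mismatch fraction), ``jc`` (Jukes-Cantor),
    ``k2p`` (Kimura two-parameter), ``poisson`` (protein), ``logdet``
    (Lockhart et al. transformation, robust to compositional bias).
    Saturated pairs whose correction is undefined are capped at
    ``SATURATION_CAP`` with a warning.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 sequences")
    if aln.alphabet == "protein" and correction not in ("p", "poisson"):
        raise ValueError(f"correction {correction!r} not defined for protein data")
    if aln.alphabet != "protein" and correction == "poisson":
        raise ValueError("poisson correction is for protein data")
    codes = _encode(aln)
    taxa = aln.taxa
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}")
            ai, bi = a[ok], b[ok]
            p = float((ai != bi).mean())
            pair = (taxa[i], taxa[j])
            if correction == "p":
                dist = p
            elif correction == "jc":
                dist = (
                    _capped(p, pair, f"p={p:.3f} >= 0.75 saturates Jukes-Cantor")
                    if p >= 0.75
                    else -0.75 * math.log1p(-4.0 * p / 3.0)
                )
            elif correction == "poisson":
                dist = _capped(p, pair, "p=1 saturates Poisson") if p >= 1.0 else -math.log1p(-p)
            elif correction == "k2p":
                transition = (((ai == 0) & (bi == 2)) | ((ai == 2) & (bi == 0))
                                           | ((ai == 1) & (bi == 3)) | ((ai == 3) & (bi == 1)))
                P = float(transition.mean())
                Q = p - P
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0 or w2 <= 0:
                    dist = _capped(p, pair, "saturated under K2P")
                else:
                    dist = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            elif correction == "logdet":
                F = np.zeros((4, 4))
                np.add.at(F, (ai, bi), 1.0)
                F /= m
                det = np.linalg.det(F)
                fa, fb = F.sum(axis=1), F.sum(axis=0)
                if det <= 0 or np.any(fa <= 0) or np.any(fb <= 0):
                    dist = _capped(p, pair, "singular divergence matrix under LogDet")
                else:
                    dist = -0.25 * (math.log(det) - 0.5 * (np.log(fa).sum() + np.log(fb).sum()))
                    dist = max(dist, 0.0)
            else:
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=list(taxa), d=d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou & Nei / Studier & Keppler) on a distance matrix.

    Additive matrices are recovered exactly (topology and branch lengths).
    Ties on the Q criterion break to the lowest index pair in taxon-sorted
    order; negative branch-length estimates are clamped to zero with the
    excess transferred to the sibling branch, preserving their sum.
    Returns an unrooted tree (trifurcating seed node) over the input taxa.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(n), key=lambda i: dm.taxa[i])
    taxa = [dm.taxa[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)

    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)

    active = list(range(len(taxa)))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = divmod(int(np.argmin(Q)), r)  # row-major argmin = lowest (i, j)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (R[ai] - R[aj]) / (2.0 * (r - 2))
        vj = dij - vi
        if vi < 0.0:
            vj += vi
            vi = 0.0
        if vj < 0.0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        # distances from the new node u to every other active node
        new_col = np.full(d.shape[0] + 1, 0.0)
        for k in active:
            if k in (i, j):
                continue
            new_col[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, :] = new_col
        d[:, u] = new_col
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # final three-point join
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    seed = dendropy.Node()
    for k, v in ((a, va), (b, vb), (c, vc)):
        seed.add_child(nodes[k])
        nodes[k].edge.length = max(v, 0.0)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def infer_tree(aln: GeneAlignment, engine: EngineSpec = EngineSpec()) -> dendropy.Tree:
    """Infer a tree from an alignment with the configured engine.

    The built-in path is pairwise distances + neighbor joining.  External
    engines get the alignment written to a temporary file, run their
    command, and must return a Newick tree on exactly the input taxa.
    """
    if engine.kind == "builtin-nj":
        return neighbor_joining(pairwise_distances(aln, engine.correction))
    if engine.kind != "external":
        raise ValueError(f"unknown engine kind {engine.kind!r}")
    if not engine.command:
        raise ValueError("external engine requires a command template")
    with tempfile.TemporaryDirectory() as tmp:
        aln_path = Path(tmp) / f"{aln.gene}.fasta"
        out_path = Path(tmp) / f"{aln.gene}.nwk"
        if engine.alignment_format == "fasta":
            write_fasta(aln_path, aln.rows)
        elif engine.alignment_format == "phylip":
            from .supermatrix import concatenate, write_phylip

            write_phylip(concatenate([aln]), aln_path)
        else:
            raise ValueError(f"unknown alignment format {engine.alignment_format!r}")
        cmd = engine.command.format(alignment=str(aln_path), outtree=str(out_path))
        result = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if result.returncode != 0:
            raise RuntimeError(
                f"engine command failed ({result.returncode}): {result.stderr.strip()}"
            )
        tree = read_newick(out_path)
    got, want = leaf_labels(tree), set(aln.taxa)
    if got != want:
        raise ValueError(
            f"engine output leaf set differs from input taxa "
            f"(missing {sorted(want - got)}, extra {sorted(got - want)})"
        )
    return tree
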