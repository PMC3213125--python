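"""Published reference values used as worked-example inputs.

Per-gene tree-concordance scores (branch-length scale factor and
Robinson-Foulds distance against the whole-mitogenome tree) reported for
the 13 protein-coding genes of a 17-taxon paraneopteran insect mitogenome
dataset.  These printed values serve as input to the gene-selection logic
and as the rate profile of the paper-like synthetic preset.
"""

from __future__ import annotations

from .tree_metrics import GeneScore

__all__ = ["PARANEOPTERA_GENE_SCORES", "FIVE_GENE_COMPARISONS"]

#: Published per-gene (scale factor, RF) scores, whole-mitogenome reference.
PARANEOPTERA_GENE_SCORES: dict[str, GeneScore] = {
    "nad1": GeneScore("nad1", rf=4, scale_factor=1.1089),
    "nad2": GeneScore("nad2", rf=5, scale_factor=0.7142),
    "nad3": GeneScore("nad3", rf=7, scale_factor=0.9596),
    "nad4": GeneScore("nad4", rf=6, scale_factor=0.9771),
    "nad5": GeneScore("nad5", rf=8, scale_factor=0.9095),
    "nad6": GeneScore("nad6", rf=8, scale_factor=0.7075),
    "nad4L": GeneScore("nad4L", rf=10, scale_factor=0.7822),
    "cox1": GeneScore("cox1", rf=2, scale_factor=2.0732),
    "cox2": GeneScore("cox2", rf=8, scale_factor=0.8565),
    "cox3": GeneScore("cox3", rf=8, scale_factor=1.1510),
    "atp6": GeneScore("atp6", rf=9, scale_factor=1.0279),
    "atp8": GeneScore("atp8", rf=11, scale_factor=0.6826),
    "cytb": GeneScore("cytb", rf=4, scale_factor=1.3414),
}

#: Published five-best-genes vs whole-genome comparisons per dataset
#: (scale factor, RF), with and without long-branch taxa.
FIVE_GENE_COMPARISONS: dict[str, tuple[float, int]] = {
    "Paraneoptera": (1.19471, 1),
    "Paraneoptera (long-branched taxa excluded)": (1.03562, 1),
    "Holometabola": (1.26578, 7),
    "Holometabola (long-branched taxa excluded)": (0.58196, 2),
    "Eumetabola": (0.79679, 13),
    "Eumetabola (long-branched taxa excluded)": (1.10733, 4),
}
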