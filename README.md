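# mitosignal

Tools for asking a practical question in mitochondrial phylogenomics: **how
much of the whole-mitogenome phylogenetic signal does each gene carry, and
can a small subset of genes replace the full genome?**

Insect mitogenomes (13 protein-coding genes, 22 tRNAs, 2 rRNAs, strongly
AT-biased) are a workhorse marker, but their genes differ widely in rate and
reliability, and fast-evolving lineages produce long-branch artefacts.
`mitosignal` implements the full assessment pipeline:

- **Codon-aware processing** — translation under the invertebrate
  mitochondrial code (NCBI table 5) and back-translation that transfers
  protein-alignment gaps onto unaligned DNA, so nucleotide alignments stay
  in frame.
- **Conserved-block filtering** — Gblocks-style column classification
  (nonconserved / conserved / highly conserved) and block selection, in
  residue or codon units, with the relaxed parameter set (IS=9, FS=13,
  CP=8, BL=10, gaps "with half") as default.
- **Supermatrix assembly** — concatenation with gap padding for missing
  genes, charset/partition bookkeeping, third-codon-position stripping,
  RY recoding, and parsimony-based site-rate binning.
- **Tree scoring** — each gene tree is compared to the whole-matrix
  reference tree by the Robinson–Foulds distance *RF* (number of
  bipartitions found in exactly one of the two unrooted trees) and the
  branch-length **scale factor**

  &nbsp;&nbsp;&nbsp;&nbsp;*K* = Σ *b*<sub>gene</sub>·*b*<sub>ref</sub> / Σ *b*<sub>ref</sub>²,

  the least-squares multiplier over matched branches (terminals matched by
  label, internal branches by bipartition); *K* > 1 means the gene evolves
  faster than the genome-wide average.
- **Gene selection and long-branch screening** — pick the *k* best genes by
  RF (topology) or |log *K*| (divergence), rebuild the subset tree, and
  compare it back to the reference; optionally remove taxa whose
  root-to-tip divergence exceeds a threshold (e.g. 0.5 substitutions/site)
  and repeat on the filtered data.
- **Built-in inference** — pairwise distances (p, Jukes–Cantor, K2P,
  LogDet, Poisson) and neighbor joining, so everything runs offline; any
  external engine that reads an alignment and writes Newick plugs in via a
  command template.
- **Synthetic data with known truth** — Yule trees, per-gene rate
  multipliers, accelerated lineages, AT-rich HKY/GTR simulation with
  optional gamma rate heterogeneity, and missing-gene masks, so every
  claim above is testable by parameter recovery.

## Worked example

Simulate a 17-taxon, 13-gene dataset shaped like a paraneopteran mitogenome
set (published relative-rate profile, 75% AT, one lineage accelerated
fourfold), then run the full assessment:

```python
import mitosignal as ms

cfg = ms.paper_like_config(seed=42)
alignments, truth = ms.make_dataset(cfg)
config = ms.AssessmentConfig(
    genes=tuple(alignments), k=5, outgroup="t01",
    long_branch_threshold=0.5, seed=42,
)
report = ms.run_assessment(config)
print(report.gene_table_tsv())
```

```
gene	scale_factor	rf
nad1	1.0153	4
nad2	0.6896	2
nad3	0.7974	6
nad4	0.9180	6
nad5	0.8916	6
nad6	0.6965	8
nad4L	0.7761	8
cox1	1.7320	6
cox2	0.8729	2
cox3	1.0741	4
atp6	0.9471	4
atp8	0.6499	8
cytb	1.2037	6
```

Each row scores one gene tree against the whole-matrix tree: `rf` counts
topological disagreements (0 = identical unrooted topology; on 17 taxa the
maximum is 28) and `scale_factor` is the gene's overall rate relative to
the concatenated matrix — compare the recovered `cox1` value 1.73 with its
simulated multiplier 2.07, measured through 14 inferred branches of noisy
data. The rest of the report:

```
>>> report.selected
['cox2', 'nad2', 'nad1', 'atp6', 'cox3']
>>> print(report.comparison_table_tsv())
dataset	scale_factor	rf
full	0.90400	2
long-branch taxa excluded	0.88546	2
>>> report.removed_taxa
[('t03', 0.5424346264964982)]
```

The five best-scoring genes concatenated reproduce the whole-matrix tree to
RF = 2 (out of a possible 28), and the root-to-tip screen at 0.5
substitutions/site flags exactly the lineage the generator accelerated
(`t03`, the ground truth in `truth.accelerated_taxa`).

The same pipeline runs from the shell on real per-gene FASTA alignments:

```bash
mitosignal backtranslate --prot cox1.faa --dna cox1.fna --code 5 -o cox1.codon.fna
mitosignal trim --in cox1.codon.fna --type dna-codon -o cox1.trim.fna
mitosignal assess --config run.yaml --outdir report/
```

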