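# Methods

## The assessment procedure

The pipeline treats the tree inferred from the concatenated matrix of all
genes as the best available estimate of the phylogeny and asks how well each
gene, and each small subset of genes, reproduces it. Per gene it reports
two complementary statistics:

- **Robinson–Foulds distance (RF).** Both trees are reduced to their sets
  of nontrivial bipartitions on the shared leaf set; RF is the size of the
  symmetric difference. It is a pure topology score: 0 means identical
  unrooted topologies, and the maximum for binary trees on *n* shared
  leaves is 2(*n*−3). Polytomies are handled by the same set definition,
  which is why odd values can occur when one tree is less resolved than
  the other.

- **Scale factor (K).** Branches are matched between the gene tree and the
  reference — terminal branches by leaf label, internal branches by
  identical bipartition — and K = Σ b_g·b_r / Σ b_r² is the least-squares
  solution of b_g ≈ K·b_r over the matched pairs. K > 1 means the gene
  accumulates substitutions faster than the genome-wide average.
  Unmatched branches are *excluded* from both sums: topological
  disagreement is already reported by RF, and folding it into K would
  conflate the two axes the method deliberately separates. Because some
  published K-score implementations penalize unmatched partitions inside
  the score, our K can deviate from theirs on topologically discordant
  trees; on concordant trees the definitions coincide. Zero-length
  branches participate in matching but contribute nothing to either sum.
  K is invariant to rerooting of either tree (the two root-adjacent edges
  of a rooted tree map to one unrooted split with summed length).

When leaf sets differ, both trees are restricted to the shared leaves.
This is implemented in split space — edges that become redundant after
restriction collapse onto the same split and their lengths are summed —
which is exactly equivalent to pruning with degree-2 suppression.

**Gene selection.** The k best genes are chosen by ascending RF (ties by
|log K|, then name) for topology, or ascending |log K| (ties by RF, then
name) for branch lengths. |log K| is symmetric in faster/slower, which is
the natural reading of "divergence closest to the whole matrix": K = 0.5
and K = 2 deviate equally. Applied to the published 13-gene score table
bundled in `mitosignal.published`, these criteria select
{cox1, nad1, cytb, nad2, nad4} and {nad1, nad3, nad4, nad5, atp6}
respectively.

**Long-branch screen.** Root-to-tip divergence is the sum of branch
lengths from the root to a leaf on the rooted tree. The root is placed at
the node where the designated outgroup attaches (midpoint rooting is the
fallback, with a logged notice — note that midpoint rooting *halves* the
apparent divergence of the single longest branch and is therefore a poor
choice for this screen). Taxa above the threshold (default 0.5
substitutions/site) are removed, and the filtered comparison re-infers all
trees from the filtered alignments rather than pruning existing trees, so
estimation feedback from the removed taxa is eliminated. By default the
filtered subset tree is compared against a filtered (re-inferred)
reference; comparing against the unfiltered reference is a config switch
(`filtered_reference=False`). The configured outgroup is never removed.

## Alignment processing

**Back-translation.** Coding genes are aligned at the protein level;
`transfer_gaps` maps each protein gap column to `---` and each residue
column to the taxon's next codon, so the output is exactly 3× the protein
alignment length and degaps back to the input DNA. Trailing incomplete
codons (truncated stop codons are common in mitogenomes) are trimmed with
a warning; a trailing stop codon present in the DNA but not the protein
row is dropped silently; internal stops translate to `*` with a warning
rather than an error, leaving removal to column filtering. Ambiguous
codons translate to `X`, and `X` masks mismatches during the consistency
check. Taxon labels are opaque strings end to end.

**Block filtering.** Columns are classified from the count m of their most
frequent unambiguous residue: nonconserved if m < IS, highly conserved if
m ≥ FS, conserved otherwise; under the `with_half` gap mode a column whose
gap count exceeds half the sequences is nonconserved outright, and
ambiguity codes count as gaps (conservative and deterministic).
Conservation is strict identity — no amino-acid similarity groups — which
can retain slightly different column sets than implementations that use
them. Block selection then (1) rejects nonconserved runs longer than CP,
(2) takes the remaining segments, (3) trims each to its outermost highly
conserved positions, (4) drops blocks shorter than BL, (5) returns the
union. In codon mode a triplet's class is the worst of its three columns
and all coordinates are expanded ×3, so the reading frame survives
filtering. Defaults are the relaxed set IS=9, FS=13, CP=8, BL=10,
gaps=with-half. The implementation is checked against an independent
direct-scan reference on random class strings; byte-parity with any
particular legacy binary is not claimed.

**Supermatrix.** Rows are keyed by taxon label, so concatenation is
invariant to per-gene row order; taxa missing a gene are padded with `-`
(switchable to `?`). Charsets are 0-based half-open internally and 1-based
inclusive in NEXUS output. Third-position stripping applies only to
protein-coding charsets and requires frame-intact lengths. Site-rate
binning uses the minimum-substitution count on a guide tree
(Fitch/Hartigan parsimony, exact for polytomous trees; gaps and
ambiguities are missing data) as the rate proxy, splits columns at score
quantiles into k categories with category 1 fastest, breaks ties toward
the faster bin, and forces constant columns into the slowest bin.
Parsimony scores are a deterministic, dependency-free proxy for
likelihood-based site rates; they are monotone in the true rate on
simulations but coarser, especially for slow sites.

## Inference

The built-in engine is pairwise distances plus neighbor joining —
deliberately modest, deterministic, and fast, so the whole assessment runs
offline; Bayesian and likelihood engines attach through a command-template
adapter and their output is validated for leaf-set equality. Distances
use pairwise deletion (columns with a gap or ambiguity in either sequence
are skipped for that pair). Corrections: p, Jukes–Cantor
(d = −¾ ln(1−4p/3)), Kimura two-parameter, LogDet (robust to
compositional drift), and Poisson for proteins. Saturated pairs whose
correction is undefined (e.g. p ≥ 0.75 under JC) are capped at 5.0
substitutions/site with a warning — the matrix stays finite and the
saturation is flagged. NJ breaks Q-criterion ties toward the lowest index
pair in taxon-sorted order for run-to-run determinism, and clamps negative
branch estimates to zero, transferring the excess to the sibling branch so
their sum (which is what the data constrain) is preserved. Additive
matrices are recovered exactly.

## The synthetic-data generator

`make_dataset` emulates the structure of a real multi-gene mitogenome
dataset on a known truth:

- **Tree.** A pure-birth (Yule) tree, which is ultrametric; branch lengths
  are rescaled so the root-to-tip path equals the configured depth
  *exactly* (default 0.2 substitutions/site). Fixed Newick input is
  accepted instead.
- **Genes.** Each gene g has a length and a rate multiplier k_g; its
  effective tree is the true tree scaled by k_g, with lineage
  accelerations applied on top. The preset profile uses typical insect
  mitochondrial gene lengths and a published relative-rate profile.
- **Accelerated lineages.** An acceleration multiplies every branch from
  the MRCA of the named taxa to those tips (the terminal branch alone for
  a single taxon). When no taxon is named, the generator emulates an
  anciently diverged, persistently fast lineage — the pattern behind real
  long-branch artefacts in parasitic insect groups: it picks the tip with
  the longest terminal branch and redraws the Yule split times until that
  branch spans at least 70% of the depth. This conditioning is what makes
  the screen guarantee sharp: at depth 0.2 and factor 5 the accelerated
  tip's true divergence is at least 0.2 + 4·(0.7·0.2) = 0.76, while every
  background tip sits at exactly 0.2, so the 0.5 threshold separates them
  with margin to spare even after distance-estimation shrinkage. Without
  the conditioning, roughly 9% of Yule(10) trees have no terminal branch
  long enough for a ×5 tip to cross 0.5 at all.
- **Sequences.** Nucleotide simulation under JC, HKY (default κ = 4) or
  GTR, with equilibrium frequencies defaulting to the AT-rich composition
  typical of insect mitogenomes (A 0.40, C 0.15, G 0.10, T 0.35; AT =
  0.75). The root sequence is drawn from equilibrium; per-site Gamma(α)
  rate multipliers are optional and off by default (α = None means
  rate-homogeneous sites). Transition probabilities come from the
  symmetric similarity transform of the reversible rate matrix
  (eigendecomposition, verified against the matrix exponential), sampled
  site-by-site. Coding genes avoid in-frame stop codons by rejection at
  the root and codon-level redraws after each branch (reverting to the
  parent codon if rejection fails) so simulated genes stay translatable;
  amino-acid matrices are obtained by translating the simulated codons
  rather than by a codon or amino-acid model — adequate for pipeline
  testing, not for studying protein-level site heterogeneity. RNA genes
  are simulated as plain nucleotide partitions without structural pairing.
- **Missing data.** A (taxon, gene) mask removes rows before
  concatenation pads them with gaps.
- **Determinism.** One integer seeds a NumPy `SeedSequence`; the tree and
  each gene get spawned child streams (PCG64), so datasets are
  byte-identical across platforms and insertion order cannot leak into
  the randomness.

What the generator does *not* emulate — heterotachy, site-heterogeneous
amino-acid profiles, structural RNA alignment, gene rearrangement,
sequencing error — bounds what passing tests show: they validate the
statistics and the pipeline mechanics, not robustness to every real-data
pathology.

## Validation studies (`mitosignal.studies`)

Problem sizes are chosen so each study runs in seconds to a few minutes on
a single core.

- **Multiplier recovery.** 20 replicates of 13 equal-length (5 kb) genes
  on 10 taxa at depth 0.2: probe genes at k ∈ {0.5, 1, 2} plus background
  genes at 0.95 so the length-weighted mean multiplier is exactly 1 — the
  whole-matrix reference is then on the true tree's scale and the expected
  scale factor of each probe equals its multiplier. Mean recovered values
  land within a few percent of truth. A known residual bias: the JC
  correction under AT-rich HKY data under-corrects long distances more
  than short ones, compressing the recovered K range slightly toward 1
  (fast genes read a little slow, slow genes a little fast). The study
  reports mean absolute error so the effect is visible rather than hidden.
- **Long-branch screen.** 20 replicates, 13 genes, one auto-selected
  lineage at ×5, screen threshold 0.5 with a background outgroup;
  expected outcome is removal in every replicate with zero false
  removals.
- **Five-gene adequacy.** 20 replicates of the 17-taxon preset (no
  acceleration — the study isolates subset adequacy from long-branch
  effects): count replicates where the top-5-by-RF concatenated tree is
  at least as close to the whole-matrix tree as the median single gene.
- **NJ additive recovery.** 200 random trees (4–10 taxa), exact
  path-length matrices, NJ must return RF = 0.

All study seeds derive from one base seed via `SeedSequence`, so
`scripts/acceptance.py --seed N` is fully reproducible.

## Numerical and degenerate-input conventions

- Distances: pairs with zero comparable columns are an error; saturated
  corrections cap at 5.0 with a warning.
- RF and K require ≥ 4 shared leaves; K additionally requires at least one
  matched branch and a nonzero reference sum.
- `bipartitions` of a tree with < 4 leaves is the empty set; a star tree
  has none.
- Quantile ties in rate binning go to the faster category; constant
  columns always land in the slowest.
- Branch lengths read as `None` are treated as 0 in comparisons.
- Newick output uses 10 significant digits and preserves underscores in
  labels verbatim.

## Known limitations

- The built-in engine is distance-based; on short genes its trees are
  noisier than Bayesian/ML trees, so absolute RF values depend on the
  engine (the report records which engine produced them). External
  engines restore full generality through the adapter.
- Scale factors inherit the distance correction's biases (see multiplier
  recovery above); with an external ML engine this compression largely
  disappears.
- Block filtering uses identity-based conservation, not similarity
  groups.
- The parsimony rate proxy is coarse for slow sites and saturates for
  very fast ones.
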