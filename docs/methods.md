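# Methods

## The problem and the model

Three lineages (L1, L2, L3) that radiated in quick succession, plus an
outgroup used for rooting and allele polarization. The species tree is
((L1,L2),L3) with an internal branch of length *t* in coalescent units
(1 unit = 2N generations). Under the multispecies coalescent (MSC), a gene
lineage pair entering that branch fails to coalesce within it with
probability e^(−t), in which case all three resolutions of the gene tree
backbone are equally likely. Hence the class probabilities

* P(Tree1) = 1 − (2/3)e^(−t)  (concordant with the species tree),
* P(Tree2) = P(Tree3) = (1/3)e^(−t)  (the two discordant classes).

Everything in the package flows from two consequences of this model:

1. **Equal minor frequencies.** ILS alone cannot make one discordant
   topology more common than the other. The quartet test conditions on the
   minor counts (m₁, m₂) and tests symmetry with
   X² = (m₁ − m₂)² / (m₁ + m₂) against χ² with 1 df (or an exact binomial
   at p = ½). Directional processes — introgression, horizontal transfer —
   break the symmetry.
2. **Equal ABBA/BABA expectations.** At outgroup-polarized biallelic
   sites, ILS produces the two discordant allele-sharing patterns at equal
   rates; a pulse of gene flow between non-sister lineages inflates one of
   them, detected by D = (ABBA − BABA)/(ABBA + BABA) with a
   block-jackknife Z.

## Procedure

The pipeline mirrors the staged accounting used in genome-scale
discordance studies: (i) drop genes whose two inference strategies
disagree on the unrooted topology (RF distance > 0); (ii) drop genes whose
internal-node bootstrap summary falls below a threshold; (iii) classify
the remainder; (iv) quantify conflict (gCF, RF/MDS); (v) test the ILS
null per quartet; (vi) test for introgression with D; (vii) compare
branch-length statistics across classes. The identity
`input = removed_inconsistent + removed_low_support + retained` is checked
on every run.

### Classification rules

The tree is rerooted on the outgroup leaf before anything else; monophyly
and sisterhood are judged on the rerooted tree, so the placement of the
root in the input file is irrelevant. A gene is Unclassified if any
lineage with ≥ 2 taxa is non-monophyletic, or if the three lineage
ancestors form a polytomy (no sister pair exists; the divergence segment
is then undefined). Classification ignores branch lengths and child order.

### Divergence segment (node1 → node2)

node1 is the MRCA of all ingroup taxa; node2 the MRCA of the two sister
lineages. The statistic is the path sum between them, which is a single
internal branch on a binary tree but remains defined through intermediate
nodes. Longer-than-species-tree segments in the discordant classes are the
classic branch-length signature of ILS; the package reports group means,
95% CIs and two-sided Welch t-tests without asserting a direction.

### Choices where the procedure is genuinely open

* **Support filter statistic**: "bootstrap support below 80%" does not say
  whether mean, median or minimum is summarized; the default is the mean
  over internal nodes (root excluded), configurable, with the boundary
  kept (≥ threshold passes).
* **Evolutionary rate**: defined here as total tree length divided by leaf
  count (configurable to total length only); a pure branch-length proxy
  that scales linearly under rate scaling.
* **Quartet test inputs**: defaults to the discordant gene trees only
  (flag `quartet_trees: all` uses every retained tree); no multiple-testing
  correction across quartets by default, since per-quartet verdicts at a
  fixed small α (10⁻⁴ by default) are the object of interest.
* **Tie for the major topology**: every admissible major choice is
  evaluated and the largest p reported — conservative toward the null.
* **gCF denominator**: decisive gene trees only. A gene tree is decisive
  for a branch if both sides of the branch's bipartition retain ≥ 2 of the
  tree's taxa; with complete gene trees every tree is decisive. Highlight
  is strict `gcf > 60`.
* **MDS**: classical (Torgerson) scaling — double-center the squared
  distances, eigendecompose, scale eigenvectors by √eigenvalue. RF
  distances are non-Euclidean, so negative eigenvalues occur; those axes
  are dropped (and reported in the eigenvalue vector). Sign convention:
  each axis's largest-magnitude loading is made positive, making output
  deterministic. A non-metric MDS would be a defensible alternative; the
  classical form was chosen for its closed form and testability.
* **D-statistic counting** is frequency-weighted, ABBA = (1−p₁)p₂p₃,
  BABA = p₁(1−p₂)p₃, reducing to indicator patterns with one sequence per
  population. Sites with a polymorphic or missing outgroup, or more than
  two alleles, are discarded. Jackknife: 50 contiguous equal blocks of
  alignment columns by default; fewer blocks (min 2) when informative
  sites are scarce; SE = 0 leaves Z undefined and flagged rather than
  infinite.

## The simulator

`simulate_gene_trees` draws genealogies branch by branch: within each
species-tree population, k lineages coalesce pairwise at rate k(k−1)/2,
truncated at the branch end; survivors pass rootward. Introgression is a
per-gene *pulse*: with probability γ the recipient lineage's ancestral
lineages are relocated into the donor population at the pulse time — the
hybrid-edge abstraction, which keeps the closed-form class probabilities
available for the unpulsed fraction. The truth table (backbone class,
pulse indicator, internal-segment times) is recorded from the coalescent
merge events themselves, not by re-running the classifier, so
truth-vs-classifier agreement is a meaningful test.

Defaults (coalescent units): lineage depth 3.0 (L1/L2 split), internal
branch 1.0, outgroup join 2.0 above the ingroup root. The depths are deep
enough that within-lineage non-monophyly is rare at the defaults but
rises as `lineage_depth` shrinks — a knob the tests use. Supports are
drawn with a logistic dependence on the subtending branch length
(midpoint 0.1 units, scale 0.05, Gaussian noise SD 8, clipped to
[0, 100]): long branches get supports near 100, short ones diffuse
values, exercising the support filter. Strategy-B trees are copies of
strategy-A trees with one random NNI applied to a configured fraction of
genes (default 2%, echoing the ~2% cross-strategy inconsistency rate such
pipelines observe); NNI moves are enumerated on internal edges of the
unrooted topology, so a perturbed gene is always genuinely inconsistent.

`simulate_site_patterns` draws an independent four-taxon genealogy per
site (fully vectorized over sites) and places exactly one mutation
uniformly along the total branch length, yielding a biallelic column.
Site-tree times default to splits at 1.0 / 2.0 / 3.0 coalescent units.
This isolates exactly what the D-statistic consumes; it deliberately
omits substitution-model realism (multiple hits, rate variation,
invariant sites), linkage between sites, and within-population sampling —
so passing tests demonstrate correctness of the statistic and its
calibration under the coalescent, not robustness to alignment error or
model misspecification in real data.

Fixture presets: `mini-ntf` (3+3+2 ingroup taxa + outgroup, 200 genes,
t = 0.5, 3% NNI noise, 20k sites) sized to run the full pipeline in
seconds; `null-ils` and `introgression` (γ = 0.3, L3→L2) for calibration
and power checks.

## Numerical and degenerate-input conventions

* Branch lengths serialize with up to 10 significant digits; round-trips
  are exact to that precision.
* Polytomies are legal everywhere and simply contribute fewer
  bipartitions; trees with < 4 leaves have an empty split set and RF 0.
* A quartet whose restriction is a star supports no topology and is
  tallied separately; a quartet with zero counted trees is
  "undetermined".
* Zero ABBA+BABA leaves D undefined and flagged; m₁ + m₂ = 0 gives p = 1
  (no evidence against the null).
* Simulated genealogies are ultrametric in coalescent units to < 1e−9
  from tips of equal depth.

## Problem sizes used in validation

The statistical checks run at: 10,000 genes per internal-branch value for
closed-form agreement and parameter recovery (t ∈ {0.25, 0.5, 1, 2});
500 replicate quartet sets of 300 trees for type-I calibration at
α = 0.05; 200 replicates of 50,000 sites for D-statistic calibration and
power. Binomial tolerances are 3 standard errors; the type-I band is
5% ± 2%.

## Known limitations

* One outgroup taxon is the fully supported configuration; several OUT
  taxa are accepted but must be monophyletic after rooting on the first.
* The introgression pulse moves the whole recipient lineage per gene; it
  does not model continuous migration or partial-locus transfer.
* The equal-minor-frequencies test uses topology counts only; variants
  that also exploit branch lengths can have more power but need rate
  assumptions this package does not make.
* gCF is gene concordance only; site concordance factors are out of
  scope, as are tree inference, alignment, and network estimation.
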