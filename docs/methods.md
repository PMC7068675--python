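# Methods

## Motif model

The unit of analysis is the lncRNA-mediated feedforward loop: a directed
three-node motif in which a gene regulates an miRNA (`gene-miRNA` layer) and
an lncRNA (`gene-lncRNA`), while the miRNA also regulates the lncRNA
(`miRNA-lncRNA`).  A triplet (g, m, l) is an FFL iff all three typed edges
exist; evidence multiplicity is collapsed to unweighted edges.  Node types
are inferred from edge layers, and an identifier used in contradictory
positions is rejected as an input error rather than silently resolved.
Identifier matching is case-insensitive after whitespace trimming (public
symbol tables mix capitalisations of the same symbol, and silent case
mismatches would drop motifs); the first-seen casing is preserved in output.
Enumeration is indexed by the gene's two adjacency sets and intersected with
the miRNA's targets, which is exactly equivalent to the cubic triple loop
(asserted against it in the tests) but linear in practice.

Network topology (degree distribution, power-law fit) is computed on the
undirected simple projection, since the motif's degree structure is usually
reported without direction.  The scale-free fit is ordinary least squares of
log10 n_k on log10 k; when the log counts have zero variance the R² is
reported as 0 by convention (the fit carries no information).

## Dysregulation scoring

Two composite scores are computed per FFL against a case/control bundle of
three feature × sample matrices sharing one ordered sample set:

* `CS_dif = P_gene · P_miRNA · P_lncRNA`, the product of two-sided
  equal-variance Student t-test p-values.  Welch's correction is available
  (`equal_var=False`) but is not the default, because the target statistic
  is the classic Student test.  A molecule with zero pooled variance gives
  p = 1 (no evidence of a difference, and no crash on degenerate input).
* `CS_PCC`, the absolute product of the three case-minus-control Pearson
  correlation differences.  Correlations are computed within one group at a
  time; a correlation involving a zero-variance vector is undefined and
  mapped to 0 with a warning.  CS_PCC ranges over [0, 8], reaching 8 only
  for full sign flips on all three edges.

Both scores are turned into ranks — CS_dif ascending, CS_PCC descending, so
rank 1 is always "most dysregulated"; ties take fractional (average) ranks,
which conserves the rank sum — and the final score is their arithmetic mean.
Mean-of-ranks was chosen over rank-of-weighted-scores as the reading of
"equal-weighted ranking"; it is scale-free in both components, which matters
because CS_dif spans many orders of magnitude while CS_PCC is bounded.

### Permutation null

Significance is assessed by permuting the sample labels.  One permutation
per iteration is shared by the gene, miRNA and lncRNA matrices: the samples
are the same subjects in all three layers, and permuting layers
independently would destroy the cross-layer correlation structure that
CS_PCC measures, producing an invalid (too-easy) null.  Label permutation
preserves group sizes by construction.  The entire pipeline — t-tests,
correlations, composites, ranking — is recomputed per iteration, and the
per-FFL empirical p-value uses the add-one estimator
p = (1 + #{b : final_b ≤ final_obs}) / (B + 1), which cannot return 0 and is
conservative at the resolution 1/(B+1).  At least 100 permutations are
required (coarser resolution is meaningless at α = 0.05); the reference
configuration uses B = 1000.  No multiple-testing correction is applied to
the permutation p-values by default — the dysregulation call is
α = 0.05 on the raw empirical p — since the statistic is a screening rank;
a Benjamini–Hochberg column can be added trivially by the caller from the
output table.

The scoring engine is vectorised (row-standardised matrices and a
closed-form pooled-variance t), making one permutation O(features × samples
+ FFLs × samples); a test asserts exact (1e-12) agreement between this path
and a per-FFL scipy `ttest_ind`/`pearsonr` implementation, which serves as
the independent oracle.

### Correlation-transition patterns

Each motif edge is labelled with its control→case correlation state
transition, with states negative (r ≤ −τ), none (|r| < τ), positive
(r ≥ τ).  τ defaults to 0.3 — a conventional "weak correlation" boundary;
"no correlation" is inherently a judgment call at n = 8 per group, so τ is
configurable and the labels are descriptive, not inferential.

## Gene sets, modules, drugs

Gene-set membership is decided on the gene vertex only; miRNA/lncRNA
identifiers are never tested against gene lists.  Subnetwork extraction
keeps exactly the FFLs whose gene is in the set, plus their motif edges; it
is idempotent and monotone in the set.  Dysregulated-set comparisons are
exact Venn partitions on full triplet identity.

The key module is the maximum-degree node plus all neighbours and induced
edges; degree ties break to the lexicographically smallest identifier and
all tied hubs are logged.  Core modules use a greedy cohesiveness
clustering in the style of ClusterONE: every unvisited node (lexicographic
order) seeds a set S grown by the single add/remove move that maximises
f(S) = w_in / (w_in + w_bound + penalty·|S|) until no move improves it;
clusters with Jaccard overlap ≥ 0.8 merge and clusters under 4 nodes are
dropped.  Penalty 2, minimum size 4 and merge threshold 0.8 mirror the
published defaults of the original tool; this is a re-implementation, so
bit-identity with the Cytoscape plugin is not claimed — on planted dense
blocks (3 blocks of 10 nodes, within-p 0.8, between-p 0.05) it recovers the
blocks with Jaccard 1.0 in the tests.

Complex modules merge FFLs with ceRNA triplets (a gene and an lncRNA
competing for one miRNA; supplied as input, not inferred from expression).
An FFL and a ceRNA merge when they share ≥ 2 molecules; merged components
are connected components of the FFL↔ceRNA share graph, so chains merge
transitively.  Because triplets have three nodes, `min_shared ≥ 4` can never
merge — asserted as a property.

The drug overlay joins drug→gene and drug→miRNA association rows onto the
dysregulated FFLs; lncRNAs are never drug-joined, and a drug enters the
bipartite network only with at least one hit (no orphan drug nodes).
Category labels (e.g. "hormonal", "anti-inflammatory") are input data; the
category fraction is |drugs with ≥1 category of interest| / |network drugs|
and is invariant to duplicated association rows.

## Synthetic data

The generator emulates the motivating study design: n = 8 + 8 matched
case/control samples measured in all three layers, continuous
(post-normalisation) expression values, within-triplet co-expression that
can differ between groups.  Each triplet draws from a trivariate Gaussian
whose correlation matrix carries per-edge targets, factored by
eigendecomposition (so exactly singular targets like r = ±1 are legal;
genuinely infeasible targets — a non-PSD implied matrix — raise an error
naming the triplet).  Planted dysregulated triplets get case-group mean
shifts in units of the noise SD (default 2.0 per molecule) and rewired
case correlations.  Baseline level 10 and SD 1 put values on a
log-like expression scale; non-planted triplets use equicorrelated ρ = 0.3
in both groups — a realistic weak co-expression background for molecules
that interact.

**Planted rewiring default.** The nominal rewiring "0.8 → −0.8 per edge" is
jointly infeasible: a 3×3 correlation matrix with all off-diagonals −0.8 is
not positive semidefinite, and with two edges at −0.8 the third must exceed
≈ 0.28.  The default planted effect therefore flips the lncRNA's two edges
fully (0.8 → −0.8) and weakens the gene–miRNA edge to 0.35, just inside the
PSD boundary.  All three per-edge correlation differences are then
non-zero (≈1.6, 1.6, 0.45), giving CS_PCC its full three-factor signal.

Scoring scenarios use node-disjoint triplet networks (one motif per
triplet), which keeps per-triplet correlation targets exact; for shared
molecules in arbitrary networks the first (lexicographic) triplet's draw
wins, with a warning.  What the generator does **not** model: read-count
noise, library-size or batch effects, covariate structure (the matched
design's BMI/age pairing), or correlation between different triplets.
Passing tests therefore demonstrate the statistic's calibration and power
under its own model assumptions, not performance on raw RNA-seq.

The fixture scenarios are `null` (200 triplets, no signal), `planted`
(10 planted among 200) and `paper-shaped` (30 planted among 200, with two
overlapping gene sets arranged so the planted dysregulated selections have
sizes 11 and 29 sharing 10; 11 ceRNA triplets each sharing gene+miRNA with
a planted FFL; 29 drugs of which 21 carry the categories of interest).
Everything is reproducible by seed via numpy's PCG64 generator, and
identical seeds give byte-identical files.

## Problem sizes and numerical choices

Reference runs use 200 FFLs × 16 samples with B = 500–1000 permutations;
one permutation of the vectorised engine costs ~1 ms, so the full
acceptance battery (including a 20-replicate power study at B = 1000)
completes in well under a minute on one CPU.  Score tables are written with
`%.12g` floats, which, with deterministic lexicographic ordering
everywhere, makes reruns byte-identical.  Calibration was verified as:
under a global null the per-FFL permutation p-values pass a KS uniformity
test and flag ≈ 5% at α = 0.05; with the default planted effect ≥ 90% of
planted triplets land in the top-10 by final score (both recomputed by
`scripts/acceptance.py` and the test suite, not quoted from anywhere).

## Known limitations

* The unpaired Student t-test ignores the matched structure of the
  motivating design; covariate adjustment and paired tests are out of scope.
* Permutation p-values of rank-based statistics are cross-FFL dependent
  (ranks are relative), so the uniformity check treats them as approximately
  independent; at 200 FFLs the dependence is mild.
* ceRNA triplets are consumed, not discovered.
* Input matrices are taken as already normalised; only an optional
  log2(x+1) convenience transform is offered.
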