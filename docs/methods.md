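# Methods

This note documents the statistical procedures `ricetf` implements, the
parameters that matter, the synthetic data used to test them, and the places
where the design was genuinely open.

## Input model

All stages consume normalized expression tables: linear or log2 intensities
for anatomy samples, signed log2 fold-changes for stress/hormone contrasts.
Upstream normalization (MAS5 for Affymetrix arrays, DESeq2 for RNA-Seq
counts) is out of scope; the package validates, reshapes and analyzes.
Probe-level tables are collapsed to loci by keeping, per locus, the unique
probe with the highest mean expression across all samples (ties broken by
the lexicographically smaller probe id, for determinism); loci with only
non-unique probes are excluded and reported — they cannot be measured
unambiguously and are also removed from the dominance denominator below.

## Tissue specificity

The Tau index of a non-negative per-tissue profile x₁…x_n is
τ = Σᵢ (1 − xᵢ/x_max) / (n − 1): 0 for a uniform profile, 1 for expression
confined to one tissue, scale- and permutation-invariant.  Defaults:
τ < 0.15 → ubiquitous; τ > 0.6 → tissue-preferential candidate.  The high
cutoff is deliberately permissive because related tissues (leaf vs flag
leaf, seed vs endosperm) depress single-gene scores; candidates are then
refined by K-means (Lloyd's algorithm, Euclidean distance, k = 5 tissue
classes by default, 10 restarts, fixed seed 7) on profiles normalized to
min 0 / max 1, and each cluster is labeled by the tissue at which its
centroid peaks.  Runs are bit-reproducible for a fixed seed.

**Handling of negative log2 values.** Tau requires non-negative input, so a
profile whose minimum is negative is shifted to minimum 0 before scoring.
The shift is applied *only* in that case: because Tau is scale-invariant,
unconditionally anchoring every profile at 0 would erase its absolute level
and score flat noise as specific (min-shifted pure noise scores τ ≈ 0.7
regardless of the noise magnitude), flooding the candidate screen with
false positives.  Conditional shifting keeps flat expressed profiles near
τ ≈ 0 while still admitting fold-change-like inputs.

**Sprent-style rescue.** As an alternative screen for two (or three)
correlated tissues, the package fits the major axis — the first principal
axis through the centroid — of the per-gene (tissue A, tissue B) scatter of
log2 means, takes each gene's signed perpendicular residual, standardizes
by the residual standard deviation, and flags genes with two-sided
normal-theory p < α (default 0.05); the residual sign gives the direction
(toward A or toward B).  The underlying parametric outlier method is not
specified to the formula level in the literature we follow, so this
realization is isolated behind `sprent_outliers` and can be swapped without
touching the rest of the pipeline.  For three tissues, apply the pairwise
test to each pair involving the focal tissue.  Final labels combine the
screens with precedence ubiquitous (Tau) → K-means-refined preferential →
Sprent-rescued preferential → unclassified, with provenance recorded.

## Stress-response calling

Log2 fold-changes of experiments profiling the same condition are combined
by arithmetic mean (median would be more robust but means keep the combined
value interpretable as the average contrast; replicate vectors are retained
for testing).  Per gene and condition, a one-sample Student t-test against
0 is evaluated on the tail matching the sign of the observed mean;
responsive requires that one-tailed p < α = 0.05 *and* |mean log2FC| > 1
(two-fold).  The fold-change cutoff is a separate filter rather than a
shifted null (μ₀ = 1), which is the simpler conjunction of the two printed
criteria; the threshold is configurable (e.g. 2.0 for a stricter four-fold
screen).  Raw p-values are the default — the procedure this reproduces used
no multiple-testing correction — with optional Benjamini–Hochberg within
condition.  Zero-variance genes are reported untestable, never silently
dropped.  Repressed genes are called symmetrically on the lower tail.  The
one-tailed test's size is checked empirically: under a pure-noise generator
(10 000 genes, 4 replicates, σ = 0.5) the induced-side significance rate at
α = 0.05 must land in [0.04, 0.06].

## Closest paralogs

Family trees arrive as newick (maximum-likelihood trees built upstream);
edges without a branch length default to 1.0, degrading gracefully to
topological distance on cladograms.  A gene's closest paralog is the leaf at
minimum patristic distance (path sum), ties broken lexicographically.  A
gene alone in its tree is a singleton.  The biological notion "no close
paralog in a subclade" has no universal algorithmic definition, so the
packaged fixture encodes singleton status explicitly (one-leaf trees), and
an optional `max_distance` cap lets users impose a distance-based singleton
rule on their own trees.

## Functional dominance

For each analyzable pair the Pearson correlation of the two genes'
anatomical meta-expression profiles is computed; r < 0.5 (strict) calls the
characterized member predominant, r ≥ 0.5 potentially redundant.  The
summary over a characterized set removes no-probe records from the
denominator, counts singleton-clade genes as predominant (no partner to be
redundant with), bins pair correlations over the right-closed bins
[−0.25,0], (0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1], and reports the
predominant percentage rounded to one decimal.  Right-closed binning keeps
0.5 in the third bin so the sub-0.5 (predominant) mass is exactly the first
three bins.  The summary's internal identities (selected = singleton +
no-probe + tested; predominant total = singleton + paired predominant;
percentage = 100 × total / (selected − no-probe)) are enforced as
assertions on every construction.

## Co-expression networks

Neighbors of a query gene are all genes with Pearson r strictly above 0.75,
truncated to the 50 highest (both configurable); ties at the boundary are
ordered lexicographically before the cut, for determinism.  The network is
query-centered (a star); neighbor–neighbor co-expression edges are not
added by default.  Term over-representation uses the one-sided
hypergeometric upper tail P(X ≥ k) against the annotated background — the
procedure this follows asserts over-representation without naming a test,
and the hypergeometric is the standard choice for draw-without-replacement
term counts.  Protein-interaction overlays add edges only between existing
network nodes.

## Synthetic data

The generators emulate the statistical structure of meta-expression data,
not its platform artifacts (no probe cross-hybridization, batch effects, or
heteroskedastic array noise — results on synthetic data bound correctness
of the algorithms, not performance on real compendia):

* **Expression matrices** — default 1000 genes over 5 anatomy groups
  (vegetative, root, SAM/panicle, anther/pollen, seed) × 3 replicates,
  background at 4.0 log2 units with σ = 0.5; planted tissue-specific genes
  are silent (≈0) outside one tissue and at effect 8 inside it — the
  one-hot pattern of a truly tissue-restricted transcript, which gives
  τ = 1 exactly at zero noise; planted ubiquitous genes sit flat at 8.0.
* **Exact-correlation pairs** — y = r·u + √(1−r²)·w with u the centered,
  normalized first vector and w an independent residual orthogonalized
  against it, so the *empirical* correlation equals the target to ≤ 1e-9
  (verified over 100 random targets), not merely in expectation.
* **Fold-change blocks** — null genes N(0, σ), responsive genes
  N(effect, σ) with effect 3.0 and σ 0.2–0.5; at those settings ≥ 95% of
  planted genes must be recovered at default thresholds.
* **Characterized fixture** — 92 records (39 singletons, 14 no-probe, 39
  pairs) shipped as versioned TSV + newick under `ricetf/data/`; pair
  target correlations sit at the three reference values (−0.09, 0.24,
  0.92) plus bin midpoints (−0.125, 0.125, 0.375, 0.625, 0.875 — any
  in-bin value yields the same accounting; midpoints are canonical),
  giving the 4/11/11/10/3 histogram.  Expression vectors (40 samples) are
  synthesized at load time from the exact-correlation construction, and
  each record's correlation is *measured* from the vectors.  All locus
  ids except the named reference genes are synthetic placeholders.

All generators are bit-reproducible from an explicit seed and use one local
`numpy.random.Generator` per call.

## Numerical choices and degenerate inputs

Tau rejects all-zero and negative profiles; Pearson and the t-test reject
zero variance (batch paths report `untestable` instead); the Sprent test
rejects exactly collinear scatters (residual sd below 1e-10 of the data
scale); histogram binning rejects out-of-range values naming the offender;
table readers reject missing samples, non-numeric cells and duplicate row
ids with coordinates.  K-means uses scikit-learn's Lloyd implementation;
the t-test and hypergeometric tail use scipy; both are cross-checked in the
test suite against independently hand-coded formula evaluations, and
closest-paralog search against construction-time distances on random trees.

## Problem sizes

Tests and the acceptance script run at desk scale: 300–1000-gene matrices,
10 000 genes for the type-I-error simulation, 281-gene matrices for the
co-expression truncation experiment, trees of ≤ 13 leaves for the
brute-force comparisons.  Genome-scale featured-group counts (hundreds of
tissue-preferential or stress-responsive genes) depend on the public
meta-expression compendia and are deliberately outside the test surface.

## Known limitations

* The Sprent-style screen is a documented realization of a parametric
  outlier idea, not a reference implementation of the original method.
* Dominance calls are expression-collinearity statements; they suggest, but
  cannot establish, functional redundancy or dominance.
* The pipeline accepts normalized matrices as given; cross-platform batch
  effects must be handled upstream.
* Singleton status on user trees is only as good as the family assignment
  and the optional distance cap.
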