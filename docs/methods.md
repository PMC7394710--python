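# Methods

## The clustering model

`morphodelim` treats each measured individual as a point x⁽ⁱ⁾ ∈ ℝᵈ, one
coordinate per continuous morphological character, and delimits groups by
spectral clustering:

- **Similarity.** S_ij = exp(−γ‖x⁽ⁱ⁾ − x⁽ʲ⁾‖²·s(d)) with s(d) = 1/d by
  default. Dividing the exponent by the character count d keeps the useful γ
  range roughly [0.05, 1.0] for z-scored characters regardless of how many
  characters were measured; `KernelConfig.exponent_scale` also offers
  `multiply` (×d) and `none` for users who want the raw-exponent variants, as
  the literature is not consistent about this scaling.
- **Laplacian.** L = I − D^(−1/2) S D^(−1/2), D_ii = Σ_j S_ij. L is
  symmetric positive semidefinite with eigenvalues in [0, 2]; for a graph
  with c disconnected components, 0 has multiplicity c.
- **Embedding.** The eigenvectors of the K smallest eigenvalues, with each
  row renormalized to the unit sphere (the symmetric-Laplacian variant of the
  standard algorithm). A full dense eigendecomposition is used — surveys in
  this domain are at most a few hundred individuals — and the decomposition
  is computed once per γ and shared across all K during a sweep.
- **Partition.** k-means with greedy (k-means++) seeding, best of 100
  restarts by within-cluster sum of squares, all restarts drawn from one
  seeded stream so runs are exactly reproducible. Labels are canonicalized by
  first occurrence (the cluster of individual 0 is label 0), so identical
  partitions compare equal as vectors.

### Model selection

The eigengap heuristic: gap(K) = λ_{K+1} − λ_K over ascending eigenvalues
(1-based). K is a *peak* when gap(K) > gap(K−1), gap(K) ≥ gap(K+1) (so
plateau ties resolve toward smaller K, the parsimonious choice) and gap(K) ≥
2.0 × the profile's median gap. The prominence factor makes the rule
invariant to uniform rescaling of the gaps; 2.0 is a documented default, not
an estimate — published eigengap analyses pick peaks by eye, and this rule is
the closest explicit formalization. A K that peaks for at least half of the
γ grid is a *consensus peak*. Deliberately, no score ever picks a single
winning γ or K automatically: the tool reports candidates and the
biological-plausibility veto (e.g. rejecting a γ that merges distinct
complexes) remains the user's, since taxonomic domain knowledge cannot be
encoded in a gap statistic.

### Preprocessing

Ratios (length/width pairs collapsed to single columns) limit
pseudoreplication; correlation pruning (flag r² ≥ 0.7 with p < 0.05, drop
the later column unless a keep-list says otherwise; report-only mode
available) prevents a trait from entering twice; z-scoring (sample SD,
divisor N−1, switchable to N) puts all characters on one scale. Missing
values are an error, never imputed: morphometric matrices at this scale are
complete, and silent imputation would distort the similarity structure.

**A caveat worth knowing:** z-scoring divides each character by its *total*
SD, which for a strongly cluster-separating character includes the
between-group spread. Separation expressed as a ratio to the within-group SD
is therefore compressed — it saturates near √(number of groups) per character
no matter how separated the raw measurements are. This is the correct
behaviour for heterogeneous real measurements (units must go), but it means
synthetic benchmarks whose characters already share a common scale should be
mean-centred (`morphodelim.center`) rather than z-scored; the recovery tests
do exactly that, and the pipeline applies full standardization as real
surveys require.

## Validation indices

NMI (mutual information of the label contingency, normalized by the
arithmetic mean of the two entropies; geometric/max/min variants exposed),
the plain Rand index, and the adjusted Rand index. The adjusted variant is
the headline pair-counting score: only it is chance-corrected and can go
negative, matching the [−1, 1] range quoted for cluster validation in this
workflow. All three are cross-checked in the test suite against a
brute-force pair-enumeration/contingency oracle over every set partition of
six items.

## Character analysis

- **Mutual information** between a continuous character and the discrete
  cluster assignment uses the Kraskov-family nearest-neighbor estimator
  (k = 3, seeded tie-break jitter), reported in nats. The estimator is
  invariant under monotone rescaling of a character, so raw and standardized
  tables rank identically. Constant characters score exactly 0 by definition
  (bypassing the estimator's jitter artifact); an equal-frequency-binning
  plug-in estimator (⌈√N⌉ bins) is available as an independent cross-check.
- **Character–eigenvector correlation**: Pearson r with two-sided p for
  every character × eigenvector pair, eigenvectors taken raw (before row
  renormalization) in ascending-eigenvalue order, i.e. decreasing importance
  for cluster formation. Pairs with p > 0.05 are flagged for display
  suppression rather than deleted.
- **Cluster-vs-rest t-tests**: Welch's unequal-variance form, because
  cluster sizes are unbalanced by construction. Clusters with fewer than two
  members or non-members are skipped with a logged reason. Zero-variance
  degeneracies are handled explicitly: identical groups give t = 0, p = 1;
  zero-variance groups with different means are recorded as infinitely
  separated, not a crash. Raw p-values are reported by default (mirroring
  how such heatmaps are usually drawn); Benjamini–Hochberg correction is a
  flag.

## Ordination baselines

PCA on the covariance matrix of mean-centred data (components by descending
eigenvalue, explained-variance fractions summing to 1 over all d).
Continuous-variable Gower dissimilarity (mean over characters of
|difference|/range). Non-metric MDS by SMACOF with isotonic regression on
dissimilarity ranks, minimizing Kruskal stress-1, best of 20 seeded starts,
300 iterations maximum; stress below 0.2 is the conventional adequacy
threshold. The comparison arm clusters the first two dimensions of either
ordination with the same k-means routine (default K = 10). On planted
non-convex structures (concentric rings) the graph-based method separates the
forms while both ordination+k-means baselines score near zero adjusted Rand —
the package's testable restatement of why spectral clustering is preferred.

## The synthetic-data generator

`SpeciesComplexConfig`/`generate` emulate a morphometric survey of a species
complex: `n_taxa` taxa with per-taxon sample sizes drawn from `per_taxon_range`
(optionally adjusted to a fixed total), `n_informative` characters that carry
taxon signal and the rest pure noise, Gaussian within-taxon variation
(`within_sd`, log-normal option for ratio-like characters), optional hybrid
individuals (convex combinations of two taxon centroids with uniform mixing
weight, parents recorded in the metadata sidecar), optional cross-complex
outliers (displaced halfway toward a centroid of the other complex), and an
optional grouping of taxa into complexes whose centres sit twice as far apart
as taxa within a complex.

Centroid geometry is exact: an isotropic Gaussian draw is spread-equalized
per character and rescaled so the *closest* pair of taxon centroids is
exactly `centroid_separation × within_sd` apart. The per-character
equalization guarantees every declared-informative character individually
separates the taxa — with a raw draw, one axis occasionally ends up carrying
no between-taxon variance, silently turning an "informative" character into
noise.

`paper_scale_preset()` fixes the survey shape to a two-complex (3 + 7),
ten-taxon design: 93 individuals, sizes in [4, 19], 16 characters of which 8
informative, centroid separation 3 × within-SD (deliberately overlapping),
one hybrid taxon intermediate between two members of the larger complex, and
2% cross-complex outliers. These defaults were chosen once as a realistic
"hard but structured" regime: recovery is partial (NMI roughly 0.3–0.6
depending on the draw), which is the operating regime the method is meant
for — trivially separable complexes would need no delimitation tool.

What the generator does **not** emulate: qualitative characters, measurement
error models, phylogenetic covariance among taxa, allometric correlations
among characters, or non-Gaussian within-taxon shapes beyond the log-normal
option. Passing tests on this generator therefore demonstrate the machinery
— recovery when structure exists, calibration when it does not — rather than
performance on any particular real complex.

## Numerical choices and problem sizes

- Eigendecomposition: `scipy.linalg.eigh` (full, dense); eigenvalue-zero
  tests use tolerance 1e-8, Laplacian range checks ±1e-10.
- Determinism: every stochastic step (generator, k-means restarts, MI
  jitter, nMDS starts) is seeded; a grid sweep derives one sub-seed per
  (γ, K) cell from the sweep seed so each cell reproduces a standalone run.
  Pipeline runs are byte-reproducible and replayable from their manifest.
- Degenerate inputs: constant characters are rejected at standardization
  (named in the error); zero-width ratios, zero-range Gower characters and
  K exceeding the number of distinct embedding points are errors; zero
  embedding rows are left unnormalized with a warning.
- Simulation sizes in the test and acceptance suites (100 recovery seeds at
  N = 60, 50–100 character-analysis replicates, 200 null-calibration
  replicates, 50 ring-benchmark seeds, one full 20 γ × 19 K × 100-restart
  sweep at N = 93 run twice for reproducibility) were chosen to bound Monte
  Carlo error well below the asserted margins while keeping a full run in the
  low minutes on one CPU.

## Known limitations

- Only the RBF kernel is implemented; the architecture leaves a seam for
  other similarity matrices (ordinal/categorical data, mixed measures) but
  none are provided.
- No bootstrap/stability-based model selection; the eigengap consensus is
  the only automated K-selection aid.
- The correlation-pruning threshold (r² ≥ 0.7) is a documented default —
  published practice applies expert judgment per pair, which report-only
  mode supports but cannot replace.
- nMDS "iteration" budgets differ across software traditions; here
  `n_starts` (restarts, default 20) and `max_iter` (within-run iterations,
  default 300) are both explicit and configurable.
- Qualitative characters are out of scope throughout.
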