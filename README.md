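# morphodelim

Unsupervised species delimitation from morphometric character tables.

Closely related taxa often form *species complexes* whose members overlap in
every individual measurement, so the traditional workflow — ordinate with PCA
or nMDS, colour the points by the taxonomist's labels, and eyeball the convex
hulls — largely validates the labels it started from. `morphodelim` instead
*discovers* groups from the measurements alone and then explains them: which
morphological characters define each discovered cluster.

It is aimed at taxonomists and morphometricians with a table of continuous
characters (rows = measured individuals, columns = characters such as lengths,
widths, ratios and counts) and, optionally, a column of taxon labels used only
for validation, never for clustering.

## Method

1. **Preprocessing** — paired length/width columns are collapsed to ratios,
   highly correlated characters pruned (Pearson r² ≥ 0.7, p < 0.05 by
   default), and every character z-scored to mean 0, SD 1.
2. **Spectral clustering** — pairwise similarities from an RBF kernel,
   S_ij = exp(−γ‖x⁽ⁱ⁾ − x⁽ʲ⁾‖²/d), where d is the number of characters and γ
   sets how sharply similarity decays; the normalized symmetric graph
   Laplacian L = I − D^(−1/2) S D^(−1/2) with D_ii = Σ_j S_ij; the embedding
   from the eigenvectors of the K smallest eigenvalues of L (rows
   renormalized); and k-means on the embedded points, keeping the best of 100
   seeded restarts.
3. **Model selection** — γ is swept over [0.05, 1.0] in steps of 0.05 and K
   over [2, 20]; for each γ the *eigengap* profile gap(K) = λ_{K+1} − λ_K is
   scanned for prominent peaks, and K values that peak across enough of the γ
   grid become consensus candidates. The final biological veto stays with the
   user.
4. **Validation** — discovered clusters are scored against taxon labels with
   normalized mutual information (NMI ∈ [0, 1]) and the Rand / adjusted Rand
   indices (adjusted Rand ∈ [−1, 1]).
5. **Character analysis** — three procedures rank cluster-defining
   characters: mutual information between each character and the cluster
   assignment; Pearson correlation between each character and each Laplacian
   eigenvector; and a Welch t-test of each character inside each cluster
   against all other individuals.
6. **Baselines** — PCA (covariance of mean-centred data) and non-metric MDS
   on Gower distances (Kruskal stress-1), each followed by k-means on the
   first two dimensions, for comparison with the traditional workflow.

A seeded synthetic-data generator (`morphodelim.synthetic`) emulates a
two-complex, ten-taxon survey (93 individuals × 16 characters, 4–19
individuals per taxon, hybrids, cross-complex outliers, uninformative
characters), so every stage is testable end to end.

## Worked example

```python
import morphodelim as md

matrix, meta = md.generate(md.paper_scale_preset(seed=7))
print(f"survey: {matrix.n_individuals} individuals x {matrix.n_characters} characters")
z = md.standardize(matrix)
result = md.sweep(z, md.SweepConfig(seed=7))
report = md.detect_peaks(result.spectra)
print("consensus eigengap peaks:", report.consensus_peaks)
for K in report.consensus_peaks:
    best = max(result.spectra, key=lambda s: s.eigengaps[K - s.k_min])
    a = result.assignments[(best.gamma, K)]
    s = md.score_partitions(a.labels, z.ground_truth)
    print(f"candidate gamma={best.gamma:.2f}, K={K}: NMI={s.nmi:.3f}, adjusted Rand={s.adjusted_rand:.3f}")
    mi = md.mi_character_cluster(z, a, md.MIEstimatorConfig(seed=7))
    print("top cluster-defining characters:", ", ".join(mi.head(4)["character"]))
```

prints

```
survey: 93 individuals x 16 characters
consensus eigengap peaks: [13]
candidate gamma=0.65, K=13: NMI=0.591, adjusted Rand=0.312
top cluster-defining characters: char_inf_6, char_inf_7, char_inf_3, char_noise_3
```

The eigengap consensus nominates K = 13 clusters for this draw; scoring that
partition against the planted taxon labels gives NMI 0.59 — partial but far
from random recovery, as expected for deliberately overlapping complexes with
hybrids — and the mutual-information ranking puts informative characters in
three of the four top slots. The same workflow is available from the shell:

```sh
morphodelim generate --preset --seed 7 --out survey.csv
morphodelim run --input survey.csv --out-dir results/ --seed 7
```

which writes every table (eigengap profile, assignments, validation scores,
character analyses) as delimited text plus a `manifest.json` from which the
run can be reproduced exactly (`morphodelim.run_from_manifest`).

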