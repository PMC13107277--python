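# morphodisparse

Comparative wing-morphospace analysis for sister radiations measured with
linear morphometrics — built around the question of whether an island
radiation of insectivorous bats (the Malagasy long-fingered bats,
*Miniopterus*) diverged more in wing shape than its same-aged continental
sister clade, or whether wing morphology stayed conservative while species
multiplied.

The package takes two inputs: a specimen table of seven linear wing/limb
measurements in mm (tibia length and six wing-bone elements: `Tib`, `D2M`,
`D3M`, `D3P1`, `D3P2`, `D4M`, `D5M`) with species and region labels, and an
ultrametric species-level phylogeny (Newick, branch lengths in Myr). From
these it computes:

- **Morphospace** — the measurements are z-scored column-wise and analysed
  by correlation-matrix PCA (eigendecomposition of the 7×7 correlation
  matrix, scores `S = Z·V`). With strongly covarying wing elements, PC1 is a
  shared size axis. A second PCA of the species centroids (the mean
  z-scored vector per species; centered, not re-standardized) summarizes
  between-species structure.
- **Disparity** — species-by-species Euclidean distance matrices in the
  full 7-D z-score space; per-region nearest-, mean-pairwise- and
  farthest-neighbor summaries.
- **Multivariate dispersion (MVDISP)** — each species' distance to its
  regional centroid in a principal-coordinates embedding of the distance
  matrix, with the standard correction for negative-eigenvalue axes
  (d² = Σ real-axis − Σ imaginary-axis squared distances, floored at 0);
  the observed mean dispersion is tested against a null built from 1000
  joint row/column permutations of the distance matrix,
  p = #{null ≥ observed}/n. A one-way ANOVA F of the per-species distances
  across regions accompanies the test.
- **Phylomorphospace** — species centroids projected onto PC1–PC2 with
  internal tree nodes placed at their maximum-likelihood ancestral states
  under Brownian motion: the states x̂ minimizing
  Σ_branches (Δx)²/branch-length, computed per axis by the linear-time
  two-pass algorithm and validated against a dense GLS solve and
  `phytools::fastAnc`.
- **Synthetic data** — a generator producing the same statistical structure
  (two monophyletic clades of 12 + 9 species split 9.06 Myr ago, species
  means evolving by BM with a dominant shared size factor, 206 specimens
  with 0.01-mm caliper noise), so the whole pipeline is exercisable and
  testable without any download.

## Worked example

```bash
morphodisparse simulate --seed 1 --out demo
morphodisparse analyze --measurements demo/measurements.csv --out demo/bundle --seed 1
morphodisparse report --bundle demo/bundle
```

prints (numbers exactly as produced by seed 1):

```
morphodisparse 0.1.0 | seed 1 | config b0e5712f41086541
species: 21
individual PCA: PC1 97.1% PC2 0.6%
centroid PCA:   PC1 99.5% PC2 0.2%
mean dispersion 1.4626 (F = 0.7432, p = 0.99800, 1000 permutations)
farthest_continental: 4.8788
farthest_madagascar: 5.8311
mean_nearest_continental: 0.3713
mean_nearest_madagascar: 0.3681
mean_pairwise_continental: 2.3038
mean_pairwise_madagascar: 1.9593
```

Reading: PC1 carries 97% of individual-level variance — a size gradient, as
in real long-fingered-bat wing data. Nearest-neighbor distances are small
and similar between regions (species pack closely in morphospace), and the
permutation p of 0.998 says the island clade's species are no more unevenly
spread around their regional centroid than random relabelings — no excess
divergence. `morphodisparse phylo --measurements ... --tree demo/tree.nwk
--out demo/phylo` adds the phylomorphospace coordinate/edge tables and a
figure.

The same statistics can be computed for any real dataset in the same
format, e.g. a museum specimen table plus a time-calibrated phylogeny:

```python
from morphodisparse.pipeline import reproduce_statistics
stats = reproduce_statistics("measurements.csv", "tree.nwk", n_reps=1000, seed=1)
```

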