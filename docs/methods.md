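# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, and the places where a
genuine design choice had to be made.

## Morphospace construction

Seven linear measurements per specimen (mm, 0.01-mm precision) are z-scored
column-wise with the sample SD (n−1 denominator). PCA is then the
eigendecomposition of the sample covariance of the z-scored matrix — i.e.
the correlation-matrix PCA of the raw data. The decomposition is done on
the explicitly formed 7×7 matrix with a symmetric-eigenvalue routine rather
than an SVD of the data; at this size the two are equally accurate and the
explicit matrix is easier to audit (a test asserts agreement with the SVD
route). Axes are sorted by decreasing eigenvalue and each loading column is
oriented so its largest-magnitude element is positive — a deterministic
sign convention across linear-algebra backends; published figure
orientations are not bit-reproduced.

Species centroids are arithmetic means of conspecific rows in the z-scored
space. The centroid-level PCA **centers but does not re-standardize** the
centroid columns: the centroids already live in one common z-scored space,
and a second standardization would erase the between-species size structure
that is the object of study. The alternative is exposed
(`--rescale-centroids` / `rescale=True`) for sensitivity analysis.

## Disparity and dispersion

Distances are Euclidean in the full 7-D z-score space. Because PCA scores
are a rigid rotation of that space, distances computed on full-rank scores
are identical (a property test asserts this); restricting to the first k
PCs is available but not the default.

Neighbor summaries per region: per-species nearest = row-wise minimum
off-diagonal distance; mean nearest = mean of those minima; mean pairwise =
mean over the C(m,2) unordered pairs; farthest = the largest pairwise
distance in the region; per-species maxima and the SDs of minima/maxima are
reported alongside.

Multivariate dispersion follows the distance-to-centroid construction of
`vegan::betadisper`: the distance matrix is embedded by principal
coordinates (Gower double-centering, eigendecomposition of −½ J D² J),
axes from negative eigenvalues are kept with coordinates scaled by
√|λ| and flagged imaginary, and each point's squared distance to its
own-group centroid is (real-axis part) − (imaginary-axis part), floored at
0 before the square root. The observed statistic is the mean of these
distances over **all** species (group means are also reported). The
centroid, not the spatial median, is used — the statistic of interest is a
*mean* dispersion. Agreement with `betadisper` (distances and the one-way
ANOVA F across groups) is asserted to 1e-6 on a non-Euclidean fixture.

The permutation null applies one uniform random permutation **jointly** to
rows and columns per replicate. Independent row and column permutations
would destroy symmetry and produce a non-distance matrix; the joint
permutation is exactly the standard group-label shuffle over the fixed
point configuration, so the embedding is computed once and only group
membership is re-assigned. p = #{null ≥ observed}/n_reps (1000 replicates
by default); the (k+1)/(n+1) estimator — which can never return 0 — is
opt-in. The F statistic reported with the test is the one-way ANOVA F of
the per-point dispersion distances with group as the factor; it is absent
when any group has fewer than two members.

The dispersion analysis operates on the 21 species centroids partitioned by
region by default (species-level spacing is the quantity of interest);
individual-level input is accepted through the same functions.

## Ancestral states and phylomorphospace

Under Brownian motion the ML ancestral states are the node values
minimizing Σ_branches (Δx)²/length — branch-length-weighted squared-change
parsimony, equivalently the GLS solution under the tree's shared-path
covariance. The production algorithm is the linear-time two-pass scheme:
a post-order pass contracts each node to a pseudo-observation (inverse-
branch-length weighted mean of its children, effective length = own branch
+ 1/Σ(1/child effective lengths)); a pre-order pass combines each node's
downpass value with its parent's finalized estimate. Polytomies need no
special handling. Tests assert agreement to 1e-8 with a dense Laplacian
normal-equation solve on random trees of up to 8 tips, and to 1e-6 with
`phytools::fastAnc` on a fixed tree.

Each PC axis is reconstructed independently (BM with no trait correlation),
the standard phylomorphospace construction; joint multivariate BM is out of
scope. Zero-length branches would give infinite GLS weights and are
replaced by ε = 1e-8 × tree height with a logged warning (an error mode is
available). Node estimate variances (effective lengths) are exported in the
coordinate CSV but not plotted. The rendered figure is a plain morphospace
scatter with branch segments — tips colored by region, internal nodes as
black dots; no fan-style tree styling.

## Synthetic data generator

The generator emulates the sampling design the analysis expects:

- **Tree**: two monophyletic clades of 12 and 9 species whose split sits
  9.06 time units before present. Each clade grows by a pure-birth (Yule)
  process whose crown height is rescaled to `crown_fraction × split_depth`
  (default 0.75 — crown radiations younger than the split, a typical
  pattern), stems making up the rest, so the tree is ultrametric by
  construction.
- **Species means**: a one-factor trait model, mean_s = m₀ + size_s·ℓ +
  shape_s, with size a scalar BM (rate `sigma_size`, default 2.1) loading
  on all variables through the unit vector ℓ (default 1/√7 each), and
  shape 7 independent BMs (rate `sigma_shape`, default 0.05). The size
  factor is additive on the measurement scale rather than log-allometric:
  the analysis consumes z-scores, so only the covariance structure matters.
  m₀ defaults to typical mid-sized clutter-edge-bat wing dimensions
  (16–42 mm).
- **Individuals**: species mean + iid Gaussian noise (`within_sd`, default
  0.5 mm) per variable, rounded to 0.01 mm to emulate caliper precision and
  floored at 0.01 mm (a caliper cannot record a non-positive length; at
  default rates the floor is never reached).
- **Sample sizes**: a fixed per-species vector totalling 206 specimens
  (12-species clade: 9, 8, 11, 10, 9, 20, 6, 13, 9, 10, 6, 5; 9-species
  clade: 19, 5, 6, 6, 5, 10, 20, 9, 10), mirroring a realistic museum
  series.

The default rate ratio sigma_size/sigma_shape = 42 was calibrated with the
package's own `tune_size_dominance` (bisection on the log-ratio, share
averaged over a fixed seed schedule) so that the **expected**
individual-level PC1 share sits at ≈ 0.936, the size-dominated regime of
real *Miniopterus* wing data. The realized share of a single dataset
scatters around that expectation with SD ≈ 0.04, driven by the random tree
shape and BM realization — a real feature of clade-level data (one tree,
one history), not simulation noise that averaging within the dataset could
remove. Tests and acceptance checks on the share therefore evaluate means
over a few seeds.

What the generator does **not** emulate: allometric curvature (log-scale
size), sexual dimorphism, measurement-error covariance between variables,
unequal within-species variances, non-BM trait dynamics (OU, early burst).
Passing tests on synthetic data therefore demonstrate the correctness of
the computations and the calibration of the null machinery, not the
biological conclusions for any real dataset.

A note on an asymptotic property: with the size factor switched off, the
PC1 share approaches the isotropic value 1/7 only when species effects are
uncorrelated (pure iid noise). On a fixed-height phylogeny the shape BM
keeps species means phylogenetically correlated, bounding the effective
degrees of freedom, so the share stays well above 1/7 no matter how many
species are simulated; the test of the isotropic limit uses the iid-noise
configuration.

## Numerical choices and degenerate inputs

- Sample SDs everywhere use the n−1 denominator.
- Zero-variance measurement columns are a hard error in z-scoring (named in
  the exception).
- PCoA eigenvalues with |λ| below 1e-9 × max|λ| are treated as zero and
  dropped; the negative ones beyond tolerance become imaginary axes.
- The permutation p comparison uses a 1e-12 absolute tolerance on ≥, so a
  replicate exactly reproducing the observed configuration counts as ≥.
- Name reconciliation between tree tips and table species lower-cases,
  collapses whitespace to underscores, and strips a leading genus token
  ("Miniopterus", "M.", "M"); strict mode errors on any unmatched name,
  listing both sides.
- Pruning collapses degree-2 nodes by summing branch lengths and drops the
  dangling root stem, so retained root-to-tip depths change only by the
  common removed stem (tested via a path-sum oracle).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a dataset, an analysis and a CLI run are
  bit-reproducible given (inputs, config, seed).

## Problem sizes

The default analysis operates on 206 specimens × 7 variables and 21
species; the permutation test uses 1000 replicates; property tests use
trees of ≤ 8 tips (against a dense-solve oracle), 200 simulated null
datasets with 99 permutations each (p-uniformity), and 10,000 sampled
permutations against an exhaustive 5!-enumeration oracle. The whole suite
runs in well under a minute on one CPU.
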