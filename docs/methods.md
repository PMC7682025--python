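# Methods

`metageo` predicts the city-of-origin of metagenomic samples from
taxonomic abundance profiles. Two settings are covered: classification
over cities present in the training data, and interpolation of origin
probabilities for cities absent from it. This note records the model,
the choices that were genuinely open, the synthetic data the tests run
on, and what those tests do and do not establish.

## Input model

A sample is a vector of relative abundances (percent) over
rank-prefixed clades (`k__...|p__...|...|s__...`), as emitted by
MetaPhlAn- or Kraken-style profilers. All clade levels are retained as
features. Tables from different sources are merged over the union of
taxa with absences stored as exact zeros, so every sample shares one
feature set; taxon order after a merge is lexicographic on the clade
string so merging is associative and platform-independent. Values are
kept as the profiler's percentages — no renormalization on read.

## Ternary discretization

Abundances are binned to {−1, 0, 1} against the 25th/75th percentiles
of the training data:

    f(x) = −1 if x < P25;  0 if P25 ≤ x < P75;  1 if x ≥ P75

with boundary semantics exactly as written (x = P25 → 0, x = P75 → 1;
a constant feature therefore maps entirely to 1 and is expected to be
discarded by feature selection). The percentile axis is ambiguous in
principle: we default to **per-feature** percentiles across training
samples, because test samples must be binned against training-derived
cut points to avoid leakage; a per-sample mode (percentiles across taxa
within each sample at application time) is available via
`BinningThresholds(axis="per_sample")`. Quantiles use linear
interpolation between order statistics, and the convention is recorded
in the serialized thresholds.

## Feature selection and classification

Recursive feature elimination repeatedly fits the one-vs-rest
classifier and drops the `step = 5` lowest-importance features per
round until `target_k = 50` remain (fewer on the last round so the
count is exact). Importance of a feature is the maximum over cities of
the absolute coefficient; ties break lexicographically by taxon name
so rankings are bit-reproducible. Fifty features is the default
because, in the large-p small-n regime of city-level surveys,
held-out accuracy saturates around that size while larger subsets
mostly add variance.

The classifier is one binary L2-regularized logistic regression per
city (city vs rest), each scoring a sample by
`p = 1 / (1 + exp(−(w·x + θ)))`. `l2_strength` (default 1.0) is the
weight of the ½‖w‖² penalty — the inverse of scikit-learn's `C`. Fits
use L-BFGS to tolerance 1e−8; the contract is the convex optimum, not
the algorithm. Per-city sigmoids are **normalized to sum to one** by
default so scores are comparable across cities when used as kriging
anchor values; raw sigmoids are available (`normalize_output=False`)
since the per-city formulation does not itself impose normalization.
Evaluation uses repeated stratified 70/30 shuffle-splits (default
100); elimination is rerun inside each split's training portion only.
Argmax ties resolve to the lexicographically first city and are
flagged.

## Biological coordinates and affine registration

Geographic proximity does not reliably track biological similarity, so
interpolation happens on a "biological" map: the top-2 PCA scores of
the training samples' profiles, with each city placed at the centroid
of its samples. PCA is computed by SVD of the mean-centered matrix;
the largest-magnitude entry of each loading vector is made positive so
embeddings are deterministic across platforms.

PCA is applied to the **raw abundance profiles** by default. The
binned, selected representation is available
(`pca_features="binned_selected"`) but empirically registers far worse:
on data with a planted affine geography–biology relation the affine
residual per unit centroid spread is roughly 0.17 for raw profiles
versus 0.63 for binned features, because ternary binning saturates
exactly the smooth between-city gradients the map needs.

Geographic (lon, lat) positions are registered to the map by the
six-parameter planar affine transform

    [x  y  1] · [[m11, m12], [m21, m22], [t_x, t_y]] = [x′  y′]

fit by least squares over the sampled cities (≥ 3 non-collinear
anchors). Coordinates are treated as planar degrees; an optional
equirectangular scaling (lon × cos mean-lat) is provided for
high-latitude city sets. An unsampled city is placed on the biological
map by applying the fitted transform to its geographic position.

## Ordinary kriging

A sample's predicted probabilities on the sampled cities are anchor
values p_i at those cities' biological positions; the probability at
an unsampled position is the best linear unbiased predictor
`p̂ₒ = Σ λ_i p_i` with weights solving the augmented system

    [Γ 1; 1ᵀ 0][λ; μ] = [γ(d(target, ·)); 1],   Γ_ij = γ(d_ij),

which enforces Σλ = 1 (unbiasedness). The semivariogram γ is estimated
from the anchors (equal-width distance bins; semivariance = mean of
½(v_i − v_j)² per bin) and fit by weighted least squares (weights =
pair counts; nugget, partial sill and range bounded nonnegative) over
gaussian (default), exponential, spherical or linear families. We take
γ(0) = nugget.

Numerical choices, all for the few-anchor regime this pipeline lives
in (typically ≤ 10 anchors):

- fewer than 3 non-empty bins, a non-converging fit, or a fitted range
  beyond 10× the largest lag fall back to the linear family (warned);
- a flat semivariogram (near-constant anchor values) makes any
  parametric system singular; because ordinary-kriging predictions are
  invariant to a scaling of γ and a constant field is reproduced by
  every valid model, the pipeline substitutes a canonical unit-slope
  linear model in that case;
- gaussian structures can be ill-conditioned for unlucky anchor
  layouts; the solver refuses systems with condition number above
  1e12 (reporting it), and the pipeline retries with the linear
  family;
- predictions are clamped to [0, 1] (kriging is not range-preserving)
  with the clamping flagged.

## Held-out-city protocol and permutation null

For each held-out city, thresholds, feature selection, classifier, PCA
embedding, centroids and the affine fit are rebuilt from the remaining
cities' samples only; the held-out city's samples never touch any
training artifact. The city is placed by the affine transform, each of
its samples' anchor probabilities are kriged there, and significance
is assessed by shuffling training-sample **city labels** uniformly at
random and rerunning classifier training, centroids, affine fit and
kriging per permutation (label shuffling rather than feature-row
shuffling matters for the centroids; it is the variant implemented).
Thresholds and the raw-profile PCA embedding are unsupervised, hence
unchanged under label permutation. Feature selection is frozen across
permutations by default to bound cost; the flag is recorded on the
result, and rerunning selection per permutation is supported.
P-values use the add-one convention `(1 + #{null ≥ obs}) / (1 + N)`,
so they are never exactly zero.

## Synthetic data

The generator emulates a multi-city survey satisfying the framework's
assumptions with full ground truth: city geographic positions uniform
in a bounding box (minimum-separation enforced), biological positions
the planted affine image of geography, each informative taxon's
log-mean abundance a Gaussian bump over the biological map (random
center, configurable length scale and amplitude), per-sample log-normal
noise, uninformative taxa i.i.d., rows exponentiated, normalized to
percent, and the smallest configured fraction of each row zeroed to
mimic profiler sparsity. Defaults mirror the regime of a 16-city
survey: unbalanced 10–26 samples per city, 5503 taxa, 50 informative,
noise sd 0.5, sparsity 0.3.

Two named regimes are frozen for end-to-end checks, both at a reduced
problem size (8 cities, 500 taxa, 50 informative) chosen so the whole
suite runs on a laptop:

- `strong_separation_config` (length scale 0.2, amplitude 4, noise sd
  0.3): short-range spatial variation maximizes between-city contrast —
  the classification regime;
- `smooth_spatial_config` (length scale 0.4, otherwise identical):
  gentle variation between neighboring cities keeps the PCA map close
  to an affine image of geography — the interpolation regime.

What the generator does **not** emulate: compositional correlation
structure between taxa, rank-nested lineages (all synthetic taxa are
independent species-level clades), sequencing-depth effects, batch
effects, or outlier samples. Passing tests therefore demonstrate that
the implementation is correct and that the method works when its
assumptions hold; they say nothing about how often real urban
microbiomes satisfy those assumptions.

## Determinism

A single global seed is fanned out to stage-keyed substreams
(`stage_seed(seed, name)`), so adding a stage never perturbs another
stage's randomness. Every CLI command is a pure function of its inputs
plus the seed; logs go to stderr and each output directory receives
the resolved configuration, so reruns are byte-identical.

## Known limitations

- With ≤ 10 anchors the variogram fit is weakly determined; the linear
  fallback is common and the gaussian family's parameters should not
  be over-interpreted.
- The affine registration is global and linear; a strongly warped
  geography–biology relation (e.g. one outlier city) degrades
  placement of every held-out city.
- Interpolated probabilities are anchored to the one-vs-rest scores of
  the *remaining* cities and are not probabilities in a calibrated
  sense; they are evidence to be combined with other sources, not
  posteriors.
- Permutation p-values inherit the granularity 1/(N+1) of the null
  size and, within a held-out city, share permutation draws across
  samples (they are not independent across samples of one city).
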