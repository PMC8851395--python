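# Methods

`alcoeeg` implements a complete alcoholism-detection pipeline for
multichannel EEG trial matrices: segmentation, cluster-stability sampling,
covariance eigen-spectrum features, distributional feature screening, and a
radius-margin SVM with a learned feature-space metric whose hyperparameters
are tuned by fruit-fly optimization. This note records the model choices,
the parameters that matter, and what the synthetic benchmarks do and do not
establish.

## Data model and segmentation

A recording is a `(channel, sample, trial)` voltage block — canonically 61
channels × 256 samples (1 s at 256 Hz) × 30 trials. Channels are stacked
channel-major into a `(n_channels · n_samples) × n_trials` matrix (61
channels give 15,616 × 30) and cut into `n_segments` equal, consecutive,
non-overlapping row chunks (default 4, giving 3,904 × 30 each). Remainder
rows that do not fill a chunk are dropped with a warning. Note that these
row chunks deliberately cross channel boundaries (3,904 / 256 ≈ 15.25
channels per segment); the segmentation is an arithmetic partition of the
stacked matrix, not a physiological grouping.

## CT-BS: cluster stability and fixed-size sampling

Rows of each segment are clustered with Lloyd k-means (k-means++ seeding,
default k = 32). Cluster ids are canonicalized by ascending centroid norm
so that "cluster j" means a comparable thing across independently clustered
segments; without this, downstream feature columns of different instances
would not be aligned and classification degrades to near chance.

Stability of each cluster C is the bootstrap mean maximal Jaccard
coefficient: for each of `b` replicates (default 100), draw n rows with
replacement, recluster with the same k, restrict both the original cluster
and the new clusters to the resampled rows, and record the maximum Jaccard
similarity; the mean over replicates with a non-empty induced cluster is
τ_C ∈ [0, 1]. The `target_k` most stable clusters are kept (default 30 of
32; ties favour the lower id) and each kept cluster is resampled with
replacement to a fixed `cluster_size` (default 120 rows) so that feature
extraction sees equal-sized blocks. On well-separated synthetic blobs
τ_C ≈ 1; forcing k = 2 on a homogeneous cloud yields visibly lower τ,
which is exactly the discrimination the pruning step relies on.

## Covariance eigen-spectrum features

Each 120-row cluster is split into 4 consecutive 30-row sub-clusters. Per
sub-cluster, the sample covariance (rows as observations, trial columns as
variables, n−1 divisor) is eigendecomposed; the descending spectrum is
summarised by ten statistics: mean, median, maximum, minimum, mode, range,
standard deviation, variance, skewness, kurtosis. Conventions, logged in
feature metadata:

- variance/SD use the n−1 divisor; skewness and kurtosis are the
  standardized 3rd/4th central moments with population normalisation
  (kurtosis of a normal sample ≈ 3, not 0); zero-variance input takes
  skew = kurt = 0;
- the mode of a continuous sample groups values at 12 significant digits
  and returns the smallest most-frequent member, so on all-distinct
  spectra mode = minimum (the two then carry identical screening
  behaviour, which matches the published screening tables);
- with fewer observations than variables the spectrum has structural
  zeros; the statistics are computed over the full-length spectrum.

A segment becomes a 40 × k matrix (4 sub-clusters × 10 statistics by k
kept clusters); a classification instance is one (recording, segment) pair
with the cluster-major flattened vector of length 40·k and the recording's
label.

## Kolmogorov–Smirnov screening

For each of the ten statistic types, all features of that type are pooled
and the control/alcoholic pools compared with the two-sample KS test,
separately within a training table and a testing table. A type is accepted
iff both p-values are ≤ α (inclusive; α = 0.05). P-values use the exact
null distribution when the smaller sample has ≤ 25 values and the
asymptotic Kolmogorov distribution with effective n = n_a·n_b/(n_a+n_b)
otherwise. No multiple-testing correction is applied — the screen is a
reproduction of the published procedure, not a calibrated inference.

Under a true null with independent train/test tables the per-type
acceptance rate is ≈ α² = 0.25%, which the acceptance checks verify by
simulation. Inside cross-validation the screen is fitted on a stratified
half-split of the training fold only (the halves play the train/test
roles), so test-fold information never reaches feature selection.

The package bundles the published screening p-values of six channel-subset
experiments on the UCI alcoholism archives (`reference_screens`); replaying
them through the decision rule reproduces the published acceptance rates
(60/90/70/50/40/80%) and the final eight retained types {mean, median,
minimum, mode, range, kurtosis, SD, variance}. One bundled cell is a
corrected presumed misprint, noted inline in the source.

## Radius-margin F-SVM

Inputs are embedded by RBF kernel PCA: the kernel k(x,y) = exp(−γ‖x−y‖²)
is double-centered and eigendecomposed, keeping the smallest G dimensions
whose cumulative eigenvalue mass reaches `kpca_ratio` (default 0.9);
coordinates are scaled U√Λ. The classifier then minimises

    f(K, w, b) = ½ wᵀK⁻¹w + Z Σᵢ δᵢ + ρ tr(K N),    K ⪰ 0,

with hinge slacks δᵢ = max(0, 1 − yᵢ(wᵀzᵢ + b)), N the sample covariance
of the embedded training coordinates, Z the margin/slack cost and ρ
(default 0.01) the weight of the radius surrogate tr(KN) that penalises
spread in the learned metric K.

The fit alternates two exact coordinate-descent steps from
K₀ = D Λ^(−1/2) Dᵀ (eigendecomposition of N, eigenvalues floored at
`eps_psd`·tr(N)/G):

1. **Hyperplane step.** With K fixed, substituting z′ = K^(1/2) z turns the
   problem into a standard linear soft-margin SVM with cost Z, solved
   exactly (libsvm); w = K^(1/2)v gives wᵀK⁻¹w = ‖v‖². The symmetric PSD
   square root is used; any A with AᵀA = K yields the same problem up to
   rotation.
2. **Metric step.** With (w, b) fixed, δ does not depend on K, and
   ∇f(K) = −½K⁻¹wwᵀK⁻¹ + ρN. K takes a projected-gradient step
   K ← P₊(K − t∇f) with the PSD projection by eigenvalue clipping at
   `eps_psd` and backtracking halving of t (initial `t1` = 1e−3) until the
   objective does not increase.

Iteration stops when the relative Frobenius change of K falls below `tol`
(1e−4) or after `max_alternations` (20). Because both half-steps only ever
lower f — and the previous hyperplane is kept if a re-solve under the new K
comes back worse at solver tolerance — the recorded objective trace is
non-increasing by construction, and K is asserted PSD after every update.
The analytic gradient matches central finite differences to ~1e−8 relative
on random instances.

Prediction embeds new points with the training centering statistics. As a
point moves far from all training data its kernel row vanishes and the
decision value converges to the constant w·z∞ + b, where z∞ is the
embedding of the zero kernel vector (nonzero because of centering); this
limit is verified numerically.

## Fruit-fly optimization (FOA)

(Z, γ) are tuned by a fruit-fly search. Each fly carries one planar
position per parameter, initialised uniformly in the window [10, 20]²
(from the ax, bx, ay, by = 10, 20, 20, 10 defaults). Per iteration every
position takes a uniform random step in [−step_scale, step_scale], the
distance to the origin gives the smell concentration d = 1/Dist, and d is
decoded to a parameter through e = clip(κd + λ, lo, hi), parameter = 2^e
(κ = 200, λ = −10, exponent range [−10, 10] — the classic 2^−10…2^10 grid,
searched continuously). After evaluation the swarm relocates to the best
position found so far (elitist vision step; ties favour the lower fly
index), so the best-so-far history is non-decreasing by construction. The
decode map and the two-positions-per-fly layout are this package's
concretisation — one scalar smell value cannot address two parameters.
Defaults of population 20 and 100 iterations follow the published setting;
the pipeline's desk-scale configuration shrinks both. On the quadratic
benchmark −(log₂Z−3)² − (log₂γ+2)² the swarm reaches the optimum to well
within one exponent unit (median over 20 seeds).

## Pipeline, evaluation, and scaling choices

Evaluation is stratified k-fold CV (default 5) over (recording, segment)
instances, with the positive class *alcoholic*. Per fold: KS screening on
a half-split of the training fold; per-segment column z-scoring with
training-fold statistics plus a global 1/√dim factor (segments cover
different channel blocks whose power differs by orders of magnitude — this
nuisance scale would otherwise bury the class signal; the segment index of
an instance is metadata available at prediction time); FOA tuning of
(Z, γ) against an inner stratified CV accuracy on the training fold only;
final F-SVM fit and prediction of the held-out fold. Accuracy,
sensitivity, specificity, PPV and NPV are derived from pooled confusion
counts; metrics with zero denominators are reported as null, never as
zero. Since segments of one recording are distinct instances, folds may
contain sibling segments of a training recording; the null-separation and
shuffled-label checks confirm this does not manufacture accuracy.

Channel ranking reruns the pipeline restricted to each single channel and
orders channels by CV accuracy (ties by channel order).

The test and acceptance benchmarks run a desk-scale configuration — 8
channels, k = 8 → 6 kept clusters, 40-row clusters, 10 bootstrap
replicates, 10 recordings per class, FOA 5×8 — chosen so the full suite
completes in minutes while exercising every stage; the worked-example
shape checks separately run the full 61-channel, k = 32 → 30, 120-row
geometry.

## Synthetic data: what it does and does not show

The generator draws two classes of recordings from latent AR(2) sources
(complex pole pair, radius 0.92, ~10 Hz at 256 Hz — an alpha-band
oscillation) mixed into channels by a class-specific matrix plus white
sensor noise (`noise_sd`, default 0.5). One unit of `class_separation`
adds a 15% amplitude gain and a random structural rotation of scale
0.2/√n to the second class's mixing, and nudges the oscillation frequency
by 2%; separation 0 makes the classes generatively identical. At
separation 2 the leading channel-covariance eigenvalue separates the
classes by far more than 3 pooled standard errors, and the full pipeline
recovers the classes at ≥ 0.9 CV accuracy (median over seeds), while
separation 0 stays inside the binomial chance band.

What passing these benchmarks shows: the pipeline's stages compose
correctly, leak no test information, and detect a covariance-level class
difference of realistic effect size. What it does not show: performance on
real alcoholism EEG — the generator has no artifacts, no nonstationarity,
no inter-subject variability (each recording is an independent draw), and
its class effect is a global mixing change rather than a spatially
focal one. Published-accuracy reproduction on the UCI archives is out of
scope here.

## Numerical choices

- Eigenvalue floors: `eps_psd` (1e−8, trace-scaled) in K₀, K inversion,
  PSD projection; kernel-PCA drops numerically zero eigendirections.
- Jaccard of two empty sets is an error, not 0; a replicate in which a
  cluster has no sampled representative contributes τ = 0 and is excluded
  from the b* normaliser, per the stability estimator's definition.
- k-means ties and re-seeded empty clusters follow scikit-learn; partition
  determinism comes from the passed seed.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; repeated runs are bit-identical.
- Exact-zero decision values predict the positive class.
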