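# Methods

This note documents the models and numerical conventions behind `radiomix`:
what each stage computes, the knobs that matter, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely open.

## Preprocessing

Tumors arrive as per-modality 3-D volumes with aligned binary masks. Both are
resampled jointly to isotropic voxels — 2.0 mm for PET, 0.5 mm for DCE-MR
(first post-contrast frame) by default — using corner-anchored voxel-center
mapping: output center *j* sits at physical position *j·t* along each axis.
Images are interpolated linearly, masks by nearest neighbor so they stay
binary. The masks are assumed to have been drawn on the native grid and are
resampled together with their images; resampling to the native spacing is an
exact identity.

PET activity concentration C (kBq/ml) is converted to standardized uptake
value

    SUV(v) = C(v) · W / (A_inj · 2^(−Δt / T½)),

with body weight W in grams, injected activity A_inj in kBq, injection-to-scan
delay Δt in minutes, and T½ = 109.77 min for ¹⁸F by default. Passing Δt = 0
treats A_inj as already decay-corrected. MR intensities are used in their
arbitrary units — no cross-scanner harmonization is attempted.

Masked intensities are discretized with a fixed bin width (0.1 SUV for PET,
5.0 a.u. for MR): level(v) = floor((I(v) − min_masked)/w) + 1. The anchor at
the masked minimum makes all downstream texture and histogram features
invariant to constant intensity offsets; the maximum value falls in its floor
bin (no special edge bin), and a constant region is a valid single-level
image, not an error.

## Radiomic features (42 per modality)

**First-order (9).** min, max, mean, population variance, skewness, kurtosis
(moment ratio m₄/m₂², not excess), histogram entropy −Σ p log₂ p, histogram
uniformity Σ p², and energy Σ I(v)² over masked voxels. A zero-variance
region returns skewness = kurtosis = 0 by convention rather than NaN. The
"energy" here is the sum of squared voxel intensities (the conventional
first-order energy), not a histogram statistic, despite the HIST-style
naming sometimes attached to it; the histogram uses the same fixed bin width
as the GLCM discretization.

**Shape (8).** Volume V (voxel count × voxel volume), surface area A,
A/V, compactness1 = V/(√π·A^{3/2}), compactness2 = 36πV²/A³, sphericity =
π^{1/3}(6V)^{2/3}/A, spherical disproportion = A/(4πR²) with R the radius of
the equal-volume sphere (the exact reciprocal of sphericity), and the maximum
3-D diameter: the largest pairwise Euclidean distance between surface-voxel
centers (computed on convex-hull vertices for speed, with a brute-force
fallback for degenerate point sets).

Two surface-area estimators are provided. `face_count` sums exposed voxel
faces and is exact on axis-aligned boxes — it backs the cube unit tests — but
does not converge to the true area of curved surfaces (a digitized ball's
face count tends to 1.5× the sphere area). `mesh` (default) triangulates the
0.5-isosurface by marching cubes after padding and smoothing the binary mask
with a Gaussian of σ = 1 voxel; the raw staircase triangulation overestimates
curved areas by ≈ 8%, while with the slight smoothing a radius-20 digitized
ball comes out within 0.5% of 4πr² (the acceptance bound is 3%).

**GLCM texture (25).** In 3-D, the 26-connected neighborhood at voxel
distance 1 collapses to 13 unique displacement representatives after
identifying d with −d. One symmetric co-occurrence matrix is accumulated per
direction — ordered within-mask voxel pairs counted in both orientations,
normalized to unit sum — and each texture feature is reported as the mean
over the 13 matrices; a direction with no valid pair inside the mask is
excluded from the average. Features: autocorrelation, cluster
prominence/shade/tendency, contrast, correlation, difference
average/entropy/variance, average intensity (μ_x), dissimilarity, energy,
entropy, homogeneity1/2, IDMN, IDN, inverse variance, maximum probability,
sum average/entropy/variance, sum of squares, IMC1, IMC2. Conventions:

- logarithms base 2 everywhere, with 0·log 0 := 0;
- correlation of a single-level (σ_x = 0) region is defined as 1, and
  IMC1 = IMC2 = 0 when both marginal entropies vanish, so constant regions
  never produce NaN;
- inverse variance sums over i ≠ j only (0 for a single level);
- IDMN/IDN normalize by the per-image observed gray-level count Ng, matching
  the per-tumor discretization (no global level cap);
- sum variance follows Haralick's original Σ(k − SE)²·p_{x+y}(k) centered on
  the sum entropy SE; the "corrected" variant centered on the sum average is
  identical to cluster tendency and would duplicate a feature;
- difference variance is the variance of p_{x−y}.

Every feature is verified against a brute-force pair-enumeration oracle
(plain Python loops over voxels and matrix entries) to 1e−10 on random
grids, and the direction-averaged values are checked to be invariant under
grid-axis permutations, which the 13-direction set is closed under.

Feature names are frozen in a registry (`PET_`/`MR_` prefix + 42 names) so
that downstream importance tallies are stable across runs: 9 + 8 + 25 = 42
per modality, 84 for a PET+MR pair.

## Consensus clustering

The z-scored feature table is clustered with resampling: each iteration
draws 80% of the tumors without replacement and partitions them at every k
in the candidate range; the consensus matrix entry M(i,j) is the fraction of
co-sampled iterations in which i and j were co-clustered. Item pairs never
co-sampled are imputed 0 with a warning. Algorithms: Ward hierarchical
clustering on the dissimilarity, k-means on the data matrix, k-means on the
rows of the distance matrix (KMdist), and PAM — a seeded k-medoids
implemented here (greedy build initialization plus medoid-swap alternation)
since no pre-installed library provides one. Dissimilarities: Euclidean,
1 − Pearson, 1 − Spearman across item feature vectors, with constant
vectors assigned correlation 0.

The number of clusters is selected from the empirical CDF of the
off-diagonal consensus entries: A(k) is the area under that CDF on [0, 1],
Δ(2) = A(2), Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2, and the k with the
largest Δ wins, ties going to the smaller k (parsimony). Final per-k labels
come from average-linkage hierarchical clustering of 1 − M, the convention
of the standard consensus-clustering implementations; the per-cluster
consensus is the mean of M over within-cluster pairs (singletons count 1)
and the median across clusters is the reported "median cluster consensus".
For each clinical variable the algorithm × dissimilarity setting with the
highest Cramér's V against that variable is reported.

Open knobs and their settings: subsampling fraction 0.8 (the conventional
default; items only are subsampled, not features), iteration default 10,000
with tests and drivers using 500 (the consensus entries are means of
Bernoulli draws, so 500 iterations put their standard error below 0.023),
k range 2–6 by default.

## Association statistics

Cluster labels vs categorical outcomes: chi-square test of independence
without continuity correction on the pairwise-complete contingency table,
with Cramér's V = √(χ²/(n·(min(r,c)−1))); significance level 0.05.
Ordered outcomes (grade, stages): Spearman's rank correlation with midrank
tie handling per feature. Unordered outcomes (subtype, recurrence status):
proportion of variance explained by a dummy-coded group regression, i.e.
one-way ANOVA η² = SS_between/SS_total, cross-checked in the tests against
an explicit least-squares fit. Missing clinical values are excluded
pairwise, so each association has its own complete-case N. The display
thresholds |ρ| > 0.2 and r² > 0.04 are report filters only; the full
matrices are always written. No multiple-testing correction is applied.

Z-scoring uses the population SD (divisor n) and returns the fitted
mean/SD so the identical transformation can be reapplied to held-out rows;
constant columns are flagged and left unscaled with a warning.

## Classification

Outcomes are dichotomized as: grade {1,2} → 0, {3,4} → 1; recurrence-free
survival at cutoff y ∈ {1..5} years → 1 if still recurrence-free beyond y
(taken from an explicit per-year label column when present, else derived
from the time to recurrence). Rows with missing outcomes are dropped and
counted.

Each classifier is evaluated by repeated stratified nested cross-validation
with 3 inner and 3 outer folds. Per repetition and outer fold: features are
z-scored with outer-training statistics only (never the full data — this
deliberately tightens the method description's ambiguous "normalized prior
to model training" to the leakage-free reading), the hyperparameter grid
point with the best inner-CV mean AUC is selected (ties to the smallest C,
the strongest penalty), the model is refit on the outer-training set and
scored by AUC on the outer test fold. A repetition whose folds lose a class
is reshuffled with a warning. All reps × 3 outer AUCs are retained; their
mean and a percentile 95% CI from 1000 bootstrap resamples of the AUC list
(resampling AUC values, not patients) are reported. The default is 1000
repetitions — 3000 outer fits, the tally denominator — although the source
protocol also mentions 10 repetitions; `reps` is a knob.

The classifier menu mirrors the [Reg][Solver]LogReg naming: logistic
regression with L1 (liblinear/saga), L2 (liblinear/lbfgs/newton-cg/sag) and
ElasticNet (saga) regularization, an RBF-kernel SVM (decision scores feed
the AUC) and a random forest. Hyperparameter grids, unspecified in the
source protocol, default to C ∈ {0.01, 0.1, 1, 10}, ElasticNet mixing ratio
∈ {0.2, 0.5, 0.8}, 100 trees; a single-point grid skips the inner search
(nothing to select), which is how the 3000-fit tally is exercised cheaply.

Feature importance is a selection tally over all outer fits: a feature
counts when |coef| > 0 (L1/ElasticNet) or |coef| > 0.01 (L2), the proportion
is count / (reps × 3), and the top 10 are reported with alphabetical
tie-breaking. Non-coefficient models raise an error pointing to permutation
importance, which is out of scope.

## Synthetic cohort generator

The generator emulates the *structure* of a PET+MR breast-tumor cohort, not
its physics. Each tumor is an ellipsoid (per-group semi-axes in mm with 12%
uniform jitter) rasterized at the modality spacing; its intensity is a group
mean plus a unit-variance Gaussian random field (Gaussian-smoothed white
noise; the smoothing σ is the group's texture correlation length) scaled by
the group SD, plus white measurement noise. PET values are clipped positive
and stored as activity concentration such that SUV conversion with the
manifest's body weight (70 kg) and injected activity (350 MBq,
decay-corrected) reproduces the group's SUV statistics.

The default cohort is 90 tumors in three equal groups with SUV means
2.0/4.5/8.0 (SD 0.4/0.6/0.85), MR means 150/250/380 a.u., correlation
lengths 0.5/1.2/2.4 PET voxels and growing sizes — separations chosen to
represent clearly distinct phenotype groups, the regime in which cluster
recovery is a meaningful correctness check. Grade, subtype and overall stage
are drawn from per-group categorical tables; T/N stage are noisy functions
of overall stage; recurrence follows a logistic model on the z-scored true
group SUV mean and correlation length (intercept −1.3, coefficients 1.1 and
0.5), with a uniform recurrence time on (0.25, 5.75) years defining the
1-5-year recurrence-free labels and a 6% "never disease free" fraction. A
truth record (latent groups, true feature values, recurrence probabilities)
is emitted so recovery metrics never need regeneration.

Not emulated: scanner point-spread functions and correlated noise, DCE
kinetics, irregular tumor shapes, class imbalance as extreme as a real
registry, and missing clinical data. Passing recovery tests therefore shows
the pipeline's statistics and selection rules are implemented correctly on
data of the assumed structure — not that radiomic features predict outcomes
in any real cohort.

Default volume sizes (≤ ~25³ PET, ≤ ~64³ MR voxels) keep a 90-tumor cohort
generation plus 84-feature extraction around 5 s, which is what makes the
20-seed consensus-recovery and 3000-fit cross-validation checks routine
desk-scale tests; the same knobs scale up.

## Degenerate inputs and tie rules (summary)

- Constant image region: valid everywhere (Ng = 1, variance 0, entropy 0,
  correlation 1, IMC 0, skew/kurt 0).
- Empty mask after resampling: error naming the tumor id.
- Cluster-number ties: smaller k. Inner-CV ties: smaller C. Importance
  ties: alphabetical. Algorithm-selection ties: first run.
- Consensus pairs never co-sampled: 0 with a warning; constant feature
  vectors: correlation 0 in correlation dissimilarities.
- Bootstrap CI of a constant AUC list: zero width.

## Known limitations

- PAM is a light k-medoids (greedy build + swap alternation), not the full
  original swap search; adequate at cohort scale (n ≈ 100) but not tuned for
  thousands of items.
- The mesh surface estimator's σ = 1 smoothing slightly rounds genuinely
  sharp corners (a cube's mesh area reads ~2% low); face counting covers
  shapes where exact box areas matter.
- Consensus clustering stores dense item × item matrices per k; memory grows
  quadratically in cohort size.
- The recurrence generator couples outcomes to two named true features only;
  real cohorts mix many weak correlates.
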