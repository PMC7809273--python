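# Methods

This note documents the models, parameter choices, and numerical
conventions behind `fcsubspace`, and what the synthetic validation does
and does not establish about real data.

## Common-component extraction

Each subject's denoised R x T ROI time-series matrix is one block. The
block is centered twice before SVD: each ROI's temporal mean is removed
(Pearson correlation downstream is invariant to it), and each timepoint's
across-ROI mean is removed. The second centering matters: any signal
shared within communities makes the global across-ROI spatial direction
*exactly* common across subjects, so without it the extraction returns an
arbitrary mixture of that direction and the genuinely shared spatial
pattern. The extractor then takes each block's top-k left singular
vectors Bᵢ and returns the top-C eigenvectors of `M = Σᵢ BᵢBᵢᵀ`.
Eigenvalues divided by the subject count give a *commonness score* in
(0, 1]; a score of 1 means the direction lies inside every subject's
retained subspace. For white-noise blocks at R=30, T=240, k=10 the null
score distribution sits near 0.63 (Monte Carlo over 100 draws,
99th percentile ≈ 0.67), far from 1 — a useful reference when judging
whether an extracted component is meaningfully common.

Defaults: C = 1 (a single common spatial map) and
k = min(20, R−1, T−1). Truncation is mandatory — with full-rank blocks
every direction is trivially common. Groups are decomposed separately,
never pooled: pooling would absorb group differences into the shared
component. Map columns are sign-fixed (largest-magnitude entry positive)
for reproducible serialization. Removal is the orthogonal projection
`Y − MMᵀY`; it is idempotent, never increases the Frobenius norm, and
leaves `MᵀY = 0` to 1e-8.

The comparison of two groups' spatial maps reports |cosine| per matched
column; its significance test is a declared construction of this package:
subjects are regrouped at random (sizes preserved), pseudo-group maps
re-extracted, and the p-value is the add-one fraction of regroupings
whose between-map similarity is at most the observed one.

## Edgewise statistics

Edges are the upper triangle in lexicographic (i, j), i < j, 0-based
order, everywhere. Group tests run on Fisher-z values (atanh with inputs
clipped to |r| ≤ 1 − 1e-7) using the pooled-variance two-sample t —
group sizes are near-equal by design; a Welch variant is available via
`scipy` directly on the same edge matrices. Degenerate zero-variance
edges are reported at p = 1 with a warning count. BH-FDR comes from
`statsmodels` and is cross-checked in the tests against a literal
step-up implementation. The tmax correction computes, per label
permutation, the maximum |t| over edges; the adjusted p is the add-one
fraction `(1 + #{max|t| ≥ |tₑ|})/(n_perm + 1)`, so p is never 0 and is
monotone in |t|. When the number of distinct label assignments does not
exceed `n_perm`, all assignments are enumerated exactly (identity
included) instead of sampled.

GSR is implemented at the time-series level (OLS residual of each ROI on
the across-ROI mean plus intercept). Head motion enters only as a
per-subject scalar (mean FD): as a covariate in nuisance regression and
in the FD-edge association test (per-group Pearson r of FD with each
edge, Fisher-z, two-sample z with BH-FDR).

## Connectome-based prediction

The fold-level procedure is strictly train-only; the leakage audit in
the test suite perturbs a held-out score and asserts the trained model
is bit-identical. Order of operations within a training fold:

1. nuisance regression of the score on intercept + covariates (age, sex
   0/1, education; optionally FD); constant covariate columns are
   dropped, genuine collinearity is an error;
2. feature selection: top ⌈fraction·E⌉ edges by |Pearson r| with the
   *residualized* score (ties to the lower edge index); default fraction
   0.5;
3. standardization of selected features by train mean/sd;
4. hyperparameter tuning by inner leave-one-out CV over a grid:
   mixing α ∈ {0.1, …, 1.0} and λ log-spaced over 50 values from
   λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻³λ_max (grid built once per
   training fold; each inner fold re-standardizes with its own
   statistics). Ties prefer smaller α, then larger λ — the sparser
   model. The solver is scikit-learn's coordinate descent
   (`enet_path` along the λ grid during tuning; `ElasticNet` for the
   final fit — identical objective, with `alpha=λ`, `l1_ratio=α`).

Evaluation designs: outer leave-one-out (accuracy = Pearson r between
predicted and residualized observed scores; prediction R² = 1 − SSE/SST
with SST about the mean observed residual); the leave-one-out bootstrap
(B draws of n with replacement, training on the unique members, scoring
out-of-bag; replicates with fewer than 3 OOB subjects or fewer than 4
unique training members are redrawn); and cross-group designs that train
on a bootstrap draw of one cohort and score m subjects sampled without
replacement from the other (default m = max(3, ⌈n_test/3⌉) — at least
two points are needed to correlate predicted and observed, and a third
stabilizes the estimate). Edge weights count, per replicate, the edges
that were both selected and given a nonzero coefficient; they are
integers in [0, B]. Jaccard overlap keeps each group's positive-weight
edges ranked by weight (ties to the lower index), thresholds at the top
20/50/100%, and reports intersection over union.

t tests on bootstrap replicate distributions replicate the evaluation
protocol of the study design this package implements; because bootstrap
replicates are dependent, those p-values are anti-conservative and
should be read as protocol outputs, not calibrated error rates.

## Multi-subject community detection

The multilayer quality function uses a uniform null `B = W − γ` inside
each layer (diagonal zeroed) and an all-to-all categorical coupling ω
between a node's copies across layers. The uniform null is what makes
negative γ values meaningful on signed correlation matrices; a
degree-based null is available behind the `null_model` flag. Subjects
are unordered, so chain coupling would be wrong by construction. The
supra-matrix is held as sparse blocks (S dense R x R blocks plus
R·S·(S−1) coupling entries); the dense (RS)² matrix is never formed.

Maximization is a generalized Louvain over node-layer units: greedy
local moves (including moves into a fresh singleton, which matters with
negative weights), aggregation, and — after the aggregation ladder
converges — a unit-level refinement pass, alternating until a full cycle
makes no move. The refinement lets single units escape super-nodes the
plain two-phase hierarchy freezes them into. The first restart grows
from singletons; later restarts start from random coarse partitions,
which escape a further class of local optima (per-node columns locked by
the inter-layer coupling). On all enumerable instances tried (R·S ≤ 12,
random signed layers), the best of 30 restarts attains the
exhaustive-search maximum. Node visit order is shuffled per restart from
the seed; the best-of-restarts partition is returned with labels
relabeled contiguously by first appearance. Q is reported unnormalized
(argmax-equivalent).

Per-node entropy across subjects is normalized by ln(max(K, 2)) with K
the partition's own community count, keeping h ∈ [0, 1] comparable
across partitions. The (γ, ω) sweep samples uniformly at random (the
reference protocol's 20,000 samples over γ ∈ [−0.7, 1], ω ∈ [−0.5, 2]
are the API defaults; desk-scale runs use a few hundred samples), one
seeded Louvain run per point. Partition selection: entropy within
MANE ± 0.02, no single-node community in any subject, optionally a
community-count range (default 5–23, the range of large-scale brain
networks commonly reported; an optional filter because the original
criterion was advisory), then minimum γ, maximum ω, highest Q. The
framework is meant to be applied on a restricted subset of the (γ, ω)
plane where communities have characteristic size and variability; on
small synthetic cohorts the tests restrict to γ ∈ [0.1, 0.7],
ω ∈ [0, 0.5] for the same reason.

## Community-size association and clinical statistics

Community sizes (per-subject node counts) sum to R, so entering all K
columns with an intercept is exactly collinear; the largest community's
column is dropped by default (`drop_largest=False` keeps all and relies
on rank detection, which errors). BH-FDR is applied across the community
predictors only, not covariates. OLS is statsmodels', cross-checked
against normal equations in the tests.

Mann–Whitney U is reported as min(U_A, U_B) with a tie-corrected normal
z carrying the sign of (U_A − n_A n_B/2), no continuity correction, and
effect size r = z/√N — the convention that reproduces standard clinical
tables. The 2x2 chi-square is Pearson's without Yates correction (the
corrected variant does not reproduce the printed statistic for the
reference cohort's gender table). Power of the overall F test uses the
noncentral F with u = #predictors, v = n − u − 1, and λ = f²·n; the
sample-size-based λ convention is a documented choice, and the test
suite cross-checks against an independent Poisson-mixture series.

## Synthetic cohort generator

Node i of subject s follows
`x_i(t) = √a·g_{c(i,s)}(t) + √(1−a)·ε_i(t) + strength·m_i·h_s(t)` with
standardized latent courses (i.i.d. normal, optional AR(1) behind a
knob, off by default — band-passed variance-normalized resting data at
desk scale motivates ignoring autocorrelation). The spatial map m is
shared within the group and drawn with zero spatial mean (identifiable
against the global direction that community signal shares exactly);
the temporal course h_s is subject-specific, because the pipeline
removes a shared spatial component, not a shared time course. Groups
share one base partition by default so that, apart from planted
differences, no edge differs in expectation; `shared_base_partition=False`
plants group-specific architectures. Subjects deviate from the base
partition independently per node with probability `node_reassign_prob`.

Planted group-difference edges draw their shared pair latent from the
endpoints' *private-noise* share: in group B the endpoint becomes
`√a·g + √(1−a−d)·ε + √d·d_e`, which boosts the pair correlation by ≈ d
while leaving the endpoints' other edges untouched (this requires
d ≤ 1 − a; nodes on several planted edges split the share equally).
Behavioral scores are `y = Σ w_e z_e + Normal(0, sd²)` on Fisher-z
edges. Covariates use typical adult clinical-cohort values: age
~N(28, 7) truncated to [21, 65], education ~N(14.5, 2), sex
Bernoulli(.5), mean FD ~|N(0.074, 0.04)| mm; the companion symptom
scales are correlated noise stand-ins. No distributional choice here is
estimated from real scans — the generator is a stand-in for undeposited
data, and passing recovery tests demonstrates internal consistency of
the pipeline, not validity on real fMRI (which has autocorrelation,
spatial smoothness, scanner artifacts, and non-Gaussian tails the
generator omits).

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale as the package's own
choice of study conditions: R = 16–30 ROIs, T = 240 timepoints, 20–24
subjects per group, B = 200 bootstrap replicates, sweeps of a few
hundred (γ, ω) samples, and hyperparameter grids of 3 mixing values by
10 penalties; API defaults retain the full-scale settings (C = 1,
top-50% features, B = 1000, 20,000 sweep samples). Determinism: every
stochastic stage takes a seed or Generator; identical parameters give
bit-identical outputs, and the pipeline writes a RunRecord sufficient to
reproduce a run. Fisher-z clipping at |r| ≤ 1 − 1e-7; orthonormality and
idempotence asserted to 1e-8; permutation p-values use the add-one
convention; edge order is fixed for all serialized outputs.

## Known limitations

- The common-basis extraction fixes block rank and component count a
  priori; no model selection for C is provided.
- Louvain optimality is verified only on enumerable toys; at brain scale
  the usual greedy-local-optimum caveats apply.
- The MANE ± 0.02 selection rule can legitimately return an empty
  candidate set on small cohorts or unrestricted parameter ranges; the
  error message says so rather than silently relaxing.
- Bootstrap-distribution t tests are anti-conservative (dependent
  replicates), as noted above.
- Voxel-level preprocessing, NIfTI handling, partial correlation, and
  dynamic connectivity are out of scope.
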