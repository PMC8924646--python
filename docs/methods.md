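# Methods

`gmnet` implements a single-subject grey-matter (GM) network pipeline and the
downstream prognostic and trial-design analyses it feeds, end to end on
synthetic data. This note documents the models, the numerical choices, and
what the synthetic generators do and do not emulate.

## Single-subject GM networks

**Nodes.** A GM probability volume on the 2 mm isotropic working grid is
tiled into disjoint 3×3×3-voxel cubes (6 mm edge), starting at voxel
(0,0,0); trailing partial blocks are dropped rather than padded, so no
intensities are fabricated. Cubes that are all-zero or have zero variance
are excluded — their Pearson correlation is undefined. Each node keeps its
27 voxel values in a fixed C-order layout plus its cube-grid position, so
the local 3D structure of the tissue enters the similarity measure.

**Rotation-maximized similarity.** Two cubes are scored by the maximum
Pearson correlation over a discrete orientation set, which lets a cube match
a structurally similar patch of cortex that is locally rotated by the
folding pattern. On a 3×3×3 block the only exact discrete realization of a
45° step is a cyclic shift of the 8-voxel perimeter ring of each 3×3 slice
perpendicular to the rotation axis (slice centers fixed); k=2 steps
reproduce the exact 90° quarter-turn. The orientation set is the identity
plus k=1..7 about each single axis — 22 orientations. Composed multi-axis
rotations and reflections are excluded: single-axis ring shifts are the
minimal faithful realization of "45° steps about each axis", and the
per-axis set is closed under inverses, which makes the score provably
symmetric in its arguments (asserted by a property test rather than by
scoring both directions).

**Thresholding.** The similarity matrix is binarized at a subject-specific
threshold chosen so that the *expected proportion of spurious connections
among retained edges* is at most 5% (expected-FDP control). The null
distribution is built by repeatedly sampling a random node pair, permuting
the 27 values of one cube — which preserves its intensity histogram while
destroying spatial structure — and scoring with the same rotation-maximized
statistic, so the maximization bias is present in the null (10,000 draws by
default, seeded). The null exceedance probability at a candidate threshold
uses the add-one permutation estimator (1 + #{null ≥ r})/(n_null + 1): with
~5·10⁵ candidate pairs and 10⁴ null draws, a raw estimate of zero just above
the largest null sample would understate the expected number of false edges
by a factor of ~n_pairs/n_null. The threshold is the smallest observed
similarity at which (estimated exceedance × pair count)/(retained pairs) ≤
the spurious level; if no value qualifies (e.g. pure noise), the maximum
observed similarity is returned with a warning and the network is
near-empty, which is the correct degenerate answer. A consequence of the
estimator's resolution is that the criterion is only satisfiable when the
data contain on the order of n_pairs/(n_null·level) genuinely similar
pairs; sparser planted structure is reported as "near-empty" rather than
thresholded anti-conservatively.

## Small-world metrics

C is the mean over *all* nodes of the local clustering coefficient
(degree < 2 contributes 0, the Watts–Strogatz convention); L is the mean
shortest path length over pairs in the largest connected component (the
LCC convention avoids infinite distances on disconnected graphs and is
standard in this literature). γ = C/C_rand and λ = L/L_rand, where the
reference values are the *means over five* degree-preserving randomized
networks (average first, then divide), each produced by Maslov–Sneppen
double-edge swaps (10×|E| attempted swaps, seeded per reference as
seed + index, via `networkx.double_edge_swap`). σ = γ/λ; σ near 1 is
random-like topology, σ > 1 small-world. Graphs admitting no legal swap
(complete graphs) are their own reference, giving γ = λ = σ = 1 exactly.

## Volumetrics

TIV is the summed GM+WM+CSF probability volume. Hippocampal GM volume is
the GM probability summed inside a binary hippocampus mask. Head-size
correction is ratio scaling to a reference TIV (default 1500 ml):
hv_norm = hv × tiv_ref/tiv, which is scale-consistent and deterministic.
The hippocampal abnormality cut-off of 3.68 ml (TIV-corrected) is applied
with *lower* values abnormal — atrophy reduces hippocampal volume. Reslicing
uses trilinear interpolation with zero fill outside the source grid; a
constant field resamples exactly, and smooth fields conserve total tissue
volume to well within 2%.

## Time-dependent ROC and cut-offs

For a marker X and horizon t (2 years), the cumulative/dynamic tROC uses
the nearest-neighbour estimator of the bivariate survival function
S(c,t) = P(X > c, T > t): each subject's conditional survival S(t | X=X_i)
is a Kaplan–Meier estimate over the subjects whose empirical-CDF rank lies
within ± span/2 of X_i (ties share one rank so tied marker values share one
neighbourhood), and S(c,t) averages these over subjects with X_i > c. Then

    Sens(c,t) = [(1 − F_X(c)) − S(c,t)] / (1 − S(t))
    Spec(c,t) = [S(t) − S(c,t)] / S(t)

and the AUC is the trapezoidal area under the (1−Spec, Sens) path. Because
S(t|X_i) ≤ 1, sensitivity is automatically monotone in the threshold. The
span defaults to 0.25·n^(−0.20), the usual rate for this estimator; it is
configurable. Markers whose abnormal side is low (γ, λ, σ, hippocampal
volume) are negated internally so that larger always means higher risk;
p-tau is high-abnormal. Orientations are fixed a priori from the known
direction of the disease effect, not learned from data.

The optimal cut-off maximizes Youden's J = Sens + Spec − 1, with ties broken
toward higher sensitivity (the more inclusive cut); a value exactly at the
cut-off is classified abnormal. Kaplan–Meier curves per marker group come
from `lifelines`.

## Binary classification and mixed models

Subjects censored event-free before the 2-year horizon have an unknown
binary label and are excluded from logistic/accuracy analyses (they stay in
tROC and Kaplan–Meier, which handle censoring). Logistic models are fitted
by maximum likelihood (`statsmodels.Logit`); ORs carry Wald 95% CIs
exp(b ± 1.96·SE); AIC = 2k − 2logL is asserted as an identity on every fit.
Complete separation is detected and flagged rather than silently reported.
The biomarker-count model codes the number of abnormal markers (small-world,
p-tau, HV) as a categorical predictor against the all-normal reference and
also reports classification statistics of each "count ≥ k" rule.

Longitudinal MMSE/CDR-SB decline uses a random-intercept + random-slope
model with fixed effects intercept, time, group and group×time, estimated by
REML (`statsmodels.MixedLM`, lbfgs with powell fallback). The group×time
coefficient is the difference in mean annual decline; the slope variance
σ_b² and residual variance σ_e² feed the sizing formula. In a balanced
complete design the group×time estimate equals the difference of per-group
mean per-subject OLS slopes, which the tests exploit as an oracle.

## Trial sizing

Per arm, n = ⌈2(z_{1−α/2}+z_{1−β})² (σ_b² + σ_e²/Σ(t_i−t̄)²)/Δ²⌉ with
α = 0.05 two-sided, power 80%, visits every 6 months over 2 years
(0, 0.5, 1, 1.5, 2; Σ(t_i−1)² = 2.5) and Δ = 25% of the control arm's
decline rate by default. The ceiling is applied last (whole subjects).
The Monte-Carlo oracle simulates the same random-slope model and tests the
arm difference with the two-sample t-test on per-subject OLS slopes, whose
variance σ_b² + σ_e²/Σ(t_i−t̄)² is exactly the quantity the formula uses —
for a balanced complete design this *is* the arm×time interaction test, and
it is fast enough to run thousands of replicates. At the worked design
(σ_b²=0.1, σ_e²=1.0, Δ=0.25 → n=126/arm) the empirical power is ≈0.80 and
the empirical type-I error under Δ=0 is ≈0.05.

CIs for n are percentile bootstrap over subjects (reps ≥ 200, seeded), the
mixed model refitted per resample; the reported interval is widened, if
necessary, to cover the point estimate. The CI method is a design choice —
variance-component-based intervals would also be defensible.

## Synthetic data: what it emulates, what it does not

**Volumes.** The base field is i.i.d. Gaussian; each planted pattern adds a
shared latent 27-vector to its member cubes, scaled so the expected
member–member correlation is `target_correlation` (0.9 by default, clearly
above the rotation-max null tail, whose 99.9th percentile is ≈0.72 for
27-voxel cubes); with `noise_sd = 0` members carry the latent exactly. The
whole field is affinely mapped into [0,1], which preserves every Pearson
correlation. Defaults (30³ voxels → 1000 cubes; 8 patterns × 20 member
cubes → 1520 planted pairs, ~0.3% of candidate pairs) give the threshold
criterion enough true structure to be satisfiable at n_null = 10⁴ while
leaving >99% of pairs null. These volumes test the statistical machinery —
they have no cortical anatomy, no spatial autocorrelation (unless smoothing
is enabled) and no partial-volume structure, so passing tests certify the
estimator's calibration, not segmentation-quality robustness.

**Cohorts.** Abnormality flags (network, p-tau, HV) are independent
Bernoulli(0.5); continuous markers are drawn from per-flag Gaussian
mixtures centred to bracket the published clinical cut-offs (e.g. σ
1.55/1.40, p-tau 40/75 pg/ml, corrected HV 4.2/3.3 ml); everyone is
amyloid-abnormal (prodromal-AD inclusion). Time to dementia is exponential
with per-subject rate = base rate × ∏ HR^flag (HR 2.0 per flag, matching
the ~2–3 published ORs); the base rate is calibrated analytically —
including the competition from Exp(0.10/yr) random censoring, administrative
cut-off 4 years — so the *observed* 2-year progression fraction is 34% in
expectation. Cognitive scores follow the random-slope model with
σ_b² = 0.1, σ_e² = 1.0 (the worked sizing design), MMSE slopes −0.4/−1.4
per year (normal/abnormal network; the −1.0 difference matches the reported
group×time effect) and CDR-SB slopes +0.5/+1.1. The exponential hazard is a
simplification: downstream analyses consume only the 2-year binary outcome
and the censoring pattern, not the hazard shape. Flags are independent,
whereas real AD biomarkers correlate; recovery tests are therefore easier
than real data.

## Problem sizes and determinism

Default test/acceptance problem sizes — 1000-node volumes, 20 simulation
seeds, 2000 trial replicates, cohorts of 150–1000 — were chosen so each
calibration quantity has a Monte-Carlo standard error well below its
tolerance while a full run stays interactive on a single core. Every
stochastic stage takes an explicit seed: volume and cohort generation, the
permutation null, each randomized reference network (seed + index), trial
simulation and the bootstrap. Identical seeds give bit-identical outputs.

## Known limitations

- No registration, segmentation or anatomy: volumes enter the pipeline
  already segmented, and the synthetic volumes are statistical phantoms.
- The orientation set excludes composed multi-axis rotations/reflections;
  a cube rotated by such a composition is not guaranteed similarity 1.
- The tROC estimator is the cumulative/dynamic variant only.
- L on disconnected graphs is an LCC summary; heavily fragmented networks
  (near-threshold noise) are better read via their density/edge count.
- The expected-FDP threshold needs enough true structure to be satisfiable
  (see above); on structureless input it deliberately returns a near-empty
  network instead of a lenient threshold.
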