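# Methods

This note documents the models, numerical choices, and design decisions
behind `artikin`, and what the synthetic test bed does and does not show
about real data.

## Grid geometry and line profiles

Coordinates are `(row, col)`, 0-based, with the row index increasing downward.
The baseline runs from the posterior landmark (upper frontal edge of cervical
vertebra 4) to the anterior landmark (incisor–palate transition); the
0-degree direction points from the baseline midpoint toward the anterior
landmark and positive angles rotate clockwise on screen. Five site lines of
exactly half the baseline length start at the midpoint (0°, 7.5°, 15°, 60°,
90° for TTR, TT-TD, TT-ARD, TB-PD1, TB-PD2); lip aperture (LA) is measured on
the segment between the upper- and lower-lip centers. The original grid's
30°/120°/150° lines and the posterior baseline half (a head-motion indicator)
are constructible but carry no site mapping and are excluded from analyses.
Because speakers move between repetitions, the grid is rebuilt per trial from
that trial's landmark entries, with the first frame as reference.

Intensities are sampled at 1-px steps from the line origin by bilinear
interpolation (`scipy.ndimage.map_coordinates`, order 1). The sampling rule of
the original acquisition toolbox is not documented; bilinear interpolation is
the natural generalization to non-axis-aligned lines, agrees with raw pixel
lookup on axis-aligned integer-coordinate lines, and is linear in the image —
a property the test suite checks directly.

## Air/tissue segmentation and gap tracking

Grey values of one line profile are modeled as a three-component Gaussian
mixture — air (dark), uncertain (grey), matter (light) — fit by EM with an
ordered-means constraint (components are relabeled into ascending-mean order
after every M-step). Initialization is deterministic at the 10/50/90th
percentiles; convergence is a relative log-likelihood change below 1e-7;
component standard deviations are floored at 0.5 grey units so atomic
(noise-free) inputs cannot collapse the model. The mixture is fit per line
profile by default (per-trial or per-subject pooling is a caller choice).

The binarization threshold is the smallest grey value above the dark mean at
which the dark component's weighted density falls below the combined weighted
density of the two brighter components (density-crossover rule; bracketing
scan plus Brent refinement). If no crossover exists — e.g. a vanishing dark
weight — the threshold falls back to dark mean + 3 dark sd and the fit is
flagged. The crossover choice is isolated behind one function because the
original work states only that the dark component "set the threshold".

Air gaps are maximal below-threshold runs per frame, registered over time by
pixel-index overlap with the previously retained gap (ties: longer run, then
smaller start index). Zero overlap records a closed gap and carries the last
open interval; on reopening the run with the nearest midpoint is taken. The
original interactive review is replaced by a declarative override table
(frame → run index, or a forced threshold per profile); every override and
every closure/reopening decision is logged on the trajectory. TTR is not a
gap: it is the run of tissue pixels from the line origin (baseline midpoint,
inside the tongue) outward to the first tissue→air transition; an air origin
yields 0 with a warning, a fully-tissue line saturates at the line length and
is flagged.

## Time normalization

The cohort median frame count T\* is computed over all included trials
jointly (the analysis description reads "from all considered samples"); even
counts take the midpoint of the two middle values rounded half-up, since
frame counts are integers. Each trajectory's index grid [0, L−1] is mapped
affinely onto [0, T\*−1] and values are linearly interpolated; endpoints are
preserved exactly and linear interpolation cannot overshoot the source range.
Perceptual screening (stuttering symptoms, mispronunciations, >250 ms pauses)
is inherently non-computable from images and enters as per-trial metadata
flags; the assembly step applies those flags, optionally drops the two
training repetitions (lowest two repetition indices per speaker), caps
repetitions at ten per speaker in ascending order, drops speakers below a
minimum repetition count, and logs every exclusion.

## Penalized function-on-scalar regression

Per site, on the T\* grid:

    y_ij(t) = beta0(t) + x_i * beta1(t) + b_i(t) + eps_ij(t)

with x_i = 1 for AWS and 0 for FS. With two groups, an "ordinal" group factor
reduces to difference coding, so testing beta1 ≡ 0 is a test for a difference
in the mean course. All curves share one cubic B-spline basis
(K = min(25, max(T\*/4, 8)) by default, configurable); beta0 and beta1 carry
second-order difference penalties, the speaker curves b_i a ridge penalty on
their basis coefficients. With theta = [beta0; beta1; b_1..b_S], the stacked
normal equations have Gram matrix kron(X'X, B'B), which keeps every REML
evaluation a single Cholesky of a (2+S)K matrix. The three smoothing
parameters are chosen by Gaussian REML on the mixed-model representation,
minimized by Nelder-Mead from four fixed starts (the REML surface is
occasionally multimodal; the best of the four is kept). Term-wise effective
degrees of freedom are traces of the corresponding blocks of
(A + S_lambda)^{-1} A.

Inference: the Wald-type test uses the penalized fit's Bayesian covariance at
rank round(edf) and a chi-square reference — a known approximation that tends
anticonservative. The primary calibrated option is the speaker-level
permutation test: group labels are permuted across speakers, coefficients are
re-fit at the observed smoothing parameters, and p = (1 + #{perm ≥ obs}) /
(1 + n_perm). Two properties worth knowing: (i) the attainable p floor is
1/(1 + n_perm), so claims like p < 0.01 need n_perm ≥ 199; (ii) with few
speakers the number of distinct label assignments, C(n, n_A), bounds the
resolution — with 4 + 4 speakers the observed assignment and its complement
recur with probability 2/70 per draw, flooring p near 0.03 regardless of
n_perm. Simulation sizes in the test suite (T\* = 30, K = 8, 4/group for
type-I calibration, 8/group for power) were chosen with these resolution
limits and with desk-scale runtimes in mind.

Exact invariances hold only in limits the tests exercise explicitly:
reference-group swap flips the sign of beta1 exactly in the vanishing
curve-penalty limit (a finite difference penalty is not preserved by the
reparametrization beta0 → beta0 + beta1); a huge penalty drives the beta1
*coefficients* into the difference null space (linear in coefficient index),
which for clamped B-splines is linear in the Greville abscissae, not exactly
linear in t near the boundaries.

## Dissimilarities and clustering

The spatiotemporal dissimilarity between two site curves is
sqrt(∫ (f−g)² dt) with the integral approximated by Simpson's rule on the
median-frame grid; odd point counts use composite Simpson, even counts
Simpson on the first T\*−1 points plus a trapezoid on the last interval. All
quadrature weights are positive, so the discretized quantity is a genuine
metric (verified on random triples). dt defaults to 1 frame: any absolute
time scale multiplies all dissimilarities and distances uniformly and cancels
from every label-level output (labels, k\*, C-index, Fisher p, PCA shares,
allocation) — the pipeline's scale-equivariance property.

Per repetition this yields the C(6,2) = 15 site-pair values; averaging per
speaker gives the speaker feature table. Speaker-to-speaker distances are
energy distances, E = 2·mean‖a−b‖ − mean‖a−a′‖ − mean‖b−b′‖ with full n²
averaging. Averaging first and then taking energy distances between the
single mean vectors is degenerate (it reduces to 2× the Euclidean distance),
so the default mode uses the repetition-level 15-vectors as each speaker's
empirical distribution; the literal-reading reduction is available as
mode="mean" and coincides with the default for single-repetition speakers.

Hierarchical clustering runs on the energy-distance matrix via the
Lance-Williams recurrence (scipy implementation), Ward's minimum-variance
method by default and complete linkage as the named alternative; reports
carry the linkage used. The cluster count minimizes the C-index
(S_w − S_min)/(S_max − S_min) over k (ties → smallest k; an all-equal
distance matrix defines C = 0 with a log message; a C-index spread below 0.05
over the range flags weak structure — note that tight, well-separated blobs
legitimately give near-zero C-index at several k, so the flag is advisory).
Cluster–group independence is tested by exact enumeration of all r×c tables
with the observed margins (hypergeometric probabilities, 1e-7 relative slack
against float ties), with a seeded margin-preserving Monte-Carlo fallback
(2·10⁵ tables) beyond n = 200. PCA on the speaker feature table is
column-centered and unscaled by default (all 15 features share units), with
optional standardization that drops constant columns. Allocation scoring
generalizes the published rule: each cluster's predominant group is its
majority label; a speaker is correctly allocated iff its group matches its
cluster's majority; tied clusters flag their members ambiguous and drop them
from the denominator. The TTR-only variant replaces the 15 pair features with
one scalar per repetition — the L2 size of the TTR curve against a gap that
stays closed — and reuses the same distance/clustering chain.

## Synthetic cohort and phantom

The generator emulates the statistical structure the analysis assumes, not
vocal-tract physics. Each site's gap-width curve over normalized utterance
time is a baseline aperture plus Gaussian bumps at phoneme-target times
(near-closures of the tongue-tip lines at the alveolar/postalveolar
consonants, a tongue-body closure for the velar, lip and velum modulations);
amplitudes are free parameters chosen to give plausible aperture ranges — no
per-site ranges are published. Speaker individuality is a smooth random curve
(Gaussian-bump basis, sd 0.4 px) shared across repetitions; repetition noise
is a smaller smooth curve (sd 0.3 px); both reflect a cohort whose speakers
differ only slightly and repeat themselves consistently. Durations are
integer frame counts, normally jittered (sd 4) around 55 frames with floor
20; gestures ride on normalized time, so duration jitter acts as uniform time
scaling, which the median-duration normalization later removes.

Group structure enters as coupling archetypes that rescale and phase-shift
the TTR gestures relative to the other articulators: two FS strategies (hypo:
amp ×0.35, −5 frames; hyper: amp ×1.9, +5 frames) and one intermediate AWS
archetype (×1.0, 0), assigned cyclically within each group. This plants a
three-cluster structure in which the AWS cluster sits between the two FS
clusters on the TTR-coupling axis, and makes the TTR pairs the discriminating
features. The contrast is set so adjacent archetypes are roughly five
within-cluster standard deviations apart in the 15-pair feature space —
"strong" coupling differences by construction; `cohort_design(separation=s)`
scales the contrast continuously down to none (s = 0), and downstream
recovery (ARI) increases monotonically with it. Group *mean* curves differ
only mildly because the AWS archetype is intermediate — so, as in the data
the generator emulates, per-site functional regression finds at most small
group effects while the dissimilarity clustering separates the cohort.

Phantom rendering writes each trial into 128×128 frames with three grey
classes (air 30, uncertain 110, tissue 200 by default, 1.4 mm/px, 55 fps).
Exact recoverability is engineered rather than hoped for: the fixed sampling
operator W (bilinear weights of every profile sample point over its four
neighbor pixels, duplicate points merged) is precomputed with its
pseudoinverse, and each frame is background + W⁺(v − W·background), the
minimum-norm pixel field whose bilinear samples equal the programmed class
values v exactly. Programmed widths are integers (rounded bundle values; the
ground-truth table carries both), gaps start at fixed offsets along each line
(10 samples; 5 on the lip line), and a frame whose gap exceeds the line
capacity raises a geometry error naming trial and frame. Gaussian grey noise
is added after construction; Rician MRI noise is out of scope — Gaussian
suffices to exercise the mixture segmentation. Line profiles therefore
contain only air/tissue values with crisp boundaries (the uncertain class
lives in an off-grid image band); real rtMRI adds partial-volume boundary
voxels, intensity inhomogeneity, and motion, so passing the phantom tests
shows the extraction chain is correct, not that it is robust to every
real-world artifact.

## What the tests do and do not establish

Green tests establish: internal consistency of the geometry and quadrature
primitives against closed forms and brute-force oracles; exact end-to-end gap
recovery on the engineered phantom and ≤1 px mean error under heavy grey
noise; calibration (type-I error within [0.01, 0.10]) and power of the
permutation test at the reduced simulation sizes; and recovery of the planted
three-cluster structure (k\* = 3, ARI ≥ 0.9) in at least 18 of 20 cohort
draws with significant cluster–group association. They do not establish
performance on real rtMRI data, robustness of the published cluster sizes or
allocation percentage (the study data are not deposited), or the behavior of
the GMM threshold under partial-volume grey distributions.

## Known limitations

- Wald p-values are approximate; use the permutation test for calibrated
  inference (it is the default method).
- The C-index can be nearly flat across k for very tight clusters; the weak-
  structure flag marks this but the reported k\* is then arbitrary among ties.
- Energy-distance clustering treats repetitions as exchangeable draws; serial
  effects across repetitions (fatigue, adaptation) are not modeled, in the
  generator or the analysis.
- The phantom's minimum-norm pixel field is exact at the sample points but
  locally non-anatomical between them; it is a test bed, not a simulation of
  MRI contrast.
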