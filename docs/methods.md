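# Methods

This note records the models, estimators, conventions and numerical
choices implemented in `sptmotion`, and what the built-in simulator does
and does not emulate.

## Units and data model

All internal quantities are SI: coordinates in metres, the frame interval
`dt` in seconds, diffusion coefficients in m² s⁻¹. Import performs the
pixel→metre conversion once; nothing downstream sees pixels. Frame indices
are 0-based and may contain gaps (trackers bridge missed detections);
every delay ("lag") is a *frame-index difference*, so a gapped trajectory
contributes exactly the lags it spans. A trajectory needs at least one
localization; sets require unique ids, `dt > 0`, `pixel_size > 0`.

## Trajectory descriptors

For the xy projection of a trajectory with n points:

- **number_of_points** — localization count.
- **length** — sum of consecutive step distances (NaN for n = 1).
- **tortuosity** — length / end-to-end distance; 1 for a monotone straight
  path, +∞ for a closed path (end-to-end 0 with positive length), NaN for
  a stationary path (0/0).
- **elongation** — 1 − λ₂/λ₁ with λ₁ ≥ λ₂ the eigenvalues of the
  gyration tensor (population-normalized second-moment matrix of the
  coordinates). Bounded in [0, 1], invariant under rotation and
  translation; NaN when λ₁ = 0 (all points coincident) or n < 2.
- **elongation_angle** — orientation of the λ₁ eigenvector,
  ½·atan2(2G₁₂, G₁₁ − G₂₂), mapped to (−π/2, π/2].
- **entropy** — Shannon entropy (bits) of localization counts over a
  square grid of fixed physical cell size (default 100 nm, of the order
  of the localization error, so immobile tracks concentrate in one cell)
  covering the bounding box. A fixed cell size, rather than a fixed cell
  count, keeps the value comparable across tracks of different extent.
- **mbcr** — minimum bounding circle radius, from Welzl's algorithm.
- **mbcc_com** — distance between the bounding-circle centre and the
  coordinate mean; large for spatially asymmetric (hybrid) tracks.
  Always ≤ mbcr.

Degenerate descriptors are recorded as NaN and never raised; only
classification of a row that is NaN *at a tested property* is an error.

The minimum enclosing circle uses Welzl's randomized incremental
algorithm in move-to-front form with a fixed internal shuffle seed, so
output is deterministic for a fixed input; containment tests carry a
10⁻¹² relative slack against rounding on near-collinear support sets. The
test suite checks it against an O(n⁴) all-circles search and against an
independent computational-geometry library.

**Immobile containment probability.** The probability that a stationary
emitter's track of `n_points` localizations — each displaced by isotropic
Gaussian localization error, standard deviation σ *per coordinate* — has
MBCR within a threshold radius is estimated by direct Monte Carlo
(deterministic given a seed). This quantifies the safety margin of an
MBCR threshold for classifying immobile tracks: with a 118 nm threshold
and 17 points the probability is ≳ 99.99% both at 12 nm (in-focus) and
28 nm (out-of-focus) error. σ could alternatively be read as the 2-D
r.m.s. error (σ/√2 per coordinate); the per-coordinate convention is used
throughout because it matches the 4σ² intercept of the 2-D MSD model.

**Property PCA** standardizes each column to zero mean and unit variance
(ddof = 1), drops constant/degenerate columns with a warning and rows with
non-finite entries, and decomposes by SVD; loadings are orthonormal,
component variances non-increasing, and retaining all components
reproduces the standardized data exactly.

## Classification trees

A tree is a binary threshold tree over property names: descend left when
`value ≤ threshold`, right otherwise, until a labelled leaf. Trees are
plain JSON and can be written by hand; training is CART-style greedy
best-first induction:

- split criterion: weighted Gini impurity decrease;
- candidate thresholds: midpoints between consecutive distinct sorted
  values of each finite-valued property;
- growth: at each step the impure leaf with the globally best split is
  expanded, until `max_splits` (default 5) internal nodes, pure leaves, or
  no impurity-reducing split remains;
- leaf label: majority class, ties to the lexicographically smallest
  label; equal-gain splits resolve by (property name, threshold), making
  training deterministic across platforms;
- no pruning, no surrogate splits, equal class weights — complexity is
  controlled by `max_splits` alone, keeping trees human-readable.

Resubstitution loss (misclassification fraction on the training set
itself) is the built-in performance measure; with ~100 training examples
a user should also inspect the classified data directly. The trainer's
loss is cross-checked in the tests against scikit-learn's best-first
`DecisionTreeClassifier` with the equivalent leaf budget.

## MSD analysis

`t_msd` averages |x_{i+n} − x_i|² over all pairs at each frame lag;
`te_msd` averages the per-trajectory T-MSD, unweighted, over the J_n
trajectories that span each lag, and records both J_n and the standard
error of that mean (the spread across contributing trajectories).

`fit_msd_linear` fits value = a·t + b by least squares over the
`max(min_points, ⌈fraction·n_max⌉)` shortest delays (defaults: fraction
0.25, min_points 3), where n_max is the number of points in the curve —
the short-delay region is where the linear model holds and noise is
smallest. TE-MSD fits weight points by J_n, since long-delay values
average few trajectories; T-MSD fits are unweighted. Then

- D = a / (2d)  (d = 2 for xy data);
- σ² = b/(2d) + 2RDΔt, from the intercept model b = 2d(σ² − 2RDΔt);
  σ is reported only when the right-hand side is non-negative (a tiny
  negative value from rounding on exact curves is clipped to zero);
- standard errors: when the curve carries per-delay SEs (TE-MSD), the
  point uncertainties are propagated through the weighted estimator
  (cov = A·diag(se²)·Aᵀ with A = (XᵀWX)⁻¹XᵀW) — the naive residual-based
  SE is more than an order of magnitude too small for TE-MSD because all
  delays share the same underlying trajectories; for single-trajectory
  T-MSD fits the residual-based covariance is used.

R is a *user input* (default 1/6, the full-frame-exposure value): a
single intercept cannot separate σ from R. `motion_blur_coefficient`
computes R = (1/Δt)∫S(1−S)dτ from any monotone cumulative shutter profile
S by adaptive quadrature (0 for instantaneous, 1/6 for full-frame, 1/12
for half-frame exposure).

Per-trajectory D estimates can be negative for noise-dominated tracks;
they are reported unchanged, and per-trajectory fit failures are recorded
in the output table rather than raised.

## Squared-displacement survival analysis

At a fixed lag (default 1 frame), all squared displacements are pooled and
the empirical survival function 1 − CDF(r²) is computed; for a single
normal-diffusion state it is exponential with scale MSD(t_n). Mixtures are
fit by maximum likelihood with EM on r² (k = 1 reduces exactly to
scale = sample mean; k = 2 uses ≥ 5 seeded starts — one quantile-based,
the rest randomized — 2000 iteration cap, relative log-likelihood
tolerance 10⁻¹², best likelihood kept, components sorted by scale).
Fitting the sample by EM, rather than curve-fitting the plotted survival
function, is the statistically principled version of reading decay rates
off the semi-log plot.

## The simulator

`simulate` emulates transient trapping as observed through a microscope's
focal slice.

**Dynamics.** Walkers start uniformly in a periodic 3-D box, in a
uniformly random state. The state (1 = trapped, D₁ = 0; 2 = mobile,
D₂ = 10⁻¹² m² s⁻¹) flips at each frame boundary with probability
`p_switch` = 0.02 (at dt = 0.05 s, a 0.4 s⁻¹ switching rate), giving
geometric dwell times and symmetric 50/50 occupancy. Within a frame, the
path advances in 5 sub-steps of i.i.d. Gaussian displacements with
per-axis variance 2·D·dt/substeps.

**Observation.** A frame is visible when the walker's z (wrapped into the
box) is within `z_visible` = 400 nm of the focal plane at the box centre.
Each visible frame emits one xy localization — the sub-step average
(motion blur; the discrete 5-point average corresponds to R = (1−1/25)/6 ≈
0.16) or, optionally, the last sub-step position — plus isotropic Gaussian
error whose per-axis σ rises linearly from 12 nm in focus to 28 nm at the
visibility edge (the two calibration values; linear interpolation is the
simplest model consistent with them). Maximal runs of consecutive visible
frames become distinct observed trajectories, labelled from the hidden
states (`immobile` / `mobile` / `hybrid`). Emitted xy coordinates follow
the *unwrapped* path: the periodic box shapes visibility statistics, but
cutting or wrapping tracks at box boundaries would condition displacements
on "no boundary crossing" and bias the MSD downward (measured at −14% for
the default box), which no real tracker geometry implies.

**Scale defaults.** Box 5×5×2 µm, 120 walkers, 300 frames — chosen to
produce a data set of ≈ 2,000 observed tracks (≈ 600 after the
≥ 5-localization filter) dominated by short mobile fragments, with hybrid
tracks longer on average than mobile ones (their trapped segments hold
them in focus) and a small population of long immobile tracks.

**What is deliberately not modelled:** image formation (PSF rendering,
photon/camera noise, spot fitting), detection failures of in-focus
emitters, linking errors between different walkers, and photophysics
(blinking, bleaching). Consequently the simulator under-produces
fragmented immobile tracks relative to threshold-limited detection, and
contamination of the mobile class arises *only* from classification
errors, not from mis-linked tracks. Passing the pipeline tests therefore
demonstrates correct estimator and classifier behaviour under a clean
noise-and-fragmentation model, not robustness to detection/linking
artefacts of real tracking software.

## Validation choices and problem sizes

The test suite verifies, at sizes chosen to keep the whole run in a few
minutes: estimator identities against brute-force oracles (1000 random
short trajectories; 500 random point sets for the enclosing circle);
containment probabilities at 10⁶ Monte-Carlo tracks; noise-free
parameter recovery (1000 tracks × 50 frames: D within 3 propagated SE and
3% relative; immobile σ within 5%); switching-probability recovery at 10⁶
frame boundaries (±5·10⁻⁴); and minor-fraction recovery (0.04 ± 0.01) by
the k = 2 mixture fit at n = 5·10⁴.

The end-to-end check — simulate, filter, train on 100 randomly drawn
ground-truth-labelled tracks, classify, fit the mobile-class TE-MSD —
is intrinsically noisy at this scale: the mobile-class D of a single
replicate has ≈ 15% spread, dominated by training-sample luck (an
occasional tree leaks long hybrid tracks into the mobile class and the
fit range extends into the flattened long-delay region). The check
therefore averages D over 25 independent replicates, which lands a few
percent below D₂ (immobile-step contamination of the mobile class is
≈ 4% of displacements on average, measurable independently via the
mixture fit). The exact deficit depends on the contamination model; with
linking errors absent it is somewhat smaller than under real tracking.

## Known limitations

- Elongation, entropy and tortuosity follow the declared conventions
  above; other SPT packages use differing definitions, so absolute values
  are not directly transferable.
- The TE-MSD fit range rule (⌈0.25·n_max⌉ shortest delays) ties the range
  to the longest track in the population; for populations with very
  unequal track lengths the J_n weights only partially compensate.
- The mixture fit supports k ∈ {1, 2}; more states require a different
  model-selection strategy.
- 3-D descriptors (bounding spheres) are not implemented; all shape
  analysis is on the xy projection.
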