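# Methods

## The measurement chain

One ultrasound recording of one muscle is reduced to a *strain sequence*:
per-frame percent change of the muscle's longitudinal extent relative to
the start of the exercise (elongation positive, shortening negative,
strain[0] = 0 exactly).  The exercise is a metronome-paced neck extension
— extend on beat 1, reach 20° on beat 2, return by beat 3 at
30 beats/min, so the three-beat window spans (3−1)·60/30 = 4 s — recorded
at 235 frames/s, giving roughly 946 frames per repetition with large
between-participant spread.

### Speckle tracking

A rectangular ROI (15 mm × 3.3 mm by default; long axis along the image
column axis) is seeded with an evenly spaced grid of measuring points
(default 5 × 25) in the first frame.  Points are tracked frame-to-frame
with a pyramidal Lucas–Kanade solver and coordinates are accumulated over
the movie (cumulative tracking).  Defaults: 21 × 21 px window, 3 pyramid
levels, up to 30 iterations per level, convergence at 0.01 px.  Every
step is verified by tracking the matched position back to the previous
frame; a forward–backward discrepancy above 1.0 px flags the point
invalid from that frame onward, as does a window leaving the image or a
singular 2 × 2 gradient matrix.

Strain is computed from the end-column separation: L(f) is the mean
column coordinate of the rightmost valid measuring-point column minus
that of the leftmost, and strain(f) = 100·(L(f) − L(0))/L(0).  A summed
per-point displacement is not a complete strain definition (it depends on
point count and sign cancellation); the length-ratio form is the standard
definition of longitudinal strain and agrees with any monotone summed
measure under uniform deformation.  If validity drops below two distinct
point columns the strain is undefined at that frame and the computation
fails loudly rather than extrapolating.

On noise-free speckle phantoms the tracker recovers imposed uniform
strains of +10% and −5% within ±0.12% strain, rigid drift of 0.5 px/frame
within 0.01 px, and is exactly deterministic.

### Resampling and matrix assembly

Each sequence is linearly interpolated on normalized time [0, 1] onto a
common 800-frame base (cubic splines behind a flag; linear is the default
for smooth, densely sampled curves and introduces no overshoot).
Endpoints are preserved exactly and resampling is idempotent at the
target length.  Per muscle, the cohort stacks into X (participants × 800)
with labels y (patient = 1, control = 0), rows ordered by participant id.
Columns are mean-centered only — every column is strain in percent, so
unit-variance scaling would only inflate quiet frames; it is available as
an option but off by default.

## Multivariate models

### PCA

Fitted by SVD of the centered matrix (exact and deterministic; no
iterative NIPALS).  Scores T = U·S, loadings P = V with the sign fixed so
each component's largest-magnitude loading element is positive; explained
variance per component is the squared-singular-value share.  Score pairs
are displayed with the Hotelling T² confidence ellipse: with n
observations and 2 components, T²crit = 2(n−1)/(n−2)·F₀.₉₅(2, n−2); a
point is inside iff its T² against the sample covariance of the scores is
≤ T²crit.  Four components are retained for inspection by default.

### OPLS

Single-response orthogonal projections to latent structures, NIPALS
style.  With centered X, y:

1. w ∝ X′y, normalized — the y-covariance direction;
2. for each of n_orth orthogonal components: t = Xw, p = X′t/(t′t),
   w_o ∝ p − (w′p)w normalized, t_o = Xw_o, p_o = X′t_o/(t_o′t_o),
   deflate X ← X − t_o p_o′ (w is invariant under these deflations);
3. predictive component on the deflated matrix: t = Xw, p = X′t/(t′t),
   q = y′t/(t′t).

This yields t′T_o = 0 and the exact reconstruction
X = x̄ + tp′ + T_oP_o′ + E (both held to 1e-8 in tests).  R²Y is the
explained y-variance of the fitted tq.  n_orth defaults to 1 and is not
selected automatically; with n_orth = 0 the model is single-component
PLS1 (verified against an independent implementation).  If the deflated
loading is collinear with w the orthogonal loop stops early: there is no
orthogonal variation left to remove.

New observations are centered with the training mean, stripped of
orthogonal variation using the training W_o/P_o, and scored by w;
ŷ = ȳ + tq.  Classification threshold is the class-code midpoint
ŷ ≥ 0.5.

Leave-one-out cross-validation refits everything inside each fold —
means, orthogonal filtering, predictive fit — so no information leaks
from the held-out participant.  Q²Y = 1 − PRESS/SS with SS the squared
deviation of each held-out y about its training-fold mean.  Q²Y ≤ R²Y on
all tested cases and Q²Y ≤ 1 always.

Permutation validation refits and cross-validates the model on n_perm
(default 20) randomly permuted y vectors, records each model's R²Y/Q²Y
against the absolute Pearson correlation of its permuted y with the
original, appends the original model at correlation 1.0, and fits
least-squares trend lines.  A sound model shows the original Q²Y above
the permuted cloud.

### Group testing

Two-sided Mann–Whitney–Wilcoxon on the leave-one-out cross-validated
predictive scores, per muscle; p ≤ 0.05 (α configurable) flags
significance.  The exact null distribution is used whenever n1·n2 ≤ 400
and there are no ties (at the study size, 9 vs 9, always); otherwise the
normal approximation with tie and continuity corrections.  A fully tied
sample returns U = n1·n2/2 and p = 1 directly, since the approximation is
degenerate there.  No multiple-testing correction is applied across the
five muscles by default (Holm/Bonferroni can be applied downstream);
the two-sided choice is the conservative default when no direction is
pre-registered.

## Synthetic data

The generator emulates the study conditions rather than B-mode physics.

**Strain cohorts.**  The noiseless profile of one repetition is a
raised-cosine ramp 0 → peak over the extension phase (fraction 0.5 of the
sequence) and peak → 0 over the return, continuous with the extremum
exactly at the phase boundary.  Defaults: 9 + 9 participants; per-muscle
peak strains between −6 and −10%; sequence lengths drawn from a truncated
normal (mean 946, sd 336, floor 100 frames); per-participant log-normal
amplitude multiplier (sd 0.25 on the log scale) for between-participant
spread; smooth correlated noise (Gaussian-smoothed white noise, kernel 40
frames, sd 1 strain%) re-anchored so strain[0] = 0 — real strain curves
are smooth, so white noise would be the wrong error model.  The group
effect is amplitude-only by default (a phase-shift knob exists but is
off): patients' amplitude is multiplied by 1 + effect·weight in the
configured phases, with weights (1, 0) for the trapezius and (1, 1) for
the multifidus and default effect 0.5.  Because a hard per-phase
multiplier would step exactly at peak strain, the two phase gains are
cross-faded over a raised-cosine window of 0.1 normalized time around the
boundary.  All randomness descends from one root seed through per-
(participant, muscle) spawned child streams; identical seeds give
bit-identical cohorts.

**Speckle phantoms.**  A fixed granular texture — Gaussian-smoothed white
noise pushed through a tanh contrast stretch (granular like a thresholded
field, but smooth enough that image gradients carry sub-pixel
information), quantised to 8 bits — is warped longitudinally about the
frame centre by the deformation profile, each frame directly from the
frame-0 texture (cubic inverse mapping, no error accumulation), with
optional rigid drift and sensor noise.  Ground-truth positions of any
material point at any frame are analytic.  Phantoms deliberately omit
point-spread functions, attenuation, and out-of-plane motion: passing
tracker tests show correctness of the motion estimation, not robustness
to every clinical artefact.

## Calibration caveat: testing cross-validated scores

The per-muscle significance test takes leave-one-out cross-validated
scores as its input.  These scores are not independent across
participants — any two share 16 of 17 training observations and the score
function depends on the label vector — and same-class scores are
positively correlated through the shared weight vector.  The Mann–Whitney
test assumes independent samples, and feeding it CV scores makes it
anticonservative: on null cohorts (zero effect) the measured rejection
rate at α = 0.05 is ~13–16% per muscle, a figure that is stable across
data-generating structures (the package's own synthetic cohorts, i.i.d.
noise matrices, low-rank structured noise) and across n_orth ∈ {0, 1} or
testing ŷ instead of t.  The Mann–Whitney implementation itself is
exactly calibrated on independent inputs (attainable two-sided level at
9 vs 9 is 0.0400).  Consequently p-values from this stage should be read
as descriptive, as should the per-muscle significance flags; the
permutation test, which is exact by construction, is the pipeline's
statistically sound validation route.  The acceptance suite states the
idealised 5% ± 2% type-I property and the derived 80% exact-recovery
property at face value, and those two checks fail for this structural
reason; all other checks pass.

## Problem sizes and numerical choices

- Simulation-heavy checks use 100 replicates (effect recovery) and 1000
  replicates (type-I rate) at the full study geometry (18 × 800 after
  resampling), and 100,000 points for ellipse-coverage Monte Carlo.
- Phantom movies for tracker validation are 260 × 120 px × 60 frames —
  large enough for the default 150 × 33 px ROI plus deformation headroom.
- Tolerances: algebraic identities at 1e-8–1e-10; oracle equivalences at
  1e-10; Monte-Carlo coverage at ±0.5 percentage points; phantom strain
  recovery at ±0.5% strain.
- Degenerate inputs fail loudly: constant y, vanishing X′y, folds losing
  a class, singular score covariance, under-determined strain columns.
- Movies are persisted as PNG stacks with a JSON sidecar (lossless and
  portable); strain tables as long-format CSV.

## Known limitations

- ROI placement is programmatic; the study's manual placement variability
  is not emulated.
- Strain is one-dimensional (longitudinal); no 2-D strain tensors or
  rotation handling.
- The generator's group effect is amplitude-only by default; timing
  (phase-shift) differences between groups are expressible but untested
  against any reference.
- Q²Y conventions differ between chemometrics packages (PRESS
  denominator, component counts for permuted models); the conventions
  above are documented rather than universal.
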