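# Methods

This note documents the models, numerical choices and limitations behind
`capdet`, in the spirit of a package methods appendix.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Filter design

**Problem.** Among real orthogonal two-channel filter banks of even length
*L* whose highpass has *p* vanishing moments, find the lowpass *h* with the
smallest mean-squared (RMS) bandwidth

B²(h) = (1/2π) ∫_{−π}^{π} ω² |H(ω)|² dω.

Orthogonality constrains only the autocorrelation
r[k] = Σ_n h[n] h[n+k]: r[0] = 1, r[2k] = 0 for k ≥ 1, and
R(ω) = r[0] + 2 Σ r[k] cos ωk = |H(ω)|² ≥ 0.  Using
(1/2π)∫ ω² e^{−jωk} dω = 2(−1)^k/k² (and π²/3 at k = 0), the objective is
*linear* in r:

B² = (π²/3) r[0] + 4 Σ_{k=1}^{L−1} (−1)^k r[k]/k².

**Convex formulation.** The vanishing-moment condition is a zero of order
2*p* of R at ω = π.  We factor it out exactly: R(ω) = ((1+cos ω)/2)^p Q(ω)
with Q a cosine polynomial of degree L−1−p, which makes the moment
conditions structural and reduces spectrum nonnegativity to Q(ω) ≥ 0.  All
remaining constraints and the objective are linear in Q's coefficients, so
the problem is solved as a linear program (HiGHS, deterministic, no random
initialization) with the semi-infinite constraint Q(ω) ≥ 0 sampled on
16 385 equispaced points of [0, π] and re-verified on a 16× denser grid.
This grid discretization of the nonnegative-trigonometric-polynomial cone
was chosen over a Gram-matrix positive-semidefinite parameterization
because it needs only a linear-programming solver, is deterministic, and
its discretization error (O((π/n_grid)²) between-grid dips) is absorbed by
the factorization step below; the two formulations describe the same
convex set up to that error.

**Spectral factorization.** h is recovered from the optimal r by root
splitting with the minimum-phase convention: zeros of the spectrum
polynomial strictly inside the unit circle are kept, reciprocal partners
outside discarded.  Zeros at z = −1 (the vanishing-moment factor) are
deflated analytically before root finding and re-attached as an exact
binomial factor ((1+z)/2)^p, so the moment structure survives at machine
precision instead of being smeared across a multiplicity-2p root cluster.
Other unit-circle zeros of a nonnegative spectrum occur with even
multiplicity; they are clustered by angle and half of each cluster is kept
at the mean angle, which simultaneously projects tiny between-grid
negative dips back onto the nonnegative cone.  A final Gauss–Newton
projection (minimum-norm steps onto the constraints Σ h[n]h[n+2k] = δ[k],
Σh = √2, and the p moment conditions) removes the residual O(1e−8)
orthogonality defect; without it, the defect compounds over five
decomposition levels and perfect reconstruction degrades to ~5e−8.  The
√2 normalization and the projection are applied only when the
autocorrelation implies R(π) = 0 (i.e. Σh² = 1 with R(0) = 2); factorizing
a generic nonnegative spectrum leaves the scale that r dictates.

**Tolerances.** LP equality constraints hold to solver precision (~1e−10);
verification tolerances are 1e−8 for autocorrelation invariants, 1e−6 for
filter-bank invariants and moment counting, 1e−5 for the factorization
round trip (double-precision root finding on degree-14 polynomials limits
what is attainable before the projection step).  For L = 12, p = 4 the
designed bank reaches B² = 0.8679 vs 0.9056 for the length-12 Daubechies
and Symlet filters (equal by construction, since B² depends only on |H|²),
and its orthogonality defect is at machine precision after projection.

## Decomposition

Dyadic analysis uses circular (periodic) extension, which keeps the
transform orthonormal on epochs whose length is divisible by 2^levels and
gives exact subband lengths N/2, …, N/2^J, N/2^J.  Analysis is the
correlation convention a[n] = Σ_k h[k] x[(2n+k) mod N]; this differs from
PyWavelets' periodized convolution by a fixed (L−2)/2-sample read offset
per level (verified in the tests).  Parseval and perfect reconstruction
hold to 1e−8 by orthonormality.

The printed subband ladder (0–1 … 16–32 Hz) corresponds to a 64 Hz signal,
while the recordings of interest are sampled at 512 Hz; the pipeline
therefore resamples to 64 Hz (polyphase, anti-aliased) before the
five-level decomposition.  An alternative reading — an eight-level
decomposition at 512 Hz keeping the lowest six subbands — would produce
the same nominal bands at eight times the cost; the resampling route was
chosen because the discarded 32–256 Hz content is outside the 0.5–35 Hz
bandpass anyway.

## Preprocessing

Fixed order: bandpass → normalize → resample → segment.  The Butterworth
bandpass (0.5–35 Hz, order 4) is applied forward-backward; zero-phase
filtering avoids distorting the morphology of phase-A transients at the
cost of squaring the magnitude response (effective order 8), which is
documented rather than hidden.  Min-max normalization to [0, 1] is per
channel per recording — not per epoch — because the classifier's main cue
is the amplitude contrast between phase-A bursts and background, which
per-epoch scaling would erase.  For standalone epoch sets (the synthetic
path) the same role is played by one global min-max per channel across the
set.

## CAP rules

The rule engine implements: merge successive A phases separated by
< 2 s (strict, iterated to fixed point); phase durations valid in
[2, 60] s; inter-A gaps become B phases; a gap > 60 s or an out-of-range
duration breaks the chain; chains with ≥ 3 A phases become CAP sequences
running from the first A's onset to the terminal A's end; isolated A
phases are non-CAP.  CAP rate = CAP time / NREM time.

Two deliberate separations: (a) for *classification*, phase B is "all NREM
time not labelled A" — the standard shortcut for building balanced epoch
sets — while strict inter-A B phases are used only for CAP parameters;
(b) expert A annotations with durations outside [2, 60] s are kept for
classification labelling (the expert label wins for the ML task) but act
as chain breakers in sequence building.  A-subtype labels (A1/A2/A3)
collapse to one class.  Epochs tile each labelled interval from its onset
(maximizing use of 2 s minimum-duration A phases); trailing partial
windows are dropped; REM and wake are excluded.  Isolated phase-A events
remain in class A for classification: they are expert-labelled
activations, and excluding them would have to be justified on grounds the
annotation itself does not provide.

## Features

Wavelet entropy is computed literally as −Σ|cᵢ| log|cᵢ| with natural log
and 0·log 0 = 0 — on raw coefficient magnitudes, without normalizing them
to a probability distribution.  A normalized variant (pᵢ = |cᵢ|/Σ|cⱼ|) is
provided but off by default; the unnormalized form is the one the feature
set is defined with, and the log base only rescales features that the
classifier consumes scale-free.  Hjorth derivatives are first differences
without sampling-rate scaling (the fs factors cancel in mobility and
complexity; activity is fs-free); variance is the population variance.
Degenerate (constant) subbands yield mobility/complexity 0 with a warning
instead of NaN so classifiers never see non-finite values.  Kruskal–Wallis
ranking uses the tie-corrected H with a χ²(1) p-value; ranks are ascending
in p with ties broken by descending H, then feature index.

## Synthetic generator

The generator emulates only the amplitude/spectral structure that the
detection problem relies on: phase B is band-limited (0.5–35 Hz) 1/f^β
Gaussian background with unit RMS (β = 1 by default, slope recoverable
from Welch fits to ±0.3); phase A adds either a raised-cosine-windowed
0.5–4 Hz burst or (probability 0.2) a biphasic ~0.8 s K-complex-like
transient, at amplitude (amp_ratio − 1) × background RMS, so amp_ratio = 1
reduces exactly to the null case of identically distributed classes.  The
two channels share 50% background variance, enough to make combined-channel
features correlated but not redundant.  Defaults: fs 512 Hz, 2 s epochs,
1000 epochs/class for the recovery experiment, amp_ratio 5 for the
separable preset.  What passing tests show is that the pipeline recovers
class structure planted in the delta band at realistic epoch counts — not
that it reaches any particular accuracy on clinical recordings: real EEG
has artifacts, inter-subject variability, stage-dependent background and
far subtler A/B contrast.

## Classification and evaluation

Classifier presets mirror common toolbox defaults: bagged trees (30
unpruned trees), AdaBoost (30 trees, depth ≤ 20, learning rate 0.1), RBF
SVM, kNN (k = 10), logistic regression, single decision tree — all
configurable, all seeded.  Cross-validation is sample-wise stratified
k-fold (default 10) with per-fold predictions pooled into one confusion
matrix (matching how single confusion matrices are conventionally
reported); fold assignment and model fitting take separate seeds.
Sample-wise CV shares subjects between folds; subject-wise CV is the
stricter protocol for clinical claims and is not what these numbers mean.
Leave-one-out (k = n) falls back to unstratified folds, since a singleton
test fold cannot be stratified.  AUC is the rank (Mann–Whitney) statistic
with midranks.  For balanced binary data the pooled metrics satisfy
κ = 2·ACA/100 − 1 exactly, which the tests exploit as a consistency check.
Metric arithmetic from column-normalized confusion matrices renormalizes
each column (tolerating printed columns off by ≤ 0.5) and weights columns
by class priors for precision and κ.

## Known limitations

- No artifact rejection, notch filtering or montage derivation; the EDF
  reader takes channels as stored.
- A-subtype (A1/A2/A3) classification and per-hour subtype statistics are
  out of scope.
- The EDF writer is a minimal 16-bit encoder (one-second records, one
  sampling rate) intended for synthetic exports, not a general-purpose
  EDF+ implementation.
- Filter lengths beyond L ≈ 40 are untested territory for double-precision
  spectral factorization and are rejected as unsupported rather than
  attempted.
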