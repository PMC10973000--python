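# Methods

## Detrended cross-correlation analysis

For two equal-length series and a scale *s* (samples), every window of *s*
consecutive values is independently detrended by an ordinary-least-squares
line fit (two parameters; higher orders are out of scope), and the
covariance of the residual pair is formed with a 1/(s−1) normalisation.
Windows are either *sliding* (step one sample, K = N − s + 1 windows) or
*non-overlapping* (K = floor(N/s)). Window averages use the 1/(K−1)
convention; this is a pure scale factor — it cancels in the detrended
cross-correlation coefficient and under trace normalisation of feature
matrices — and with a single window (N = s, sliding) the divisor is taken
as 1, where the convention would otherwise be undefined. The optional
profile step (cumulative summation before windowing) is **off** in the
classification path, which detrends the native band-passed EEG, and **on**
in the DFA path.

Applied pairwise to an n-channel epoch the procedure yields the Gram matrix
of the flattened residual windows, hence a symmetric positive semi-definite
matrix; strictly rank-deficient inputs (e.g. duplicated channels) are
repaired by adding `ridge × mean(diagonal)` to the diagonal (default ridge
1e−10, scaled up if needed to clear zero at double precision), and every
repair is reported through a warning and the optional info dict — silent
repair would mask broken preprocessing. A channel with zero detrended
variance (constant or exactly linear) raises instead: no covariance
structure exists at that scale.

### Streaming form

With fixed *s* the detrending projector M = I − H (H the hat matrix of the
[1, t] design) is constant, and each window's detrended cross-covariance
is x′My = Σxy − [Σx, Σtx] (DᵀD)⁻¹ [Σy, Σty]ᵀ. The stream therefore keeps,
per channel, the running window sums Σx and Σtx, and per channel pair the
window cross-product Σxy, all updatable in O(1) per sample from a ring
buffer of the last *s* samples; each new sample completes one new sliding
window whose contribution is accumulated. The emitted matrix after n
samples equals the batch sliding computation on the same n samples up to
round-off (tested at 1e−8 relative Frobenius over random packet sequences).
Memory is O(n_channels × s + n_channels²), independent of stream length.

### DFA and DCCC

The DFA exponent is the slope of log F(s) against log s (natural logs; the
slope is base-invariant) over at least three scales, with F(s) the
root-mean-square detrended fluctuation of the integrated series;
non-overlapping windows are the default for DFA, matching the classic
estimator. The DCCC divides the cross term by the two self-fluctuations.
For sliding or non-overlapping windows this is a normalised inner product
of residual vectors, so |DCCC| ≤ 1 holds up to round-off; overshoot beyond
1e−10 is treated as an error rather than clipped.

## Riemannian decoding

Matrix square roots, logarithms and powers are evaluated through symmetric
eigendecomposition with an eigenvalue floor of 1e−12 (relative to the
largest eigenvalue), which keeps the maps stable on near-singular inputs.
The AIRM distance is computed in the congruence-symmetric form via the
generalized eigenvalues of the pair, mathematically equal to
‖log(P₁⁻¹P₂)‖_F. The Karcher mean uses the standard fixed-point iteration
(step size 1, tolerance 1e−8 on the mean tangent norm, at most 50
iterations) from the arithmetic-mean initialisation; failure to converge
raises an error carrying the last iterate. These settings converge reliably
at EEG-scale condition numbers.

MDM stores per-class Karcher means; ties in the distance comparison break
to the first class in sorted label order. Because the online protocol needs
a probability, distances are mapped through a softmax over their negatives
(temperature 1) — any monotone map preserves the decision rule; softmax is
bounded and smooth.

Sample covariance features use the Ledoit–Wolf analytic shrinkage toward
(tr S / n) I, guaranteeing positive definiteness even with fewer samples
than channels. Trace normalisation is applied by default to **both** SCM
and DCCA features: beyond its usual role for SCMs it removes the window
normalisation convention from DCCA features, so results do not depend on
the 1/(K−1) choice.

### Recentering

Offline recentering conjugates every matrix by R^{−1/2} with R the Karcher
mean of the set; the recentred set then has identity Karcher mean, and all
pairwise AIRM distances are preserved. The adaptive (causal) variant keeps
a running reference: the default rule recenters the first test matrix with
the training reference and then resets the reference to that matrix, after
which each incoming matrix C_i is recentred with the current reference
before the reference moves toward C_i along the geodesic with step
1/(i−1). A `running_mean` variant instead starts at the training reference
and uses step 1/i throughout. The published update rule is ambiguous at
i = 2 (its cases overlap); the reset reading is the default and both
variants are implemented and tested. Recentering always happens before the
reference update, so no output depends on later epochs.

## Preprocessing

Offline: 3rd-order Butterworth band-pass 8–30 Hz applied forward–backward
(zero phase, effective order doubled) with odd (point-symmetric) reflection
padding of length min(N−1, 10·rate/low_hz); the generous padding is what
makes the operator symmetric under time reversal to high accuracy and
avoids in-band leakage from padding discontinuities. Online: 2nd-order
causal Butterworth from zero initial state, with filter state carried
across packets so packet-wise filtering equals one-shot filtering exactly.
Epochs are 1 s with a 62.5 ms step (32 samples at 512 Hz, 10 at 160 Hz),
0-based and half-open in samples; non-integer sample steps are an error
rather than rounded. The EOG gate rejects an epoch only when the absolute
amplitude *strictly* exceeds 320 µV.

## Trial protocol and metrics

Evidence accumulates as p ← (1−α)p + α·p_inst with α = 0.05, from 0.5 at
trial start, one update per 62.5 ms. A command is delivered at the first
strict threshold crossing (per-class thresholds, default 0.7 — in practice
they were experimenter-tuned per run, and neither sample-wise nor
normalised command metrics depend on them); otherwise the trial times out
at 7 s (112 updates) and the final bar direction is recorded. A bar exactly
at 0.5 counts as *not* toward the truth for bar dynamics and as an error
for timeout-inclusive accuracy (conservative convention). The smoothing
recursion treats the right-hand probability as the instantaneous classifier
output; any other reading would make the recursion vacuous.

Cohen's κ uses marginal-product expected agreement; κ_norm multiplies the
completed-trial κ by the non-timeout fraction, so κ_norm ≤ κ with equality
iff no timeouts. Chance levels are k*/n with k* the smallest integer whose
binomial CDF at accuracy 1/n_classes reaches 1 − 0.001. Group contrasts:
Friedman across ≥ 3 paired pipelines (identical columns short-circuit to
statistic 0, p = 1), pairwise Wilcoxon signed-rank (exact for n ≤ 25
without zeros, normal approximation otherwise; an all-zero difference
vector is undefined and, inside the group routine, contributes p = 1),
Benjamini–Hochberg step-up adjustment, and per-column Lilliefors flags.

## Post-hoc analyses

DCCC networks are per-epoch coefficient matrices averaged within subject
and class (diagonal 1 by construction). Class contrasts run per connection:
Lilliefors on the paired differences at 0.05 routes to the paired t-test
(normal) or Wilcoxon (otherwise; with fewer than 4 subjects the screen is
not computable and the t-test is used); significance is unadjusted at 0.05
— exploratory by design. Significant connections are partitioned by the
group-mean coefficient signs into positive-in-both, negative-in-both, and
sign-flip categories. DFA topography applies the same machinery to
per-channel exponents (dyadic scales 16–256, profile step on).

## Synthetic data

The generator reproduces the statistical structure the decoder assumes, not
the biophysics. Defaults: 22 sensorimotor channels at 512 Hz, four runs of
20 trials (10 per class, shuffled), 5-s active trials with 2-s rest gaps.
Each trial is band-limited (8–30 Hz) Gaussian noise — not sinusoids, which
would give degenerate covariance — coloured by a class template: a common
random well-conditioned correlation matrix with the variance at C4 (left
imagery) or C3 (right imagery) halved, emulating contralateral ERD. The
background is fractional Gaussian noise (H = 0.7, circulant-embedding /
Davies–Harte simulation, exact autocovariance) mixed across channels at
half the oscillation RMS. Local non-stationarities are per-channel random
cubic polynomials spanning each trial at twice the oscillation RMS: trends
that whole-epoch covariance absorbs but 0.25-s local detrending removes.
Between-session shifts apply x → Wx with W = exp(S), S random symmetric
with ‖S‖_F = 0.3. All outputs are deterministic under the spec seed.

What passing tests therefore show: the decoder chain is correct and the
DCCA feature is robust to exactly the nuisance family it targets
(polynomial trends, covariance shifts). What they do not show: performance
on real EEG, where artifacts are not polynomial, ERD has temporal
structure, and volume conduction correlates everything.

## Problem sizes in the test suite

The acceptance-style checks run reduced study conditions chosen as the
package's own test scale: the drift-robustness comparison uses an
8-channel montage, one 20-trial run per session and a 0.25-s epoch step
over 20 generator seeds; the contrast-calibration check uses 4 channels, 8
paired subjects and 50 repetitions; DFA recovery uses 200 replicates of
length 4096. The headline command-delivery quantities are recomputed by
replaying the full 100-trial protocol per reported subject.

## Known limitations

- Polynomial detrending is linear only; no multiscale DCCA feature tensors.
- The MDM probability map is a modelling choice; calibrated probabilities
  are not claimed.
- The EDF writer targets the minimal 16-bit EDF subset (integer sampling
  rates, one-second records, no annotation channel); exact round-trips use
  the plain-text fixture format.
- Wall-clock per-update cost of the streaming feature is logged by the CLI
  replay but never asserted — it is hardware-dependent.
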