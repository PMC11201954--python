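# Methods

This note documents the models, estimators and numerical choices behind
`mdte`, the assumptions they rest on, and what the synthetic benchmark
does and does not demonstrate.

## Signal model and preprocessing

A `Recording` is a channels × samples matrix in microvolts with a known
sampling rate (512 Hz by default) and authoritative channel order; no
electrode-geometry information is used anywhere. Preprocessing follows a
fixed chain — baseline (per-channel mean) correction, common average
reference, zero-phase filtering, ICA, epoching — and every step before
epoching preserves shape and sampling rate.

Filters are a 4th-order Butterworth band-pass (0.5–60 Hz) and a
second-order IIR notch at 50 Hz with Q = 30, both run forward–backward
(`filtfilt`). Zero-phase filtering was chosen so that epoch boundaries are
not skewed by group delay; the cost is an effective doubling of the filter
order, which the attenuation tests account for. Trailing samples that do
not fill a 2 s window are dropped, not padded — padding would fabricate
data at the recording edge.

## ICA

The mixture model is `X = AS` with statistically independent sources.
Estimation splits into PCA whitening `Z = Q(X − mean)` (eigendecomposition
of the sample covariance) and an orthogonal rotation `B` found by
symmetric fixed-point iteration with the tanh contrast, maximizing
non-Gaussianity; the demixing matrix is `W = BᵀQ`. The symmetric (parallel)
update was preferred over deflation because it makes no component-order
choices and is deterministic given the seed of the random orthogonal
initialization.

Two practical points:

- **Rank after CAR.** Common average referencing leaves the data on an
  exact (channels − 1)-dimensional subspace, so the pipeline whitens to
  channels − 1 components. Full-dimension whitening retains its strict
  contract and rejects rank-deficient input.
- **Convergence.** Band-passed EEG background is close to Gaussian, so
  many rotation directions are weakly identifiable and the symmetric
  iteration may oscillate without meeting a tight tolerance. `fit_ica`
  raises on non-convergence by default; the pipeline uses the `warn` mode
  (200 iterations, tolerance 1e−5) and proceeds with the last iterate,
  whose decomposition invariants (orthogonal `B`, `W = BᵀQ`,
  `W·A_hat = I`) hold regardless. When every component is near-Gaussian
  (|excess kurtosis| < 0.5) the rotation is unidentifiable in principle
  and only a warning is ever issued.

Artifact components are selected automatically as those with sample excess
kurtosis above 5.0 (configurable, with a manual override list): ocular
transients are sparse and heavy-tailed, background EEG components are
near-Gaussian, so excess kurtosis separates them cleanly on both simulated
and typical real data. Reconstruction zeroes the rejected source rows in
`A_hat · Y` and restores channel means.

## Discrete fractional Fourier transform

The order-p FrFT rotates the time–frequency plane by α = pπ/2. The
discretization builds the commuting Dickinson–Steiglitz matrix `S`
(tridiagonal plus corner terms), diagonalizes it separately on the even-
and odd-symmetric invariant subspaces (preventing near-degenerate
eigenvalues from mixing DFT eigenvalue classes), assigns discrete Hermite
indices (0…N−2 and N for even N), and forms
`F^p = U · diag(exp(−iπpk/2)) · Uᵀ`.

This construction was chosen over chirp-based O(N log N) approximations
because the defining properties — unitarity, order additivity, period 4,
inverse at −p, exact reduction to the DFT at p = 1 and to parity at
p = 2 — hold to machine precision and are therefore machine-verifiable.
The O(N²) application cost is acceptable at the epoch length used
(N = 1024); operators are cached per (N, p). Order p ≡ 0 (mod 4) returns
the exact identity so the time-domain representation equals |epoch|
bit-for-bit. No windowing taper is applied before the transform.

Per epoch, the absolute amplitudes at p ∈ {0, 0.5, 1} form the three
domain representations; amplitudes are kept rather than complex
coefficients so all downstream quantities are real and sign-free.

## Transfer entropy

TE(J→I) is estimated in the standard history-k form with one-step horizon
(defaults k = 1, lag = 1): the reduction in conditional entropy of the
target's next symbol when the source's history is added. Probabilities are
plug-in (maximum likelihood) over discretized sequences; entropies are in
bits.

Discretization is equal-frequency binning with 8 symbols. Each distinct
value maps to the bin containing the midpoint of its empirical-CDF mass,
which makes the symbol map deterministic, invariant under monotone
rescaling (important because FrFT amplitude scales differ by orders of
magnitude across domains), and correct for heavily tied data (a discrete
uniform over 8 values maps one-to-one onto the 8 symbols). k = 1 keeps the
joint alphabet at 8³ = 512 cells, which a 1024-sample epoch can populate;
larger k would starve the histogram. Tiny negative plug-in estimates are
clamped to zero (logged if below −1e−9). Sequences must exceed
k + lag + 10·bins samples.

Per epoch and domain, all ordered channel pairs share one symbolization
pass; the 32 × 32 matrices (zero diagonal, generally asymmetric) are
horizontally cascaded in domain order into the 32 × 96 connectivity image.
Estimator quality is checked against three independent oracles: the
deterministic-copy pair (TE = source entropy ≈ log₂ 8), a 200-shuffle
permutation null for independent pairs, and the Gaussian Granger closed
form ½·log₂(σ²_reduced/σ²_full) computed by least squares on simulated AR
pairs.

## PCANet

Two stages of PCA-filter convolution with 3 × 3 patches and 9 filters per
stage (the complete patch eigenbasis — the only reading of a 9 × 9 filter
bank consistent with 3 × 3 patches), followed by binarization, bitwise
hashing and block histograms:

- Patch sampling is dense (one patch per pixel over a zero-padded image,
  so the count is exactly m·n) with per-patch mean removal. Mean removal
  nulls the DC direction, so one zero eigenvalue of the patch scatter is
  structural; the corresponding ninth filter is the (unique up to sign)
  orthonormal completion. A degeneracy warning is only raised when the
  deficiency exceeds this structural one (e.g. all-zero inputs).
- Eigenvector signs are fixed deterministically (largest-magnitude element
  positive), so fitted models are identical across runs and platforms.
- Stage-2 filters are learned from one scatter pooled over all stage-1
  maps of all training images, giving a single shared stage-2 bank.
- Hashing: stage-2 map l contributes bit 2^(l−1) where strictly positive
  (zero maps to bit 0), giving integer maps in [0, 2^9 − 1].
- Block histograms: 32 × 32 blocks advance with stride
  block·(1 − overlap) = 16; a final flush-to-edge block is added when the
  stride does not align (not the case at the 32 × 96 default, which gives
  exactly 1 × 5 blocks). Feature length is L1 · 2^L2 · B = 23,040.

Every stage is verified bit-for-bit (integer stages) or to 1e−8 (real
stages) against a literal nested-loop transcription kept in the test
suite, and the learned filters against a dense SVD.

## Classification and evaluation

Linear-kernel SVM with C = 2; multi-class handled by one-vs-one voting.
Features are standardized with training-fold statistics — histogram counts
have large dynamic range and unscaled margins would be dominated by
high-count bins. Cross-validation is stratified 10-fold with a seeded
shuffle; the PCANet filter banks, the scaler and the SVM are all refitted
inside each fold on training data only (a monkeypatch-based test asserts
the filter learner never sees test-fold images). Binary sensitivity/
specificity refer to the designated stress class; with three classes both
are macro-averaged one-vs-rest rates, since single Sen/Spe values are
otherwise undefined.

## Synthetic data generator

Each state is a stable VAR(2) process: the diagonal carries per-channel
resonant AR(2) backgrounds (pole radius 0.95, peak frequencies spread over
6–20 Hz, emulating band-limited EEG rhythms), and the off-diagonal lag-1
terms carry the state's directed coupling. The benchmark states differ in
*which* 12 disjoint channel pairs are coupled (gain 0.8); because each
state's graph is a union of single directed edges with no feedback loops,
stationarity holds for any gain below 1, and it is verified via the
companion-matrix spectral radius before simulation. On top of the VAR
signal the generator adds a 50 Hz sinusoid (5 µV, random phase per
channel), Poisson-timed ocular-type transients (raised-cosine bumps of
0.33–2 s, 5–10× the background SD, on the first 4 "frontal" channels, 6
per minute) and white sensor noise (0.5 µV SD). Durations default to
5 minutes per state — the length of one resting/task recording block —
giving 150 non-overlapping 2 s epochs per state. One global seed drives
all randomness through per-state substreams derived from the state's
index, so output is bit-reproducible.

What the generator does *not* emulate: volume conduction and the mixing of
cortical dipole sources across electrodes, 1/f broadband structure beyond
the AR(2) resonances, non-stationary artifact regimes, or inter-subject
variability. Consequently a high benchmark accuracy shows that the
pipeline detects state-dependent directed-coupling differences end to end
— it does not predict accuracy on real recordings, where class differences
are weaker and confounded.

## Benchmark sizes and determinism

The end-to-end benchmark uses two states × 300 s × 32 channels (150 epochs
each), 10-fold CV, and a label-permutation control; the ablation compares
the three single-domain 32 × 32 images against the cascaded 32 × 96 image
under identical fold assignments. Component oracles run at 10⁴ samples
(TE, ICA) and N = 1024 (FrFT). With a fixed config and seed the entire
pipeline — simulation, ICA, folds, filters, SVM — reproduces its
evaluation report byte-for-byte.

## Known limitations

- The plug-in TE estimator is biased upward by finite sampling
  (≈ (cells)/(2N ln 2)); comparisons across conditions with equal epoch
  lengths are unaffected, absolute values should not be over-interpreted.
- Computing TE on frequency-domain amplitude sequences treats the
  frequency index as the "time" axis of the information flow; this is the
  method's design, not a physical claim about spectral causality.
- The eigenbasis FrFT costs O(N²) per transform and O(N³) once per length;
  epoch lengths beyond ~8k samples would need the chirp-based
  approximation the package deliberately omits.
- ICA component rejection is kurtosis-only; rhythmic (e.g. muscle-tone) or
  low-kurtosis artifacts would not be flagged automatically.
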