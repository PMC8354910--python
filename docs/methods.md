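# Methods

This note records the modelling assumptions, numerical conventions and
design decisions behind the package, in the spirit of a methods appendix.

## Study design encoded in the generator

A simulated subject consists of `n_sessions` movement-task sessions and one
resting run. A task session is a block design: one leading 18 s rest block,
then eight 18 s task blocks (four wrist, four finger, alternating), each
followed by an 18 s rest block — 17 blocks × 6 scans at TR 3 s = 102
volumes (306 s). Odd-numbered sessions begin with the wrist task and
even-numbered sessions with the finger task, so block position and class
are counterbalanced across sessions. The resting run has 200 volumes at the
same TR. These counts are design constants surfaced in `SimConfig` /
`DEFAULT_CONFIG` and are what the count-checking tests pin down.

### Spatial patterns

The two class patterns are unit-Euclidean-norm voxel vectors built from two
i.i.d. Gaussian draws by mean-centred orthogonalisation and remixing, so
their Pearson correlation equals the requested `pattern_overlap` *exactly*
(default 0). Because both patterns are zero-mean and unit-norm, overlap 0
also means exactly orthogonal, which keeps the latent-process recovery
tests clean. There is no 3-D geometry: all downstream operations are
permutation-covariant in the voxel index, so a flat index loses nothing.

### Task signal

Per-scan amplitude is an 18 s boxcar convolved with a canonical
double-gamma haemodynamic response (gamma shape 6 minus gamma shape 16
divided by 6, sampled at the TR, peak normalised to 1). No GLM is fitted
anywhere in the pipeline, so the analysis is insensitive to the exact HRF;
the kernel is a fixed documented constant, not a parameter.

### Resting signal: the mixture assumption

Resting scans are generated as

    x(t) = rc_amplitude · (a_w(t)·p_w + a_f(t)·p_f)
         + nuisance_gain · (confound series · random loadings)
         + noise_sd · ε(t),

where `a_w, a_f` are independent zero-mean unit-variance processes obtained
by low-pass filtering white noise (4th-order Butterworth, 0.08 Hz cut-off,
zero phase), so ≥ 95 % of their power lies below 0.1 Hz — inside the
analysis band-pass. `rc_amplitude = 0` yields an exact task-irrelevant null
world. With unit-norm patterns over `n` voxels and per-voxel noise SD σ,
the per-scan correlation between data and pattern is approximately
`rc·a / sqrt(rc²·a² + n·σ²)`; at the defaults (n = 200, σ = 1) an amplitude
of rc ≈ 10 puts the typical scan–pattern correlation near 0.5, which is the
"strong" level used in the power checks.

### Nuisance processes

Motion parameters are scaled Gaussian random walks; CSF/WM/global-signal
are slow sinusoids (periods 40–120 s, random phase) plus 20 % white noise.
These shapes are plumbing: only their removal matters. They couple into the
voxel signal through a random 9 × n loading matrix scaled by
`nuisance_gain` (default 0.5).

### What the generator does not emulate

No spatial autocorrelation, scanner drift/spike artefacts, motion-induced
spatial shifts, physiological aliasing, or inter-subject anatomical
variability. Passing tests therefore demonstrate the *logic* of the
pipeline (calibration, power, equivalences) under the stated mixture
assumption, not robustness to real-scanner nuisance structure.

## Temporal preprocessing

* Confound design: for each of the nine base series the design carries the
  series, its temporal derivative, its square, and the derivative's square
  (36 columns). The derivative is a first-order backward difference with a
  leading zero, preserving length. Each confound column is divided by its
  maximum *absolute* value (sign-preserving; a plain maximum would break
  for negative-dominated series); all-zero columns stay zero. Trend model:
  one constant column plus one linear ramp scaled to [−1, 1].
* Removal is least-squares via the pseudoinverse, so duplicated or zero
  columns are harmless; residuals are orthogonal to the design and the
  operation is idempotent.
* Band-pass (resting runs only): Butterworth of order 4 designed on the
  0.010–0.10 Hz band, applied forward–backward (`sosfiltfilt`) for zero
  phase; the effective magnitude response is the square of the single-pass
  response (transmission ≥ 0.9 at 0.05 Hz and ≤ 3·10⁻⁶ at 0.15 Hz for
  TR 3 s). The passband is validated against the Nyquist frequency and runs
  must exceed 6 × order samples.
* Resting order of operations: demean → band-pass → regression, with the
  confound series passed through the *identical* filter before the
  regressor expansion. Filtering the regressors identically prevents the
  regression from reintroducing frequencies the filter removed. Task runs
  get regression only (no band-pass).
* A practical consequence measured on synthetic data: fitting the 38-column
  design to a 102-scan session removes a small, block-dependent share of
  task signal by chance correlation, which caps leave-one-session-out
  accuracy a few points below 100 % even at extreme SNR. The decoder itself
  is exact: on raw high-SNR runs cross-validated accuracy is 1.0.

## Decoder

Trial patterns: per task block, drop the first 2 scans (haemodynamic lag
carries the previous state into early scans), unit-normalise each remaining
scan, average. Normalising scans rather than trials keeps task and resting
scans on a common scale, which matters when the decoder is later applied
across states.

The model is binary logistic regression with an L2 penalty on the weights
(bias unpenalised), Finger coded as the positive class. The objective
`Σ log(1+exp(−yᵢ(xᵢ·w+b))) + (λ/2)‖w‖²` is minimised by L-BFGS with an
analytic gradient to a gradient norm ≤ 10⁻⁶; scikit-learn's
`LogisticRegression(C=1/λ)` minimises the same objective and serves as an
independent cross-check in the tests, never as the implementation. λ
defaults to 1.0, appropriate for trial patterns whose norms are ~0.5 (means
of 4 unit-norm scans); predictions are invariant to jointly rescaling
patterns by c and λ by c². Prediction ties at probability 0.5 go to Wrist
(fixed, arbitrary). Accuracy is assessed by leave-one-session-out CV
(training and test session ids asserted disjoint per fold); paired accuracy
comparisons against a control region use the two-sided Wilcoxon signed-rank
test with Bonferroni correction over 8 regions. Weight maps threshold the
top 10 % of voxels by |w| (ceiling count; ties break to the lower index),
signed positive = finger, negative = wrist.

## Cross-decoding statistic

* RI = x·w + b per resting scan, after unit-normalising the scan (option
  `normalize_scans`, default on, mirroring the task-scan treatment). The
  SD of the RI is computed with the sample (n−1) convention and is
  invariant to b, so including the bias cannot affect the decision.
* IAAFT surrogates operate on the weight vector in voxel-index order. The
  iteration alternates imposing the original Fourier amplitudes (keeping
  current phases) with rank-remapping onto the original value multiset, and
  stops when the rank order repeats or after `max_iter` (100). Ending on
  the rank step makes the value multiset exact; the power spectrum is then
  matched approximately — relative error ≈ 1 % at n = 256 for strongly
  coloured (1/f) vectors, smaller for the flatter spectra of real weight
  vectors. Convergence flags and spectral errors are recorded per
  surrogate. A constant vector is its own surrogate. Shuffling weights by a
  permutation is *exactly* equivalent (up to float summation order) to
  shuffling each resting scan's voxels by the inverse permutation, which is
  why one surrogate per iteration suffices for the null.
* Correction: `SD_RS − (mean(SD_IC) + SD(SD_IC))` and `SD_IC − mean(SD_IC)`,
  with SD(·) again the sample convention. Subtracting the null's own spread
  from the observed statistic makes the test conservative: in the null
  world the measured per-subject false-positive rate is far below the
  nominal 5 % (the calibration test asserts it stays at or below the exact
  binomial 95 % upper bound).
* Decision: critical value = k-th largest corrected null value with
  k = round(α·n) (50 of 1000 at α = 0.05); significance requires a strictly
  greater corrected SD_RS (a tie is not significant). The empirical p-value
  uses the add-one convention `(#{SD_IC ≥ SD_RS}+1)/(n+1)`, so it is never
  exactly zero.
* Group-level use: the experiment report carries per-subject decisions plus
  pooled summaries (mean corrected SD_RS, significant fraction); no single
  aggregation is privileged.

## Orchestration and reproducibility

All pipeline constants (block length, TR, dropped scans, passband, filter
order, λ, null size, α, weight-map fraction) appear as named keys in a
single config with defaults; unknown keys raise with the full offender
list. Randomness derives from one master seed: subject *i* uses
`SeedSequence([master_seed, i])`, split once for data generation and once
for the null, so any subject can be reproduced in isolation. Reports are
JSON (validated against `report_schema.json` by a small built-in checker)
plus a deterministic TSV; the NIfTI adapter records the flat mask index
order used for voxel extraction.

## Problem sizes

The test-suite simulations use desk-scale configurations chosen to make the
statistical assertions sharp: 30 subjects at 100 voxels for the
chance-level check (Monte-Carlo SE ≈ 1.2 points), 200 subjects at 200
voxels with 200-iteration nulls for type-I calibration, and 3 × 50 subjects
for the power/monotonicity ladder at resting amplitudes {0, 4, 10}. The
acceptance script uses 100 subjects for the chance-level estimate and a
full 1000-iteration null for the rank check.

## Known limitations

* The original variational-Bayes regularised logistic decoder is replaced
  by a plain L2-penalised fit; weight values (not the pipeline logic)
  would differ numerically from a variational implementation.
* The IAAFT null preserves the weights' value distribution and spectrum
  but, like any surrogate scheme, defines "task-irrelevant" only relative
  to those constraints.
* With spatially white synthetic data the voxel-index spectrum carries no
  anatomy; on real data the (arbitrary) voxel ordering determines what the
  spectrum constraint preserves, so the ordering is recorded with results.
* The conservative SD correction trades type-I error for power; at small
  resting amplitudes the test under-rejects by design.
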