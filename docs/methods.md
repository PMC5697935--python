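# Methods

This note documents the statistical machinery in `riskephys`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Task and data model

A session is a three-block instrumental task: on every trial a cue is
followed by a nose poke (the *action*) and reward delivery. The
action–punishment contingency P(shock | action) is 0, 0.06 and 0.1 in
blocks 1–3 (50 trials per block by default), so round(0.06·50) = 3 and
round(0.1·50) = 5 trials in blocks 2 and 3 carry a foot shock. Shock
trials contain electrical artifacts and are excluded from every neural
analysis (`exclude_shock_trials`), leaving 50/47/45 trials at the default
geometry. Timestamps are seconds from session start; intervals are
half-open `[start, end)`. The baseline epoch is the 2 s window beginning
2.5 s before cue onset. Peri-event epochs run −2 to +2 s around cue,
action, or reward.

On disk a session is a directory of plain formats: `trials.tsv`,
`spikes.tsv` (one row per spike), `lfp.h5` (one group per region with
`fs`/`t0` attributes), and a `session.json` sidecar with the task
configuration, RNG seed, unit registry, and — for synthetic sessions —
the ground-truth record. Validation is strict by default (event ordering,
rt ≡ action−cue to 1 ns, shock flags only in risk blocks, spike times
sorted and inside the recording); silent coordinate bugs dominate failure
modes in this analysis class, so a violation raises with the offending
trial or unit named. An opt-out (`validate=False`) exists for forensic
loading.

## Single-unit encoding

**Binning and rates.** Spike counts are taken in rectangular windows
(50 ms non-overlapping for rate displays; 200 ms stepped by 50 ms for the
encoding statistic; 50 ms stepped by 5 ms for onset-timing variants).
Rates are smoothed with a centered 5-bin boxcar, truncated and
renormalized at the edges (the kernel shape is a package choice; only the
5-bin span is fixed). Trial-averaged rates are z-scored per unit against
the pooled mean/SD of its baseline-window rates; a unit with zero baseline
variance cannot be normalized and is flagged and excluded downstream
rather than silently clamped.

**wPEV.** For each time bin, the one-way layout of across-trial counts by
block gives

    wPEV = (SS_blocks − df_blocks · MS_error) / (SS_total + MS_error),

the bias-corrected omega-squared, with expectation 0 under equal block
means. When SS_total + MS_error = 0 (all counts identical) the statistic
is defined as 0, consistent with that null expectation. The statistic is
invariant to relabeling blocks and bounded above by 1.

**Surrogate bands.** Block labels are permuted across trials — jointly for
all bins of a trial, preserving within-trial temporal correlation — 1,000
times, and the wPEV trace recomputed per permutation. Following the
stepping construction, levels rise from the pooled surrogate mean in
increments of SD/100; the pointwise band at a bin is the lowest level with
fewer than α of surrogates above it at that bin, and the global band is
the lowest level such that fewer than α of surrogate *traces* exceed it in
any bin (α = 0.01). "Fewer than α" is implemented as the strictly-fewer
order statistic (at most ⌈αN⌉−1 exceedances). The search is capped at
max(surrogate)+SD, which is unreachable in practice but bounds the loop.
A unit encodes punishment risk iff its observed trace crosses the global
band anywhere. Bands are built per unit (the conservative reading), with
per-unit RNG substreams keyed by a hash of the unit id so parallel and
serial runs agree.

Because the band is a tail order statistic estimated from 1,000
surrogates, the crossing rate of fresh null traces is itself stochastic:
across independent draws it averages ≈1% with a standard deviation of
roughly 0.4 percentage points. This is a property of the published
construction, not of this implementation.

**Direction and correlates.** The SRC of counts on block index (1, 2, 3)
is the simple-regression coefficient standardized by Sx/Sy, identically
the Pearson correlation; its sign labels units excitatory or inhibitory.
Baseline (inter-trial) block modulation is tested with Kruskal–Wallis at
α = 0.05 (the omnibus test is a package choice; only "significant
modulation" is prescribed), with direction from the SRC sign on baseline
counts. Firing-rate–RT correlations use log RT; RT distributions are
right-skewed and the log transform linearizes them.

## VTA cell classification

Criterion 1 is electrophysiological: baseline rate < 12 Hz and waveform
width > 1.2 ms, both strict inequalities. Criterion 2 is functional:
per-unit auROC of across-trial firing in fifteen 100 ms bins (−0.5 to
+1.0 s around reward) against the across-trial baseline-rate
distribution, ties counted half (the Mann–Whitney identity, so the
profile is invariant to monotone rate transforms). The unit × bin auROC
matrix is column-mean centered (standard PCA; centering is a documented
choice) and decomposed by SVD; units are clustered in top-3 PC space by a
2-component full-covariance Gaussian mixture (20 k-means-seeded EM
restarts, covariance regularization 1e−6, tolerance 1e−8, best restart by
likelihood). Component indices are arbitrary, so the cluster whose mean
profile has the larger mean auROC in the 0–300 ms post-reward bins is
anchored as Type 1 (phasic reward excitation); swapping mixture components
can never change final labels. A unit is putative DA iff it passes both
criteria. mPFC units are not classified; those with baseline > 20 Hz are
flagged as metadata only.

## GPFA

Observations are square-rooted spike counts in 20 ms bins over the −0.5
to +0.5 s peri-action window (the window is prescribed; the bin width is a
package default). The model is linear-Gaussian per bin with diagonal
observation noise, and each latent dimension is a zero-mean GP over the T
bins with kernel (1−σn²)·exp(−Δt²/2τ²) + σn²·δ, σn² = 1e−3. EM uses the
closed-form joint-Gaussian E-step (posterior covariance shared across
trials), closed-form M-steps for C, d, R, and a bounded scalar
optimization of each log-timescale that is accepted only when it improves
its expected-likelihood term — a generalized EM step, so the marginal
likelihood is non-decreasing (asserted in tests to 1e−8 relative slack).
The marginal likelihood itself is obtained free of extra cost from E-step
byproducts via the Woodbury identity. Initialization: factor analysis for
C and R, data mean for d, τ = 100 ms; maximum 500 iterations, tolerance
1e−8 by default (tests and the pipeline use smaller budgets, stated per
call).

Dimensionality is chosen by 4-fold cross-validated held-out likelihood
over trials (seeded folds) with the 1-SE plateau rule — the smallest p
whose mean per-trial held-out likelihood is within one standard error of
the best candidate's. The pipeline default is p = 5 for cross-population
comparability, with per-run override.

For trajectories, C = UΣVᵀ is orthonormalized: basis U, latents ΣVᵀx, so
Cx is reproduced exactly. The per-trial *deviation* is the mean over time
bins of the Euclidean distance to the block-1 mean trajectory, computed in
the full orthonormalized space (not a 3-D visualization subspace) — the
measure is invariant to orthogonal rotations. Behavioral deviation is
log RT minus the block-1 mean log RT; Pearson r and two-sided p are
reported pooled and per block.

## Field spectra and Granger causality

Multitaper power uses nine DPSS tapers with time-bandwidth product NW = 5
(K = 2NW−1), 500 ms windows stepped by 50 ms, linear detrend per window,
one-sided Parseval-consistent normalization (the PSD integrates to the
segment variance up to taper bias). The implied half-bandwidth is ±10 Hz
at 500 ms — a deliberate trade of frequency resolution for variance, which
matters when interpreting narrowband peaks. Baseline z-scoring uses the
across-trial mean/SD of pre-cue baseline power at each frequency; zero-SD
frequencies become NaN and are logged, never imputed. Coherence pools
cross- and auto-spectra over tapers and trials per window, giving MSC in
[0, 1]; pooling requires at least two effective samples or the call
errors (a single taper-trial pair is degenerately 1).

The VAR for Granger causality is fitted by least squares pooled over
per-trial peri-action segments, each linearly detrended; order 1..20 by
AIC (ln|Σ| + 2·4p/N). The spectral decomposition follows Geweke: with
transfer function H(f) = (I − Σ_j A_j e^(−2πifj/fs))⁻¹ and spectral
matrix S = HΣH*, the causality 1→2 is −ln(1 − (Σ11 − Σ12²/Σ22)|H̃21|²/S22)
with H̃ the instantaneous-correlation-normalized transfer function
(H̃21 = H21 + (Σ12/Σ22)H22). The normalization is required for exactness
when the residuals are instantaneously correlated and reduces to the bare
formula when Σ12 = 0; integrated over normalized frequency the measure
matches the time-domain causality (tested against ln 1.25 for a known
one-lag coupling and against explicit reduced-model fits). Frequencies
where the characteristic determinant is numerically singular are excluded
as NaN. Significance uses a permutation bound: whole trial segments of one
channel are shuffled against the other (preserving autocorrelation,
destroying cross-dependence), and the per-frequency (1−α) surrogate
quantile is the upper confidence bound (α = 0.001, 1,000 permutations in
the full procedure; tests use smaller, stated budgets). Frequency grids:
1–125 Hz for spectra/coherence, 1–50 Hz for causality; the theta band is
5–15 Hz throughout and band summaries are means over in-band bins.

## Spike–field phase locking

The LFP is bandpass filtered 5–15 Hz with a 4th-order Butterworth applied
forward-backward (zero phase, so spike-phase relations are not shifted by
the filter), and the instantaneous phase taken from the Hilbert analytic
signal with phase 0 at the oscillation peak (cosine convention — stated
because preferred-phase values depend on it). Spike phases are linearly
interpolated on the unwrapped phase; at 1 kHz the difference from
nearest-sample assignment is negligible but interpolation is the
documented choice. MRL = |mean phasor| ∈ [0, 1]. Because MRL is biased
upward at low counts, the PLV is the MRL averaged over 1,000 random
100-spike subsamples (without replacement within each iteration, seeded
per unit/block/reference region); units enter only with > 100 peri-action
spikes in every block. Rayleigh z = NR², with
p = exp(√(1+4N+4(N²−(NR)²)) − (1+2N)). The lagged profile recomputes PLV
with spikes shifted by −100..100 ms in 4 ms steps; lagged spikes leaving
the analysis window are dropped and counted. Peak-lag ties break toward
zero and then toward negative lags — conservative with respect to claims
that the oscillation leads the spikes. Block comparisons across units use
Wilcoxon signed-rank (PLV distributions are unknown, so nonparametric),
with per-block proportions of Rayleigh-significant units reported.

## Synthetic sessions: what is and is not emulated

The generator reproduces the statistical structure the analyses assume,
with every effect size and the seed configurable, and a ground-truth
record for recovery testing. All randomness derives from one session seed
through named substreams (CRC-keyed `SeedSequence`s), so any module can be
re-run independently and sessions are bit-reproducible.

* **Behavior.** RT is shifted-lognormal per block: rt = 0.75 s +
  exp(μ_b + σ_b ε). The shift models the animal's minimum cue-to-poke
  latency; without it, occasional implausibly fast trials drag the
  cue-locked response into the peri-action window and generate an
  artifactual negative trajectory–RT correlation. Block medians ~1.0,
  1.3, 1.8 s with rising σ give both the rising mean and rising
  trial-to-trial variance with two knobs per block. Immobile RT is a
  Beta-distributed fraction of RT with block-increasing mean; retrieval
  latency is shifted-lognormal, block-independent.
* **Spiking.** Inhomogeneous Poisson: baseline × per-block offset +
  event-locked Gaussian bumps with per-block gain, all scaled by
  exp(latent_gain · z) where z is one *half-normal* scalar per trial
  shared across the population and added (scaled) to log RT. The
  half-normal choice makes trajectory deviation — an unsigned distance —
  monotone in the latent, so the programmed trajectory–RT correlation is
  recoverable by construction. A unit is ground-truth *encoder* iff its
  block gain or baseline offset is non-constant: both produce genuine
  block-dependent firing.
* **LFP.** Pink noise (spectral 1/f shaping with seeded phases) plus an
  action-locked theta burst per trial: Hann envelope (2.5 s), amplitude
  declining over blocks, frequency drawn per trial from 5–15 Hz, random
  initial phase. The mPFC trace receives a delayed (15 ms), scaled (0.6)
  copy of the VTA theta component — the VTA→mPFC direction that the
  Granger and cross-correlation analyses must recover. The per-trial
  frequency draw matters: with a fixed frequency, a time lag is a pure
  phase rotation and the lagged-PLV profile would be flat; frequency
  dispersion across trials makes the profile peak at the true lag.
* **Phase coupling.** Spikes are thinned against a von Mises acceptance
  exp(κ_eff cos(φ−φ₀)) with κ_eff = κ_block × burst envelope, and the
  candidate rate is pre-inflated by e^{κ_eff}/I₀(κ_eff) so the expected
  rate equals the programmed λ(t) at every instant regardless of coupling
  strength. Without that normalization, block-varying κ would leak into
  block-varying rate and contaminate the encoder ground truth. Units may
  lock to the local or the remote theta with a configurable oscillation
  lead (default 12–20 ms), which the lagged-PLV analysis recovers as a
  negative peak lag.

Default cohort: 24 mPFC + 16 VTA units; 17 true encoders (mixed signs,
including three baseline-offset-only encoders), 8 DA-like and 8
non-DA-like VTA templates (including suppressed-by-reward units), theta
coupling declining over blocks for half the mPFC units and all DA units.
Effect sizes are set so that recovery is reliable but not trivial — e.g.
encoder gains of 1.5–2× (rising) or 0.25–0.5× (falling) on ~10 Hz
responses over 45–50 trials per block.

Not emulated: spike waveforms and sorting artifacts, conduction delays,
non-Poisson spiking (refractoriness, bursting), nonstationary baselines,
volume conduction, movement artifacts, and any biophysical detail of the
shock itself. Passing recovery tests therefore demonstrates correctness of
the estimators under the generative assumptions, not robustness to every
pathology of real recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the full chain at desk scale: one
40-unit session (150 trials, ~1,000 s of 1 kHz LFP), 500–1,000 surrogates
per unit, GPFA with T = 50 bins and 60–150 EM iterations, and permutation
counts of 25–60 where a bound is exercised — sizes chosen so the whole
suite completes in a few minutes on one core while keeping every
statistical check well-powered. Degenerate inputs fail loudly rather than
silently: zero-variance baselines are flagged, duplicated GC channels
raise a singularity error naming the cause, units below the spike-count
floor are excluded with no fallback, and empty blocks after shock
exclusion warn.

## Known limitations

* The GPFA timescale M-step optimizes each τ independently; strongly
  correlated latents can trade timescales between dimensions (the usual
  identifiability caveat — the latent space is defined up to rotation).
* The wPEV global band inherits ~0.4-point stochasticity in its realized
  family-wise rate from the 1,000-surrogate construction (see above).
* The peri-action epoch mixes cue- and reward-locked activity on trials
  with short latencies; this is a property of the task, and it is why the
  encoder ground truth is defined by programmed block dependence rather
  than by "any detectable block difference".
* Bivariate Granger causality cannot distinguish direct coupling from a
  common driver; the generator contains no common driver, but real data
  might.
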