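# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic sessions

The generator exists so that every downstream stage can be validated
against known ground truth. It emulates the statistical structure of
multichannel auditory-EEG sessions, not their biophysics.

**Background.** Each EEG channel carries an independent Gaussian process
with a 1/f^α power spectrum (spectral shaping of white noise; α = 1 by
default, RMS 10 µV by default) plus a band-limited 8.5–12.5 Hz alpha
process that is stronger over posterior channels. A property test fits
the log–log periodogram slope of long realizations and checks it is
within 0.2 of −α. Ear electrodes (A1/A2) are simulated quiet, so
ear-referencing is the identity on clean data; EOG and EMG channels carry
their own processes.

**Eyeblinks.** Stereotyped biphasic 400 ms transients (≈200 µV on VEOG)
occur at Poisson times at the subject's blink rate and propagate into
scalp channels through fixed known coefficients (0.30 at Fz, falling
posteriorly). The blink-removal stage must recover these coefficients;
tests check recovery to ±0.05.

**Oddball sessions.** Every tone evokes an N100-like negative Gaussian
deflection (100 ms latency, σ = 15 ms). Deviants additionally evoke a
deviance response: a negative Gaussian trough (default latency 150 ms,
the center of the 100–205 ms detection window; σ = 25 ms) with amplitude
given by the subject's per-deviant ground truth. The component is built
as a difference of Gaussians (width ratio 2.5, equal areas) so it
integrates to zero: acquisition-style AC coupling leaves near-DC-free
waveforms, and a unipolar pulse would otherwise lose ~7% of its peak to
the 1 Hz high-pass, making "recover the planted amplitude" ill-posed.
The trough depth equals the planted amplitude exactly, and the flanking
positivities resemble the deflections that surround real difference-wave
troughs.

**Click-train sessions.** Each train adds a sinusoid at its stimulation
rate, windowed to the 500 ms train with 10 ms ramps, amplitude 5 µV by
default, plus an onset N100. Per-train phase offsets are von Mises with
concentration κ solved from the mean-resultant-length identity
R(κ) = I₁(κ)/I₀(κ) = PLF, so the population phase-locking factor equals
the planted value; PLF = 1 is the zero-jitter limit, and measured PLF is
monotone in κ (tested over κ ∈ {0.5, 2, 8, 32}). The 5 µV default is
deliberate: against the default background the in-band (39–41 Hz) noise
is ≈2 µV per trial, and a weaker entrained response both biases measured
PLF downward (phase estimates degrade) and cannot clear the SNR > 4
gate. At 5 µV the sessions sit just above the gate, which mirrors a
usable patient recording.

**Resting sessions.** Sums of independent band-limited Gaussian
processes with configured variances per canonical band (eyes-closed,
alpha-dominant defaults: 8/4/15/4 µV² for delta/theta/alpha/beta, gamma
from the subject profile). Each process is confined to its band minus a
0.25 Hz guard at the edges — one analysis bin — so the configured
variance lies unambiguously inside the band and ground truth does not
depend on how the estimator splits leakage across a shared edge. With
the guard, all five bands are recovered within ~2% from a 300 s session.

**Cohort.** One latent severity z ~ N(0,1) per subject drives both the
clinical scores and the EEG ground truth. Scores are Gaussian-copula
draws against z: for a planted Spearman target ρ_s the latent Pearson
correlation is 2·sin(πρ_s/6) (the exact bivariate-normal inversion),
then mapped to instrument marginals (cognitive composite T-scores
~N(30, 12); symptom subscales summing to the total, integer-rounded and
range-clipped). Biomarker truth is monotone in z — phase locking,
entrained amplitude and (negative) mismatch amplitude all degrade with
severity, gamma power drifts up — so biomarker × score rank correlations
approach the planted severity × score targets as n grows; with noiseless
extraction at n = 400 the mean estimate over 100 seeds lands within 0.05
of targets 0/0.3/0.5. End-of-treatment values add a per-arm effect
(zero by default: the package's default study is null for treatment
response) plus test-retest noise scaled so change-from-baseline SDs are
~1.4 µV for MMN, ~0.07 for PLF and ~1.9 µV² for gamma — the scale seen
in repeat-session EEG. Arm allocation is exact largest-remainder at
1:1:1:1:2. What the generator does *not* model: volume conduction and
realistic channel covariance, non-stationary artifacts (movement,
electrode pops), drug pharmacokinetics, site effects. Passing tests
therefore demonstrate correctness of the estimators under a plausible
noise model, not performance on any particular real recording.

## Extraction pipelines

**Filters.** Butterworth second-order sections, order 4 by default;
zero-phase stages run forward–backward, which squares the magnitude
response and cancels phase (a 10 Hz probe through the 30 Hz low-pass
keeps its amplitude to <1% with its correlation peak at lag 0). The
mains notch is a 2 Hz-wide zero-phase band-stop with a true magnitude
zero at center. Order 4 was chosen over 2 because the gentler roll-off
of order 2 removes ~2% of a deviance-response trough at the 1 Hz
high-pass; order 4 keeps the zero-noise recovery error below 0.5%.

**Blink removal.** Blink intervals are flagged where the 10 Hz-low-passed
VEOG exceeds 75 µV (dilated ±100 ms); each EEG channel is regressed (OLS)
on the EOG channels over flagged samples only — where blinks dominate —
and the fitted propagation is subtracted over the whole record. Flat EOG
or no detected blinks degrade to a no-op with a status flag.

**Epoching and QC.** Epochs are half-open [t_min, t_max) windows
(round((t_max−t_min)·fs) samples); events whose window crosses a record
edge are dropped with reason `edge`, and kept + rejected + edge-dropped
always equals the number of scheduled events. A channel within an epoch
is bad above ±100 µV or below 0.5 µV peak-to-peak; up to 20% bad EEG
channels are replaced by the mean of their clean montage neighbors,
more rejects the epoch. The operation is idempotent on its own output.
These thresholds are package defaults (exposed in config), as automated
surrogates for visual artifact rejection by trained staff.

**MMN.** Stage order: 1 Hz high-pass → blink regression → epoch
[−100, 400] ms → baseline [−100, 0) ms → rejection/interpolation →
second baseline → 30 Hz zero-phase low-pass → pooled-standard difference
waves → windowed minimum. The low-pass is applied to the condition
averages (filtering commutes with averaging). The peak is the windowed
minimum sample (earliest on ties) rather than a local-extremum search:
reproducible, and well-defined even for non-negative difference waves.
"Signal strength" in the SNR gate is RMS — the only scale-free reading
that makes one threshold meaningful for a 100 ms and a 400 ms window.
The ±2 µV baseline rule is evaluated on the pre-stimulus segment of the
Fz difference wave, boundary inclusive; the SNR threshold is strict
(exactly 2 fails). All standards are pooled for the standard ERP.
The windowed-minimum estimator has a known noise-dependent negative
bias (picking a minimum over correlated noise): calibration over 50
simulated sessions (2000 tones, 10 µV background) gives a pooled bias
of −0.17 µV and a per-session SD of 0.66 µV for a −2.5 µV planted
amplitude; the recovery tests freeze tolerances at that calibration
(bias + ~2.5 standard errors at the replicate counts used). About a
quarter of such sessions fail the SNR > 2 gate — comparable to the
analyzable-data fractions reported in multicenter patient studies.

**ASSR.** Morlet kernels use n_cycles = 6 with support ±5σ_t and are
amplitude-normalized (unit sinusoid → |TFR| ≈ 1 in steady state), so PLF
is amplitude-invariant by construction. The scalar endpoints need only
the 39–41 Hz band (re-centered at rate ±1 Hz for 20/30 Hz runs), so the
session pipeline evaluates wavelets on that band at 0.5 Hz steps; the
full 4–100 Hz map remains available through `morlet_tfr`. The dB
baseline interval is [−0.5, −0.1] s — inside the TFR domain, clear of
wavelet edge effects — and is shared by induced and evoked power. The
SNR gate is the linear ratio of in-band induced power over the 100–500 ms
bins to the baseline interval, strict at 4. Scalars are unweighted means
of the four 100 ms bins. Epochs with residual excursions above 200 µV
are dropped before the TFR.

**Resting qEEG.** Welch estimation with 4 s Hanning segments at 50%
overlap (0.25 Hz resolution — resolves the 1.5 Hz band edge), windowed
periodograms compensated for window power so the density integrates to
the mean square (Parseval, verified to 5% on white noise). Band
integrals use half-open [lo, hi) bins so shared edges count once and
delta..beta absolutes sum exactly to the 1.5–30 Hz total. Relative power
uses the 1.5–30 Hz denominator literally — including for gamma, which
therefore sits outside the 100% budget of delta..beta; a full-spectrum
denominator is available as a switch since the printed definition is
ambiguous on this point.

## Statistics

Spearman's ρ is the Pearson correlation of mid-ranks (tie-aware).
Two-sided p-values: exact permutation enumeration for n ≤ 10 (permutation
matrices built recursively in numpy; verified against a brute-force
itertools oracle for n ≤ 8), t-approximation with n−2 df above. Pairs are
deleted pairwise per score column (per-measurement missingness is the
norm in such substudies); pairs with fewer than 4 complete cases are
reported as missing rather than dropped. Flags: '+' iff ρ ≥ 0.3 and
p < 0.05, '−' iff ρ ≤ −0.3 and p < 0.05; no multiple-comparison
adjustment (these are hypothesis-generating screens, and the flag count
itself is the readout). Group summaries use the n−1 SD, SEM = SD/√n
(missing at n = 1), and report rounding is half-away-from-zero to two
decimals — the convention that reproduces SEM cells exactly from printed
SD/N pairs. The "10+25 mg" pooled arm is a pure relabeling; pooled
summaries equal summaries of the pooled raw values.

## Problem sizes and determinism

Default test and acceptance runs use reduced but honest problem sizes:
oddball recovery at 2000 tones per session with ≤8 replicate sessions,
phase-locking recovery at 50 trains, resting sessions at 300 s, cohorts
of 79 (study-sized) or 400 (correlation recovery) subjects. All
randomness flows through explicit integer seeds; per-subject seeds are
derived from a base seed with a stable string hash below 2³¹, and the
click-train rate order is keyed by subject (not visit) so both visits of
a subject replay the same pseudo-random order.

## Known limitations

- EDF support is deliberately minimal (plain EDF, 1 s records, integer
  sampling rates, one rate per file); recordings that are not a whole
  number of seconds are zero-padded on write.
- The oddball randomization constraint (no two adjacent deviants, uniform
  over non-adjacent position sets) is a design choice; the constraint is
  configurable but alternatives are untested.
- Only Fz is validated end to end; other electrodes flow through the same
  code paths but have no ground-truth claims.
- The windowed-minimum MMN estimator is biased under noise (documented
  above); debiasing was deliberately not attempted because the estimator
  definition itself is the endpoint.
- 20/30 Hz ASSR runs are supported as configuration (band re-centering)
  but carry no calibrated recovery claims.
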