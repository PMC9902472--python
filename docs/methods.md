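# Methods

This note documents the models, conventions and numerical choices behind
`photosleep`: what the synthetic-session generator emulates, how each
analysis stage is defined, and where design decisions were genuinely open.

## Conventions

All times are seconds, 0-based; windows are half-open `[start, end)`;
vigilance states are W (wake), N (NREM) and R (REM) on a fixed 5-s epoch
grid. A `Trace` is a uniformly sampled signal with a declared unit that
follows the pipeline order `raw_F → dFF → zscore → norm_zscore /
detrended`. All randomness flows from one integer seed through
`numpy.random.SeedSequence` fan-out, so every simulation, shuffle and ICA
initialisation is reproducible; the pipeline derives per-stage child seeds
from the global seed by a fixed derivation.

## Synthetic sessions

The generator produces the statistical structure the analyses assume, not
biophysically detailed signals.

**Hypnogram.** A semi-Markov chain on {W, N, R}: bout lengths are
geometric in epoch counts with mean `state_mean_bout[s] / 5 s`
(memoryless, the simplest model consistent with 5-s quantisation), and the
successor state is drawn from configurable transition weights with
self-transitions excluded. By default REM is entered only from NREM and
exits to wake, the usual rodent convention. Defaults (wake/NREM/REM mean
bouts 120/120/60 s) are realistic for the mouse light phase; no published
quantitative bout distribution was fitted.

**EEG/EMG.** The EEG is a sum of three Gaussian-noise components —
band-limited delta (0.5–4 Hz), theta (6–10 Hz), and broadband — whose
variances are scaled per state (NREM delta-dominant, REM theta-dominant,
wake mixed); the EMG is white noise with a per-state amplitude (wake ≫
NREM > REM). This reproduces exactly the features the scorer uses and
nothing else: no spindles, K-complexes, movement artifacts or electrode
drift. Passing scorer tests therefore shows the rules and thresholds are
implemented correctly, not that the scorer would reach the same accuracy
on real recordings.

**Photometry.** Event times are an inhomogeneous Poisson process with a
per-state rate (defaults: 2/min in wake and REM, 0.3/min in NREM);
amplitudes are lognormal in ΔF/F (default median 20%, shape 0.4 —
large, clearly supra-threshold transients of the kind these sensors
report). Each event contributes a difference-of-exponentials kernel
(rise 2 s, decay 8 s, unit peak; the kernel shape is a package choice).
Channel B repeats channel A's event times shifted by `coupling_lag` with
amplitudes `slope·a + ε`, ε ~ N(0, σ_ε²); B shares A's tonic state
dependence. ε is not clipped, so a tiny fraction of B amplitudes may be
negative when σ_ε is large. The measurement model is

    F(t) = F₀(t) · (1 + ΔF/F(t)) + background + white noise,
    F₀(t) = A₁·e^(−t/τ₁) + A₂·e^(−t/τ₂),

i.e. bleaching acts multiplicatively on the fluorescence, as
photobleaching does physically; the constant background (fiber
autofluorescence) is additive and not bleached. The optional isosbestic
channel carries bleach + background + a shared low-pass motion artifact
but no sensor signal. Interventions scale the amplitudes of events after
the injection time before convolution; the session is regenerated from
the same seed so an effect of 1 reproduces the input bitwise.

## Sleep scoring

Spectra are per-epoch Hann-tapered FFTs, zero-padded to the smallest
power of two giving a bin width ≤ 0.19 Hz at the recording rate
(0.186 Hz at 1525 Hz). Scoring rules, in precedence order: EMG RMS above
threshold ⇒ W; else delta fraction (delta / total 0.5–30 Hz) above
threshold ⇒ N; else theta(6–10 Hz)/delta ratio above threshold ⇒ R; else
N. Default thresholds are data-driven: a deterministic Otsu split of the
log EMG RMS, an Otsu split of the delta fraction over low-EMG epochs, and
a fixed ratio threshold of 1 (theta power exceeding delta power). Both
EEG features are scale-free, so scoring is invariant to EEG gain. If the
EMG is constant the scorer warns and falls back to EEG-only rules. No
smoothing or minimum-bout post-processing is applied by default.

Two theta conventions coexist deliberately: REM *scoring* uses 6–10 Hz,
while band-power *reporting* uses theta = 4–8 Hz; sigma (10–15 Hz) and
beta (15–30 Hz) follow conventional rodent definitions since no single
standard exists. State spectra are normalised so total 0.5–30 Hz power is
100%.

A bout is a maximal run of identical labels; bouts clipped by an analysis
window count with their clipped duration, so per-state percent time sums
to exactly 100 within any window. Zeitgeber profiles bin epochs by ZT
hour with epoch-weighted aggregates for ZT0–12, ZT12–24, ZT13–17 and
ZT18–24.

## Photometry preprocessing

The fixed stage order is: 1-Hz block-mean binning (means, not decimation
— robust to high-frequency noise; the trailing partial block is dropped)
→ background subtraction → ΔF/F₀ → ~10-min initial trim → optional
isosbestic unmixing → z-score → either NREM-SD normalisation or drift
removal. The order in the middle is not fully determined by common
practice; it is fixed here and documented so results are comparable.

**Bleach baseline.** "Second-order exponential" is interpreted as a sum
of two exponentials plus offset, the standard photobleaching model. The
fit is bounded (all parameters ≥ 0), initialised with A₁ = A₂ = half the
decaying amplitude, τ₁ = span/10, τ₂ = span, C = final value. On
non-convergence (or a non-positive fitted baseline) a single exponential
plus offset is used and the result flagged. ΔF/F₀ = (F − background −
F₀)/F₀.

**Normalisation.** z-scores use the mean/SD of the full trimmed trace.
The norm. z-score divides the z-scored trace by its SD over NREM-labelled
samples — NREM is the quiescent reference state, so this expresses
signals in units of their quiet-period fluctuation and makes sessions
comparable across animals; it requires ≥ 10 NREM epochs.

**Drift removal.** Default: zero-phase (forward–backward) 4th-order
Butterworth high-pass at a cutoff expressed in cycles/sample at the 1-Hz
analysis rate — 0.00035 for adenosine/ATP sensors, 0.001 for Ca²⁺
indicators (slower sensors tolerate a lower cutoff). A sparsity-assisted
alternative is provided: an asymmetric-least-squares (Whittaker) baseline
whose smoothing weight is matched to the same cutoff via
λ = (2π·f_c)⁻⁴, with asymmetry p = 0.01 so positive transients are
excluded from the baseline. Both satisfy the same invariants (DC
rejection; ≤ 5% amplitude loss one decade above the cutoff; ≤ 10% AUC
change for transients with ≤ 10 s decay at the Ca²⁺ cutoff).

**Isosbestic unmixing.** Two-source FastICA on {signal, isosbestic} with
a fixed random state; the source more correlated (absolute value) with
the isosbestic channel is removed and the signal reconstructed, rescaled
to its original variance. On ICA non-convergence the isosbestic channel
is regressed out instead (with a warning).

## Transient analysis

**Detection.** Local maxima above mean + k·SD (default k = 2) with ≥ 10 s
peak separation; the SD is computed over the whole trimmed trace (the
window is configurable), making detection invariant to affine rescaling.
Noise bumps riding on an event's envelope can appear as separate peaks;
peaks whose delineated windows overlap — or whose bound had to be placed
at the inter-peak midpoint because no 10% crossing separates them — are
merged, keeping the taller peak.

**Delineation.** Amplitude is measured from the pre-peak local baseline
(the trace minimum over the approach to the peak, bounded by the previous
event) — one of several defensible conventions (vs. zero, or the 100-s
mean); it is the most robust to tonic state offsets. Onset/offset are
the last/first crossings of 10% of that amplitude, linearly interpolated;
missing crossings are bounded at inter-event midpoints and flagged. The
per-event baseline is the trace mean over the 100 s before onset (clipped
at the trace start, flagged); AUC integrates `x − baseline` over
`[onset, offset)` — half-open, so AUC is exactly additive over adjacent
sub-windows.

**Lag (C₅₀).** Both signals are aligned to one signal's event onsets;
each PETH is min–max normalised to [0, 1]; C₅₀ is the first upward
0.5-crossing on the rising phase (from the pre-peak minimum to the global
maximum), linearly interpolated; the lag is the difference of the two
C₅₀ values, which makes the estimate antisymmetric under channel
exchange. Lags below ~2 samples at 1 Hz are resolution-limited; the
estimator still interpolates but such values should be read as "≲ 2 s".

**Coupling and null.** Per event, the partner AUC is taken over the
lag-shifted window relative to the partner's own 100-s pre-window mean;
Pearson r, p and a least-squares line summarise the pairs. The null
circularly shifts the partner trace by a uniform offset ≥ 200 s
(preserving its autocorrelation, which is stricter than i.i.d.
permutation) and recomputes r; the empirical p is the add-one rank of
|r|. Dense event trains bias the measured r upward, because neighbouring
events contribute identical mass to both channels' windows and baselines;
the validation studies therefore use sparse trains (~1 event / 5 min)
where the measured r matches the generative value.

**Interventions.** The drug-effect quantifier compares mean supra-2SD
event amplitudes before the injection and from 10 min after it. The
hemisphere quantifier detects events on the reference (control) channel,
evaluates the test channel over the same onset–offset window (peak minus
its own 100-s pre-window mean — "corresponding events" are resolved by
same-window evaluation, not nearest-peak matching) and averages the
test/reference ratios over the pre-injection window and the 2-min-to-1-h
post-injection window. Detecting on the unchanged reference channel
avoids threshold-censoring bias when the test channel's events shrink.

## Statistics

`auto_compare` gates on Shapiro–Wilk at α = 0.05: for paired data the
gate is applied to the difference vector (a paired t-test only assumes
normal differences); for unpaired data to each sample. Normality not
rejected ⇒ paired/unpaired t-test; otherwise Wilcoxon signed-rank /
rank-sum. All tests are two-tailed at 0.05. An all-zero difference vector
is reported as undefined rather than forced through a test.

`mixed_anova_tukey` implements the balanced split-plot decomposition
(group between subjects, treatment within): SS_subjects(group) tests the
group effect; SS_error(within) tests treatment and the interaction. With
two within-levels sphericity holds trivially and no correction is
applied; with one group the treatment F equals the squared paired t
statistic exactly. Tukey HSD runs over all cell means using the
studentized-range distribution: within-group contrasts use
MS_error(within); contrasts crossing the between factor use the pooled
error (MS_subjects(group) + (b−1)·MS_error)/b with Satterthwaite degrees
of freedom (the error-term construction for split-plot post hoc tests is
not standardised; this is the classic Winer choice). Unequal group sizes
use the Tukey–Kramer standard error.

## Validation studies and problem sizes

Every stage is validated by parameter recovery (`photosleep.studies`),
with problem sizes chosen to give stable estimates on a single CPU:
lag recovery over lags {5, 10, 23, 40} s on ~8-h sessions with ~80 events
at a 1-Hz analysis rate; coupling recovery over 20 seeds with the
coupling noise set analytically so the generative event-amplitude
correlation is 0.7; sleep scoring on 4 simulated hours at 1525 Hz;
statistical calibration with 2000 null replicates. Simulations for the
coupling studies run the photometry carrier at 2–5 Hz before 1-Hz
binning; the generator's defaults remain at the acquisition-style rates
(EEG 1525 Hz, photometry 1017 Hz).

## Known limitations

* The generator omits hemodynamic and movement artifacts (beyond the
  shared isosbestic component), EEG microstructure, and any circadian
  modulation of bout statistics; recovery results bound algorithmic
  correctness, not real-data performance.
* The bleach fit is biased upward when event mass is a large fraction of
  the recording (very high rates or very large ΔF/F); amplitude recovery
  degrades gracefully but visibly above ~10% duty cycle.
* C₅₀ lags are undefined for PETHs that never cross 0.5 on a rising
  phase (pure noise); the estimator raises rather than guessing.
* The 2·SD detection threshold censors small events; quantities defined
  on detected events (mean amplitudes, coupling r) refer to the detected
  subpopulation, as in the original analysis convention.
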