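# Methods

This note documents the models, parameters and numerical conventions of the
package, the design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Synthetic stimuli

Each of the 11 default vocalization analogues is a sum of band-limited
Gaussian noise carriers and/or harmonic stacks (amplitudes ∝ 1/h, random
phases), multiplied by a (1 + sinusoidal AM) envelope and 5-ms raised-cosine
on/off ramps, peak-normalised, and rendered at 97.656 kHz.  The taxonomy
mirrors the call classes of the emulated study: three low-frequency
periodic calls with envelope periodicities of 10.3, 15.4 and 14 Hz and
energy below ~3 kHz, harmonic calls with fundamentals of 0.9–2.3 kHz, and
band-limited noise calls up to 30 kHz.  Durations span 0.30–0.98 s so that
every call fits a 1-s trial after the 20-ms onset; trials of 1.6 s (the
alternative recording length of the emulated protocol) accommodate
templates up to the 1.3-s type limit.  Presentation level scales the
waveform by 10^((dB−70)/20) relative to the 70 dB SPL reference; the
protocol studies 30–70 dB in 10-dB steps.

Spectral profiles integrate a one-sided, Hann-windowed, full-signal
periodogram over 36 contiguous bands.  The first two bands are the fixed
anchors {0–0.25} and {0.25–0.55} kHz; the remaining 34 band edges are
geometrically spaced from 0.55 to 45.5 kHz, matching the log-frequency
organisation of the midbrain.  Band powers are normalised to unit sum and
floored at 1e-12 before the log so empty bands stay finite.  (The exact
rule generating the unprinted interior edges is a package choice; only the
three printed anchors are fixed by the emulated protocol.)

## Rate model and spike generation

Each multi-unit cluster u has a best frequency (BF), Gaussian tuning in
log2 frequency with SD = bandwidth_oct/2.355 (so bandwidth_oct is the
tuning FWHM in octaves), a spontaneous rate, and a gain.  The stimulus
drive is the call's time-resolved band-amplitude envelope (5-ms Hann
spectrogram, power integrated per band, square-rooted so it scales
linearly with amplitude, peak-normalised at the 70-dB reference) weighted
by the tuning curve.  The instantaneous rate is

    λ_u,s(t) = baseline_u + gain_u · drive_u,s(t − latency_u)
               + c · gain_u · 0.5 · common_k(t),    clipped at 0,

with latency drawn once per unit within [0, 5] ms, and common_k(t) a
unit-variance Ornstein–Uhlenbeck path (τ = 10 ms) shared by all units on
trial k — one knob (c ∈ [0, 1]) that produces trial-matched noise
correlations while leaving single-trial statistics otherwise unchanged.
Spikes are drawn by thinning an inhomogeneous Poisson process on a 1-ms
rate grid; no refractory period is imposed, consistent with multi-unit
activity that pools several single units.

Defaults: baseline 50 spikes/s and gain 800 spikes/s per unit drive, i.e.
peak driven rates of a few hundred spikes/s for well-matched calls.  These
are realistic for ICC multi-unit clusters (≈3–10 single units each) and
place single-unit discrimination in the intermediate regime — well above
chance, below ceiling — which is the regime where pooling and window
effects are measurable.  The emulated study reports no quantitative rates
for its clusters; these defaults are chosen for realism, not fitted.

Geometries: `linear_double_shank` log-spaces BFs across the requested range
in contact order (100-µm contact spacing, 500-µm shank spacing) — the
tonotopic gradient; `tetrode` draws BFs within a ≤0.5-octave band (similar
tuning, 25-µm within-tetrode spacing).

## Voltage synthesis and spike detection

Optional raw voltage at 24.414 kHz places a spike template at every
ground-truth spike time on band-limited (100–6000 Hz) Gaussian background
noise rescaled to `noise_sd`.  The default template is a sharp positive
lobe (SD ≈ width/12, default width 1 ms) with a shallow, broader
undershoot: positive-dominant to match the positive-going threshold
detector, and with most of its energy inside the 300–3000 Hz detection
band while keeping total waveform energy low, so spikes landing in the
threshold-measurement window inflate the statistic only mildly.

Detection band-passes with a zero-phase (forward–backward) 4th-order
Butterworth filter — the phase-free choice; the emulated protocol states
Butterworth but not order or phase — and thresholds at Θ = μ + zσ (z = 3)
with μ, σ measured per trial on the filtered first 20 ms.  One spike is
reported per contiguous supra-threshold excursion, stamped at the
excursion's peak sample.  Positive deflections only; whether μ, σ are
taken on raw or filtered voltage is unstated in the emulated protocol and
we use the filtered trace.

Two intrinsic failure modes of the Θ = μ + zσ rule are worth knowing.
(1) If the 20-ms window happens to contain no spikes, σ collapses to the
background-noise floor and the 3σ threshold admits band-limited Gaussian
noise excursions at ~10–20 events/s (Rice's upcrossing rate).  (2) At high
firing rates, spikes closer than the excursion width merge into one
detection (expected recall loss ≈ rate × excursion width / 2).  The
detection validation therefore uses the regime the rule is designed for —
clusters with ~100 spikes/s ongoing activity, so the window almost never
sits silent, and spikes at 10× the noise SD — where recall ≥ 0.95 at ≤ 5%
false positives holds; outside that regime the rule degrades as described,
which matches its behaviour on real recordings.

## Preprocessing and features

Spike trains are binned at 1 ms (half-open bins) and convolved with the
causal alpha kernel k(t) = (t/τ)·e^{1−t/τ} (peak 1 at t = τ), with τ
solved numerically so the kernel FWHM is 3 ms (τ ≈ 1.226 ms).  The peak-1
normalisation is immaterial: the correlation measure is invariant to trace
scaling.  (The printed kernel form t·exp(α·t) diverges for α > 0; the
decaying alpha function is the standard EPSP kernel its description and
stated FWHM require.)  LFPs are the 0.5–500 Hz band of the same trace.
Features for the comparison grid: mean rate over 300 ms; six consecutive
50-ms rates; the five most prominent LFP spectral peaks (Hann periodogram,
4× zero-padding, peaks ranked by power, ties to the lower frequency); and
the correlation-template features themselves.  LFP "mean response rate" is
implemented as mean absolute amplitude.

## Classification

Stratified 10-fold cross-validation (10% test data; with 20 trials per
class every fold tests exactly 2 per class — stratification is required
for the per-class diagonal to be defined in every fold).  The fold split
is sklearn's StratifiedKFold with a fixed seed.  Decoders: the
correlation template (assign to the class of maximal mean Eq.-type
correlation; ties, including all-zero test traces, to the lowest class
index); "max" (alias of the template rule); LDA (shared covariance,
least-squares solver, automatic shrinkage on singular fits); Gaussian
naive Bayes; 1-nearest-neighbour (Euclidean); and minimum squared
rate-difference (class-mean of squared distances — the emulated text is
ambiguous between per-trial and class-mean comparison; class-mean is the
package's choice).  Zero-variance traces correlate 0 with everything, so
empty segments never crash sparse runs; each occurrence is logged.

Confusion matrices are stored column-normalised in percent; CC(k) is the
fold-averaged diagonal, CC the mean of CC(k), and the error bar the SD of
fold-wise overall accuracy.  N_voc (classes) and N_xval (folds) are
distinct quantities throughout.

## Pooling

Concatenation joins per-trial EPSP segments in a fixed unit order
(spectral + temporal information); addition sums binned counts before
smoothing (temporal only; by linearity identical to summing smoothed
traces); rate pooling concatenates per-unit mean rates over 100-ms windows
and classifies by minimal class-mean squared rate difference (spectral
only).  Pooled trials pair equal trial indices across units, so
simultaneity is preserved unless trials are shuffled upstream.

The pooling curve grows the set one unit at a time.  Gradual ordering
grows by nearest spatial neighbour to the current set; iteration 1 starts
from the lowest-BF unit and iteration 2 from the highest-BF unit (the two
ends of the gradient — the emulated protocol does not state its start
unit), averaged over the 2 iterations; random ordering uses 3 uniform
permutations.  Curve error bars propagate the per-iteration fold SDs as
√(Σ sd²)/n_iter.

## Response correlations

CorrRes is the maximum over integer 1-ms lags τ ∈ [−10, +10] ms of the
truncated-numerator, full-denominator lagged correlation: the numerator
sums the n−|τ| overlapping samples while both denominators keep the
full-length deviations, exactly as defined — which permits values slightly
above 1 for strongly lagged self-similar traces, and reduces to the
zero-lag Pearson coefficient at τ = 0.  Pairwise matrices average CorrRes
over trials per unit pair; only the lower half is materially reported.

Trial shuffling permutes trial indices uniformly and independently per
unit and stimulus (a trial may map to itself); the first unit keeps the
identity permutation as the reference frame.  Shuffling preserves every
single-unit statistic and destroys only cross-unit alignment.

Correlation-augmented classification concatenates the pooled time courses
and adds, per trial, each unit's mean CorrRes with the other pooled units.
The two stated criteria — maximal mean time-course correlation and minimal
mean squared CorrRes-vector difference — are fused by summing their
per-class ranks and taking the lowest rank-sum (ties to the lowest class
index).  The emulated text states both criteria but not their fusion; rank
summation is the package's scale-free choice, and when the CorrRes
features are identical across classes it reduces exactly to the plain
correlation template.

Statistical comparisons dispatch on a Shapiro–Wilk screen at α = 0.05:
both samples normal → Student's t-test (paired or independent), otherwise
Wilcoxon–Mann–Whitney (signed-rank when paired).  Identical degenerate
samples return statistic 0, p = 1 by convention.

## Analysis conveniences

Window sweeps tile the trial with consecutive 10-ms or 100-ms windows or
grow segment length from fixed starts; the per-vocalization start points
default to (0.54, 0.53, 0.54, 0.11, 0.52, 0.53, 0.06, 0.09, 0.53, 0.53,
0.21) s in stimulus order (values interpreted as seconds within the 1-s
trial), overridable per call.  Tonotopic profiles average CC(k) over units
within 1/3-octave BF bins anchored at 0.5 kHz, with SE propagated from
across-fold SDs as √(Σ sd²)/m; empty bins are omitted.  Profile-vs-spectrum
match is (1 − d/√2) × 100 with d the Euclidean distance between the two
unit-sum-normalised vectors on the profile's bins (√2 is the maximal
distance between probability vectors; the percent mapping is a package
definition, chosen as the simplest bounded one).  Best frequency is the
tone frequency (40 log-spaced tones, 0.5–45 kHz, 50-ms duration) with the
highest mean spike rate, ties to the lower frequency.  Aggregation across
shanks/positions/animals/intensities computes grouped means with the same
propagated-SE rule and refuses to mix different analysis segments.

## Seeds and determinism

Every stochastic stage draws from a NumPy SeedSequence keyed by the master
seed plus a fixed stage tag (and unit/stimulus/trial indices), so any
stage can be replayed in isolation and full runs are bit-reproducible.
String-dependent keys hash with CRC-32, never Python's salted `hash`.

## What the generator does not emulate

Real guinea-pig call acoustics (only their spectrotemporal taxonomy);
biophysical spike waveform diversity and spike-sorting ambiguity;
anesthesia effects; adaptation and non-Poisson spiking statistics;
stimulus-dependent noise correlations (the shared noise is deliberately
stimulus-independent, matching the null the shuffling analysis tests).
Passing tests therefore certify the analysis chain and its calibration on
a known ground truth — not quantitative claims about biological ICC data;
the real-data headline numbers of the emulated study depend on recordings
that are not publicly available.

## Problem sizes

Test and validation runs use desk-scale versions of the study conditions:
4–11 stimuli, 2–32 units, 10–20 trials, 10-fold cross-validation,
10–20 seeds per property.  These sizes give the test suite stable
statistics while keeping a full run in minutes on one CPU.
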