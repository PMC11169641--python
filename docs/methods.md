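# Methods

This note documents the measurement models, defaults, and design choices
behind `pdspeech`, and what the synthetic test bench does and does not
establish about performance on clinical recordings.

## Recording model and shared DSP

Input audio is mono PCM WAV (the clinical protocol records at 48 kHz /
16-bit; any rate is accepted and band-limited polyphase resampling is
available). Multi-channel files are averaged to mono with a warning rather
than rejected.

**Pitch tracking.** F0 is estimated per frame (40 ms frames, 10 ms hop) by
normalized autocorrelation: frames are Hann-windowed and the
autocorrelation is divided by the window's own autocorrelation, which
removes the taper bias so a perfectly periodic frame peaks near 1 at its
period. Among near-maximal candidate peaks (within 85% of the best) the
shortest lag is taken, which suppresses octave-down errors on strongly
periodic frames; parabolic interpolation gives sub-sample period
resolution. A frame is voiced when the peak height reaches 0.45 and the
frame RMS is above silence level. The search range defaults to 75–400 Hz
(adult speech) and every constraint is a keyword argument, because
clinical practice tunes pitch constraints per recording; frame length 40 ms
guarantees at least three periods at the 75 Hz floor.

**HNR.** With `r` the normalized autocorrelation at the pitch period, the
frame harmonics-to-noise ratio is `10*log10(r/(1-r))`; the recording value
averages voiced frames. On synthetic vowels the estimate is within
~0.5 dB of the injected ratio between 5 and 20 dB; above ~25 dB it
saturates upward (the windowed-autocorrelation estimate of `r` approaches
1 faster than the true harmonic fraction), so high-HNR values should be
read as "very clean voice" rather than a calibrated number.

**Intensity** is frame RMS in dB re full scale. Envelope-peak intensities
used by the DDK features add a +40 dB offset (dB re 1% full scale) so that
coefficients of variation of intensity are computed on a positive,
speech-level-like scale; SDs in dB are unaffected by this choice.

**Formants** come from LPC (autocorrelation method, Levinson recursion)
after downsampling to ~11 kHz and pre-emphasis, with order `2 + fs_kHz`
(one pole pair per kHz plus spectral tilt). Roots with bandwidth over
400 Hz are rejected for sustained vowels; the /i/-/u/ tracker relaxes this
to 600 Hz with 20 ms frames because a rapidly sweeping formant appears
broadened within an analysis frame. Formant estimates on sustained vowels
are harmonically quantized at high F0 — a pole is attracted to the
strongest harmonic near the resonance — which is the familiar
pitch-formant interaction of real vowels, not an artifact of the
synthesizer.

**Silence trimming** removes leading/trailing stretches more than 40 dB
below the envelope peak; task durations are measured on trimmed audio so
recorder start lag cannot inflate reading time or deflate DDK rate.

## Paradigm analyses

**DDK (/pa/).** Syllable nuclei are envelope peaks (20 ms smoothed
rectified envelope) with prominence at least 10% of the envelope maximum
and spacing at least 100 ms — below the shortest physiologic DDK period
(9/s) and above the burst-to-vowel gap, so release bursts never register
as extra syllables. Onsets/offsets sit at half-prominence crossings.
DDKavr divides the event count by the trimmed task duration; DDKsdp/DDKcvp
use peak-to-peak periods over the mean half-prominence duration
(matching the published construction, where the period CV is the ratio of
the period SD to the mean syllable duration); DDKjit is the mean absolute
consecutive-period difference over the mean period (a local jitter
analog); DDKcvi is the coefficient of variation of peak intensities — the
published wording "ratio of DDKavi to DDKsdi" is read as a typo for the CV,
the only construction consistent with its percent units.

**VOT.** Per syllable, the burst onset is the first crossing of the
high-band (>3 kHz) envelope above the larger of (noise floor + 12 dB) and
15% of the syllable's high-band peak; the voicing onset is the analogous
low-band (<1 kHz) crossing confirmed by the pitch tracker. Band envelopes
give millisecond resolution where frame-level voicing flags (10 ms hop)
could not support the ±5 ms recovery target.

**Sustained vowels.** All statistics are over voiced frames only. vAmp
uses linear per-frame RMS amplitudes (SD/mean), since a percentage of dB
values is ill-defined; Ampstd stays in dB. MPT is the longest voiced
segment (gaps under 50 ms bridged), so silence in the file cannot inflate
it. Per-vowel F1/F2 are medians over voiced frames, robust to tracking
glitches; the vowel space area is the shoelace area of the /a/-/i/-/u/
triangle.

**/i/-/u/ alternation.** The F2 track takes, per frame, the lowest LPC
resonance inside 500–3200 Hz (F1 sits below this band during /i/-/u/),
interpolates gaps, rejects outliers against a 50 ms median curve, and
smooths lightly. Cycles are segmented by a hysteresis state machine on the
centered track: a boundary is the midline crossing of each low-to-high
transition, refined by a local linear fit — transitions are the steep,
well-localized part of the trajectory, unlike the broad vowel plateaus.
F2reg is the CV (%) of cycle periods, so lower means more regular; F2rate
divides the cycle count by voiced task time, mirroring DDKavr. F2aver,
F2min and F2max are computed over the whole voiced track rather than cycle
extremes (track extremes are consistent with the published control-group
magnitudes).

**Passage reading.** Pause candidates are stretches of the fine-hop
envelope below −25 dB relative to the speech level (90th envelope
percentile); candidates containing confidently voiced frames are rejected
(fricative/plosive energy keeps true consonants above the floor), and
survivors shorter than 30 ms are discarded. NSR divides the known syllable
count (default 105, configurable for non-standard passages) by reading
time net of pauses; DPI is the median pause duration with a NaN sentinel
when no pauses exist. Running amplitude variation excludes pause frames;
running F0 statistics use all voiced frames.

## Cohort statistics

Features are z-scored per sex against healthy-control means and SDs.
Group comparisons use the pooled-variance two-sample t-test (Welch behind
a flag) and Hedge's g with the small-sample correction
`J = 1 - 3/(4·df - 1)`. Feature ranking orders by |g| and demotes features
whose absolute correlation with an already-kept feature exceeds 0.9; the
six-feature diagnostic set (DDKavr, NSR, DPI, F0std, F2reg, VowelArea) is
shipped as a named preset. Partial correlations residualize both variables
on an intercept plus covariates by OLS and refer the Pearson correlation of
residuals to a t distribution with `n - k - 2` degrees of freedom. FDR is
Benjamini–Hochberg. The stage analysis bins patients into H-Y stages
(1.5–2.0, 2.5, 3.0, 4–5), runs a one-way ANOVA, compares each stage to
controls with Bonferroni correction, and compares patient stages pairwise
with Fisher's LSD on the ANOVA's pooled variance. The classifier is
Gaussian Naive Bayes (variance floor 1e-9 of the largest feature variance)
in stratified 5-fold cross-validation with a recorded shuffle seed;
stratification keeps both classes in every fold at 40/80 group sizes. The
pooled out-of-fold AUC is primary and per-fold AUCs are reported
alongside, since pooling convention is otherwise a silent degree of
freedom. Missing clinical scores are handled by row-wise deletion, never
imputation.

## Network metrics

Node-by-node Pearson correlations are Fisher-z transformed (|r| clipped to
1−1e−7 so duplicated nodes give a large finite weight), thresholded to a
binary graph keeping the top fraction of edges by |z| (sparsity default
0.2, sign handling configurable, deterministic tie-break), and summarized
by nodal clustering, NE (mean inverse shortest-path distance) and NLE
(global efficiency of each node's neighbor subgraph); aCp and aEloc are
their means. Because the published pipeline leaves the thresholding scheme
unstated, the sparsity and edge-ranking rule are echoed into every report
and a sweep utility reports metric-vs-sparsity curves.

## Synthetic data

The generators are a measurement test bench, not a speech synthesizer:
the voice source is a Rosenberg glottal pulse train through second-order
formant resonators, so every parameter has an exact ground truth.

- *Pitch variability* is injected as per-cycle F0 perturbation smoothed
  over ~8 cycles and renormalized to the requested SD: white per-cycle
  jitter would be averaged out inside a 40 ms analysis frame, whereas the
  clinically observed F0 instability in sustained vowels is slow drift and
  tremor-band modulation.
- *Noise* for a target HNR is shaped by wide-bandwidth (4x) copies of the
  vowel's resonators: the spectral envelope stays speech-like (so formant
  tracking remains possible), while the shaped noise decorrelates well
  before the pitch period, keeping the autocorrelation HNR calibration
  exact.
- *DDK syllables* are a high-passed noise burst of the requested VOT
  followed by a short voiced vowel with a fast attack to a unique early
  envelope peak; periods and peak amplitudes are drawn with the requested
  CVs and rescaled to tile the task duration exactly, and a −36 dB
  low-frequency ambient floor spans the task so trimmed duration equals the
  nominal one.
- */i/-/u/ alternation* sweeps a per-sample time-varying F2 resonator over
  a smoothed trapezoid (30% dwell per vowel, 20% transitions) between the
  targets, over static F1/F3/F4; real alternation dwells on each vowel
  rather than passing through it instantaneously.
- *Passages* are equal-length voiced syllables with per-syllable F0 drawn
  around the running-F0 target, interleaved with exactly specified silent
  pauses at evenly spaced syllable boundaries.
- *Cohorts* draw features independently per group from a packaged table of
  published control/patient means and SDs for all 29 features (n = 40/80
  by default), with covariates from the published cohort's ranges. Motor
  subscores (bradykinesia, tremor) have no published summaries and use
  plausible clinical ranges; they only exercise the correlation/regression
  plumbing.

What passing recovery tests shows: the measurement chain recovers known
rates, periods, pitch statistics, pauses and formant targets under clean,
stationary, single-speaker conditions with controlled noise. What it does
not show: robustness to room acoustics, channel variation, disfluencies,
coarticulation, tone-language F0 dynamics, or pathological voice qualities
beyond elevated jitter/noise — conclusions about clinical recordings
require clinical validation.

Because cohort features are drawn independently, the synthetic
classification problem is easier than the real one (real acoustic features
correlate); the cross-validated AUC on synthetic cohorts (~0.99) is
therefore an upper plausibility check, not a reproduction of the published
0.931.

A note on the published effect sizes: recomputing Hedge's g from the
published group means and SDs (n = 40/80) reproduces the printed values
for most features (DDKavr 0.875, F0std 0.752, TotalDur 0.673, VowelArea
0.945), but the printed NSR value (0.903) is inconsistent with its own
printed summaries, which imply 1.056. The packaged parameter table stores
the summaries, so the generator's implied NSR effect is the larger one.

## Numerical choices and degenerate inputs

- Unvoiced frames carry NaN in Hz-valued tracks; statistics are defined on
  voiced frames only, and recordings with under 0.5 s of voicing are
  rejected rather than silently producing numbers.
- Thresholding ties in networks break deterministically by (value, node
  pair); classifier folds, generator draws and cohort sampling all consume
  explicit integer seeds, so identical configurations produce
  byte-identical outputs.
- Simulation sizes in the test suite (e.g. 5 s vowels, 20-seed classifier
  sweeps, 500–1000 ANOVA replicates, graphs up to 8 nodes for brute-force
  oracles) were chosen as the smallest sizes at which the checked
  tolerances are statistically meaningful.

## Known limitations

- Fully automatic operation: the clinical workflow this models included
  manual supervision of event detection; an annotation sidecar
  (event_type, start_s, end_s CSV) can override detected events, but no
  interactive correction exists.
- The passage analysis does no forced alignment; NSR assumes the reader
  completed the passage.
- Two of the 31 parameters mentioned in the source protocol are not listed
  in its feature tables and cannot be implemented; the 29 tabulated
  features are covered.
- No weighted-graph metric variants; binary graphs at explicit sparsity
  only.
- Only the fast single /pa/ DDK paradigm has dedicated features;
  /pa/-/ta/-/ka/ input is accepted and analyzed identically.
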