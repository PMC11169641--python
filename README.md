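# pdspeech

Acoustic assessment of hypokinetic dysarthria — the motor speech disorder
of Parkinson's disease — for clinical speech researchers working with the
standard four-paradigm recording protocol: sustained vowels (/a/, /i/,
/u/), fast /pa/ diadochokinesis (DDK), fast /i/-/u/ alternation, and
reading of a 105-syllable passage.

The package covers the full analysis chain:

- **Feature extraction** — 29 acoustic features from mono PCM WAV
  recordings: DDK rate/period/intensity statistics and voice onset time
  (VOT); F0 mean/SD, amplitude variability, maximum phonation time and
  harmonics-to-noise ratio from sustained /a/; the F1–F2 vowel space area;
  second-formant alternation magnitude, rate and regularity; pause
  statistics, net syllable rate (NSR) and running pitch statistics from
  passage reading.
- **Cohort statistics** — sex-stratified z-scores against healthy
  controls, pooled-variance t-tests with Hedge's g, Benjamini–Hochberg
  FDR, covariate-adjusted partial correlations, disease-stage ANOVA
  (Bonferroni vs controls, Fisher's LSD between stages), OLS prediction of
  motor scores, and a Gaussian Naive Bayes classifier evaluated with
  stratified 5-fold cross-validation and ROC/AUC.
- **Brain-network metrics** — Fisher-z functional connectivity from node
  time series, sparsity thresholding, clustering coefficient, nodal
  efficiency (NE) and nodal local efficiency (NLE).
- **Synthetic generators** — glottal-pulse/formant-resonator audio and
  Gaussian feature cohorts with exact ground truth, so every stage is
  testable without clinical recordings.

## Core quantities

For a detected syllable train with peak-to-peak periods $T_i$ (ms) and
half-prominence durations $d_i$:

$$\mathrm{DDKavr} = \frac{N}{T_{task}},\quad
\mathrm{DDKjit} = 100\cdot\frac{\overline{|T_i - T_{i-1}|}}{\bar T},\quad
\mathrm{DDKcvp} = 100\cdot\frac{\mathrm{SD}(T_i)}{\bar d}$$

The vowel space area is the shoelace area of the F1–F2 triangle of /a/,
/i/, /u/; NSR is the syllable count divided by reading time net of pauses
(minimum pause duration 30 ms). Group effects use Hedge's g,

$$g = \left(1 - \tfrac{3}{4(n_1+n_2-2)-1}\right)\frac{m_1-m_2}{s_{pooled}},$$

and the classifier AUC equals the Mann–Whitney probability that a patient
outscores a control.

## Worked example

Synthesize a /pa/ train with known ground truth and analyze it:

```python
import pdspeech as pk

spec = pk.SynthesisSpec(task="ddk_pa", seed=7, duration_s=7.0, ddk_rate_hz=4.5,
                        period_cv=0.08, intensity_cv=0.05, vot_ms=35.0)
rec, truth = pk.synth_ddk(spec)
feats, events = pk.analyze_ddk(rec)
print(f"syllables detected: {len(events)}")
print(f"DDKavr = {feats.DDKavr:.2f} syll/s   (true rate 4.50)")
print(f"VOT    = {feats.VOT:.1f} ms        (true 35.0)")

params = pk.reference_feature_params().set_index("feature").loc["DDKavr"]
g = pk.hedges_g(params["hc_mean"], params["hc_sd"], 40,
                params["pd_mean"], params["pd_sd"], 80)
print(f"Hedge's g (DDKavr, published summaries) = {g:.3f}")
```

prints

```
syllables detected: 32
DDKavr = 4.57 syll/s   (true rate 4.50)
VOT    = 37.1 ms        (true 35.0)
Hedge's g (DDKavr, published summaries) = 0.879
```

The detected syllable count and rate match the generator schedule (the
true rate 4.5 syll/s over 7 s yields 32 syllables), the VOT estimate is
within a few milliseconds of the injected value, and the effect size
recomputed from the published control/patient summaries reproduces the
reported group separation in DDK rate.

A command-line interface mirrors the library:

```bash
pdspeech synth --task ddk --rate 5 --seed 7 -o out/
pdspeech extract --manifest manifest.csv -o features.csv
pdspeech stats --cohort cohort.csv --seed 1 -o reports/
pdspeech network --timeseries ts.csv --sparsity 0.2 -o metrics.json
```

## Documentation

`docs/methods.md` describes the measurement models, the synthetic-data
generators and what they do and do not emulate, the default parameters and
the reasoning behind them, and known limitations.
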