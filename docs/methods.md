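# Methods notes

This note records the scientific and numerical choices behind `afbnp`:
what is modelled, which knobs matter, what the synthetic cohort does and
does not emulate, and where the design was genuinely open.

## Problem setting

Persistent AF abolishes sinus-driven beat-to-beat HRV interpretation:
the ventricular response is irregularly irregular, so short-term HRV
cannot be read as autonomic modulation the way it is in sinus rhythm.
The pipeline therefore treats 30-min aggregated windows of the RR series
as surrogate markers of global autonomic tone and hemodynamic burden,
and asks whether their multi-day evolution predicts the direction and
magnitude of a patient's NT-proBNP change over 6–12 months.

## Preprocessing

* Noise intervals and analysis windows are half-open `[start, end)`; a
  peak exactly at an interval's end is kept. This makes adjacency
  unambiguous and windowing an exact partition.
* Window membership follows the interval's *onset* (its first peak), so
  a window's RR list may describe beats extending slightly past its
  right edge; windows stay disjoint and no interval is lost or counted
  twice (property-tested).
* RR plausibility bounds default to 300–2000 ms — wide enough for the AF
  ventricular response — and are configurable; the filter drops
  intervals without re-bridging the gaps they leave.
* The usability gate quantifies "unusable signal" as noise-interval
  coverage of the recording span and "analyzable" as span minus noise;
  defaults (≤ 20 % noise, ≥ 48 h analyzable) mirror standard enrolment
  practice for multi-day ambulatory ECG. Both thresholds are parameters
  so scaled-down synthetic studies (below) can run.
* Trailing partial windows are kept and flagged; the <2-interval
  sentinel rule handles the degenerate ones. No ectopic-beat filtering
  is applied beyond the noise labels, consistent with AF physiology.

## HRV features

* SDNN uses the sample (n−1) standard deviation; NN50 counts successive
  differences *strictly* greater than 50 ms. Both conventions are pinned
  by an independent direct-formula oracle test at 1e-9 relative error.
* Frequency-domain settings follow task-force practice and are exposed
  in `SpectralConfig`: 4 Hz linear-interpolation resampling, Welch PSD
  with 5-min Hann segments, 50 % overlap and linear detrending; band
  edges LF 0.04–0.15 Hz, HF 0.15–0.40 Hz, TP 0.0033–0.40 Hz, integrated
  half-open so LF and HF never double-count the shared 0.15 Hz bin.
  Powers are reported in ms².
* "Insufficient data for spectral estimation" is operationalized as
  fewer than two intervals **or** less than 5 min of interpolable
  tachogram; such windows carry −1 in LF/HF/LF-HF/TP. If HF is exactly
  zero the LF/HF ratio is also −1 (with a warning) rather than ±inf, so
  feature matrices stay finite. A window is `valid` iff it has at least
  two intervals; `valid=False` implies the full nine-metric sentinel
  block and exclusion from scaler statistics and attention.
* The long-term summaries are computed over the *entire* recording
  (3–7 days), with HR values as instantaneous-rate transforms
  (HR = 60000/RR), so minHR pairs with maxRR. meanRMSSD averages RMSSD
  over valid windows only.

## Feature assembly

* Standardization is Yeo–Johnson (per-feature maximum-likelihood λ via
  `scipy.stats.yeojohnson_normmax`) followed by z-scoring, fit on the
  training fold only; the fitted state records the fold's patient ids so
  leave-one-out hygiene is assertable. Zero-variance features are
  centered and passed through; all-sentinel features are flagged and
  passed through untransformed.
* Sentinel entries (−1) never enter transform statistics; after
  standardization masked rows carry the fill value 0 plus a mask
  channel. The raw −1 convention is preserved in feature tables for
  auditability.
* Interaction terms are a declared default, not a reconstruction:
  per-window `RMSSD × (60000/meanNN)` (variability scaled by
  instantaneous rate) and `LF/HF × SDNN` (sympathovagal balance weighted
  by overall variability). The set is config-visible and recorded with
  the run.
* Variable sequence lengths are padded to the batch maximum with
  mask-false rows; the attention's exact masking makes predictions
  provably invariant to padding.

## Model

* Architecture: LSTM(64) → LSTM(32) → LSTM(16) → context attention →
  concat(pooled, context) → dense(16, tanh, dropout) → dense(1). The
  attention is additive, $e_t = v^\top\tanh(W_h h_t + W_c c + b)$, the
  minimal form in which a static clinical context vector can modulate
  temporal weighting; a bilinear variant ($e_t = h_t^\top W_b c$) is a
  config switch. Masked steps receive −inf scores and exactly zero
  weight.
* The network is implemented directly in numpy with hand-derived
  backpropagation (fused-gate BPTT); the test suite checks every
  parameter's analytic gradient against central finite differences for
  both attention forms. Training is Adam (lr 0.001), batch size 8, MSE,
  L2 weight decay 0.001 on weight matrices, dropout 0.5 after attention
  pooling and inside the head (not on recurrent connections), early
  stopping on training loss with patience 10 and `max_epochs` 200 —
  under LOOCV at n≈50 there is no room for an inner validation split.
  The best-epoch parameters are restored at the end. All randomness
  (init, shuffling, dropout) derives from `random_state`.
* **Regression target.** The raw NT-proBNP change is heavy-tailed
  (baseline values are log-normal with sd in the thousands of pg/mL), so
  a plain MSE on deltas is dominated by a handful of high-baseline
  patients and barely sees the sign of the rest. The default target is
  therefore the standardized log follow-up/baseline ratio, inverted
  through the patient's own baseline for pg/mL reporting; the scaled raw
  delta remains available (`target_transform="scaled_delta"`). Head
  size 16 with tanh is a declared default.

## Evaluation

* LOOCV refits scalers and model per fold; per-fold seeds derive from
  `crc32(f"{seed}:{patient_id}")`, so folds are reproducible in any
  execution order. Each fold records a SHA-256 fingerprint of every
  training patient's features and outcome, making the held-out patient's
  absence provable after the fact.
* Direction labels binarize the change as increase vs decrease/stable
  with exact zero assigned to decrease/stable, for both truth and
  prediction. An alternative would be a tolerance band around "stable";
  the strict sign rule is the simplest reading and is what the metrics
  here mean.
* The report exposes per-fold absolute-error quartiles because fold-wise
  error dispersion in this problem largely reflects baseline
  heterogeneity, not model instability; the trajectory figure overlays
  per-patient spaghetti lines with observed and predicted group means ±
  95 % normal-approximation CIs.

## Synthetic cohort

* Clinical covariates: continuous variables are truncated-normal or
  log-normal fits to published median/IQR pairs (age truncated to
  [40, 95]; NT-proBNP log-normal with median 1344 pg/mL and IQR
  708–3527.5); binary flags are Bernoulli at the published prevalences
  (HFpEF prevalence 1.0 by design — it is a constant feature and
  exercises the zero-variance scaler path). Hb, platelet, uric acid and
  TR Vmax have no published distribution; standard adult cardiology
  reference values are used.
* RR streams: shifted-gamma intervals (300 ms floor) around the
  patient's mean RR with sd `rr_dispersion`, lightly smoothed (0.85/0.15
  AR blend) for short memory, multiplicatively modulated at 0.1 Hz
  (amplitude `lf_modulation_amp`) and over 24 h (circadian), clipped to
  300–2000 ms and accumulated into integer-ms timestamps. The smoothing
  attenuates the realized sd by ~14 % relative to `rr_dispersion`; the
  parameter is the pre-smoothing draw sd. Noise labels are contiguous
  blocks with exponential lengths (mean 5 min) placed uniformly — an
  assumption, since real device noise statistics are not characterized.
* Outcomes: log follow-up/baseline ratio $y = \mu + \beta b + \epsilon$
  with burden $b \sim N(0,1)$, $\beta = \sigma\sqrt{\text{effect}}$,
  $\mathrm{sd}(\epsilon) = \sigma\sqrt{1-\text{effect}}$, total
  $\sigma = 0.6$ on the log scale (roughly ±80 % swings, consistent with
  the published change dispersion), and $\mu$ set so the expected
  fraction of increases equals `direction_balance` (default 0.5).
  Burden enters the generator through both RR dispersion and LF
  amplitude, so the signal is recoverable through RMSSD and LF — the
  pipeline's actual feature set.
* What the generator does **not** emulate: waveform morphology,
  comorbidity-conditional outcome pathways, device-specific noise
  signatures, non-stationary rhythm changes (cardioversion), or
  measurement error in NT-proBNP assays. Passing tests therefore
  demonstrate pipeline correctness and signal recoverability under the
  stated generative model, not clinical performance on real cohorts.

## Problem sizes in tests

End-to-end checks run at study conditions for cohort size and effect
strength (n = 50, effect 0.6, fixed seed 42) but use 0.5–1-day synthetic
recordings (24–48 windows) and capped training epochs (60 for signal
recovery, 3 for the permutation null), chosen as the analysis sizes for
the suite; the usability-gate thresholds are relaxed accordingly for
those short recordings. Calibration checks use n = 5000. An inherent
ceiling worth noting: at effect strength 0.6 with balanced directions,
the Bayes-optimal directional accuracy is
$\tfrac12 + \arcsin(\sqrt{0.6})/\pi \approx 0.78$ in expectation, so
observed accuracies near 0.8 at n = 50 are at the statistical ceiling,
not evidence of overfitting.

## Known limitations

* The permutation-null experiment permutes outcomes on the log-change
  scale (each patient keeps their own baseline); permuting raw deltas
  can imply negative follow-up concentrations and is not meaningful
  here.
* `yeojohnson_normmax` can be ill-conditioned on near-binary columns;
  the fit falls back to λ = 1 (identity) on optimizer failure.
* The LSTM runs over padded/masked steps (causality plus exact attention
  masking keeps outputs invariant), which wastes some compute on very
  ragged batches.
* Early stopping monitors training loss, so `max_epochs` is an active
  regularizer in small-sample settings; the defaults reflect that.
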