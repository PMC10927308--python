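# Methods

`hypoxeeg` implements a sensor-space resting-state EEG analysis for paired
two-condition studies (the motivating design: the same subjects recorded at
sea level and during acute exposure to 4,000 m altitude), together with a
synthetic-data generator that provides ground truth for every quantity the
analysis estimates. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
does and does not emulate.

## Analysis model

### Spectral decomposition

Per-channel power spectral density is estimated with Welch's method: 4-s
Hann windows, 50% overlap, giving a frequency resolution of 0.25 Hz.
Relative band power is the trapezoidal integral of the PSD over a band
divided by the integral over the broadband range 0.5–30 Hz; the four bands
are δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz (half-open `[low, high)`
convention; a shared edge belongs to the lower band's closed upper edge).
Because it is a ratio of integrals of the same spectrum, relative power is
invariant to global signal rescaling.

The spectrum between 4 and 40 Hz is modeled as an aperiodic background,
linear in log10 power versus log10 frequency (PSD ∝ f^−χ), plus up to six
Gaussian oscillatory peaks in (linear-frequency, log-power) space.
`fit_aperiodic` proceeds in three stages:

1. **Robust line fit.** Ordinary least squares, then points lying above
   the line beyond a low percentile of the positive residuals are dropped
   and the line refit — oscillatory peaks otherwise drag the background
   estimate upward.
2. **Iterative peak stripping.** The largest residual exceeding
   `peak_threshold_sd` (default 2.0) residual standard deviations is fit
   with a Gaussian (σ bounded to [0.25, 6] Hz, i.e. full widths 0.5–12 Hz)
   and subtracted; repeated up to `max_peaks` times.
3. **Final aperiodic refit.** The line is refit on the peak-stripped
   spectrum, *excluding* bins where the fitted peak model exceeds 0.05
   log10 units. Real (and simulated) peaks are not exactly log-Gaussian;
   residual peak skirts left after subtraction would otherwise tilt the
   line. If fewer than 10 bins survive the exclusion, the fit falls back
   to the subtracted spectrum on all bins.

Sign convention: the package reports χ ≥ 0 with PSD ∝ f^−χ. The "1/f
slope" plotted in the EEG literature is −χ, so a *flattened* spectrum
(higher electrophysiological noise) is a *smaller* χ. All outputs state
the convention; a knee term is not modeled, as the 4–40 Hz range on these
signals is well described by a single power law.

### Functional connectivity

The weighted phase lag index between channels x and y is

    wPLI(f) = | E{ Im S_xy(f) } | / E{ |Im S_xy(f)| }

with S_xy the cross-spectrum. Only the imaginary part enters, so
instantaneous (zero-lag) mixing — the signature of scalp volume
conduction — contributes nothing; the index lies in [0, 1] and is
invariant to per-channel amplitude rescaling.

Cross-spectra are estimated on non-overlapping 12-s epochs with DPSS
multitapers (default 7 tapers, time-bandwidth 4). The expectation E is by
default pooled over all epochs × tapers (the lower-variance estimator);
computing wPLI within each epoch and grand-averaging across epochs is
available via `per_epoch=True`. The band value is the unweighted mean of
per-bin wPLI over the band's frequency bins. Pairs with an identically
zero denominator (e.g. a channel against itself, or purely zero-lag
coupling) are set to 0 and counted in a log message.

Overall FC for a subject and band is the mean of the off-diagonal entries
of the weighted, nonthresholded wPLI matrix; nodal strength is its row
sum.

### Graph topology

Weighted matrices are reduced to binary graphs by proportional
thresholding: the top fraction p of upper-triangle weights become edges
(k = round(p·n(n−1)/2)), so all compared networks share edge density.
Ties at the cutoff break by ascending (row, col) index, which makes edge
sets deterministic and nested across increasing p. Metrics on the binary
graph:

* global/nodal efficiency — mean inverse shortest-path length
  (breadth-first distances; unreachable pairs contribute 0);
* transitivity — Σ 2tᵢ / Σ kᵢ(kᵢ−1), collectively normalized;
* nodal clustering — Cᵢ = 2tᵢ / (kᵢ(kᵢ−1)), 0 when kᵢ < 2 (the network
  *mean* clustering is exposed separately);
* degree.

Each metric is evaluated at thresholds 5%–40% in 1% steps (36 points) and
summarized by the trapezoidal area under the curve over the
threshold-fraction axis (a constant metric c integrates to 0.35·c; the
AUC is deliberately not normalized by the range width, since only
condition differences are compared). Degenerate denominators yield 0
throughout.

### Statistics

Condition contrasts use a paired sign-flip permutation test: under the
within-subject null each subject's two condition labels are exchangeable,
so the null distribution of the mean paired difference is built from
independent random sign flips (default 10,000; exhaustive enumeration of
all 2ⁿ patterns available for n ≤ 20). Two-sided p-values use the add-one
rule (1 + #{|null| ≥ |obs|}) / (1 + N), so p = 0 is never reported. An
unpaired full-reshuffle variant is not provided; the paired scheme is the
correct one for this design.

Effect sizes are pooled-SD Cohen's d across the two condition samples
(not the paired dz — with strong between-subject variability this gives
the familiar regime of modest d alongside very small paired p; `cohens_dz`
is available). Age effects: Pearson correlation of each headline metric
with age pooling both conditions, and an age-adjusted re-analysis that
replaces each metric by its residuals from a pooled OLS regression on age
before re-pairing and permuting. Benjamini–Hochberg FDR correction is
applied within each analysis family (e.g. all bands of the global
relative-power contrast; all region × band cells of a nodal metric);
family membership is carried as a column of the study table and is
user-overridable.

### Preprocessing and pipeline

Per recording: broadband zero-phase FIR band-pass (default 0.5–45 Hz;
applied as two FFT-convolution passes of a symmetric Hamming-window
kernel — identical contract to filtfilt but O(n log n)), optional
polyphase downsampling, common average reference; then per band a
zero-phase 3rd-order Bessel band-pass and 12-s epoching for connectivity.
Filters are forward-backward (zero-phase) throughout because the
connectivity metric is phase-based; the doubled effective order is
accepted. Artifact handling (ICA, visual rejection) is intentionally out
of scope — it is a manual step on real data; pre-cleaned recordings enter
directly.

Region-level values are the mean of channel-level values over the
region's channels, computed per subject before testing. The default
partition of the 64-channel 10-20 montage into frontal / frontocentral /
centroparietal / occipitoparietal / temporal regions follows label
prefixes (FT/TP/T temporal; Fp/AF/F frontal; FC/C frontocentral; CP/P
centroparietal; PO/O/I occipitoparietal) and is overridable — published
head-map analyses rarely state exact channel membership, so any fixed
partition is a convention.

## Synthetic-data generator

Each channel is a sum of independent components:

* **Aperiodic background**: white Gaussian noise shaped in the frequency
  domain by f^(−χ/2) (population PSD ∝ f^−χ), DC removed, variance
  normalized to 1. Frequency-domain shaping (rather than an AR process)
  makes the target exponent exact in expectation, which is what a
  recovery oracle needs.
* **Oscillations**: Gaussian-envelope narrowband noise (white noise whose
  FFT is weighted by a Gaussian at the band's center), giving smooth
  realistic spectral peaks for the peak-stripping stage. Default centers
  2/6/10/20 Hz with amplitudes 0.55/0.35/0.65/0.30, which puts roughly
  half of broadband variance into oscillations with the usual resting
  alpha dominance.
* **Coupling**: a shared narrowband source injected into a set of
  channels with a constant frequency-domain phase rotation accumulating
  per channel (frequency-independent lag within the band). Zero-lag
  coupling is deliberately invisible to wPLI.
* **Sensor noise**: white noise, SD 0.05. Kept small so that no flat
  noise floor intrudes on the 4–40 Hz fit range — a floor there compresses
  fitted-exponent differences, which real EEG does not show at these
  frequencies.

The default coupling layout, per band (δ and θ): four modules of eight
channels sharing a source with lag π/4 per position (π/4 increments keep
almost all within-module pair lags away from the wPLI-blind values 0 and
π), plus one "expansion" link from each of the 32 remaining channels to a
module channel (lag π/2, strength 0.28 — around the wPLI noise floor at
25 × 12-s epochs).

Condition effects at altitude (defaults encode the qualitative pattern of
acute hypobaric hypoxia): exponent −0.3 (spectral flattening), α
amplitude ×0.75, δ amplitude ×1.35 (slowing), and coupling boosts ×1.6.
The δ boost scales *all* δ couplings: overall FC rises while the edge
ranking — hence density-matched binarized topology — is essentially
unchanged. The θ boost scales *only the expansion links*: the periphery
is recruited into the coupled core, which raises global efficiency at
matched density. This asymmetry is deliberate; uniformly boosting a fixed
set of clique couplings cannot change proportional-thresholded topology
at all (the same k edges survive), so a topological effect must be
programmed as a change in which pairs are strongly coupled, not how
strongly the same pairs couple.

Subject structure: 16 subjects, ages uniform on 19–45 years, identical
age across a subject's two conditions. The aperiodic exponent is
`exponent_base` (1.5) − 0.02·(age − 19) plus a per-subject normal jitter
(SD 0.08); band amplitudes and coupling strengths carry per-subject
log-normal jitter (SD 0.2 and 0.1). The jitters are drawn once per
subject and shared across conditions, so paired differences stay clean
while pooled between-subject variance is realistic (this is what places
the pooled-SD Cohen's d in a plausible range instead of absurd values).
All randomness flows from a single `numpy` Generator seeded by
`SynthConfig.seed`.

Desk-scale defaults are fs = 256 Hz and 300 s per recording (the
motivating studies use 2048 Hz and ~10 min; both are configurable). At
this scale a full 16-subject study — 32 recordings through synthesis,
preprocessing, spectra, four-band wPLI, 36-threshold graph sweeps, and
10,000-permutation statistics — completes in about 4–5 minutes on one
CPU. Unit tests use further-reduced studies (3–6 subjects, 20–60 s) for
structural and direction checks; the full-scale run is exercised by the
end-to-end acceptance test and `scripts/acceptance.py`.

### What the generator does not emulate

No volume conduction (beyond the zero-lag mixing surrogate used in
tests), no blinks/EMG/line noise, no non-stationarity, no spatially
correlated background, no electrode-position geometry (the region map is
nominal). Passing recovery tests therefore demonstrates correctness of
the estimators and inference chain under the stated generative model, not
robustness to real-world contamination — for real recordings, artifact
cleaning must happen upstream.

## Numerical conventions and edge cases

* Proportional-threshold tie-break: descending weight, then ascending
  (row, col); k = round(p × number of pairs); k = 0 warns and returns an
  edgeless graph.
* wPLI zero-denominator pairs → 0, with a degenerate-pair count logged.
* Transitivity and clustering → 0 when their denominators vanish;
  efficiency of an edgeless graph → 0; unreachable pairs contribute zero
  inverse distance.
* Permutation p uses add-one correction; exact enumeration divides by 2ⁿ.
* The aperiodic fit requires ≥ 10 bins and strictly positive power in the
  fit range; Gaussian peak σ is clipped to [0.25, 6] Hz.
* Epoching floors to complete epochs; the trailing partial segment is
  discarded. Welch and epoching refuse recordings shorter than one
  window/epoch.
* Determinism: identical configs (including seeds) produce bit-identical
  synthetic data and identical result tables.

## Known limitations

* The aperiodic fit is knee-free; spectra with a bend inside the fit
  range would bias χ.
* The θ-integration ground-truth mechanism (periphery recruitment) is one
  of many network reconfigurations that produce an efficiency increase;
  the pipeline recovers its direction and significance but the AUC
  difference magnitude is specific to the layout.
* Cohen's d is computed in its pooled two-sample form on paired data by
  design; users wanting the paired standardization should use
  `cohens_dz`.
* Real-data (EDF/BDF) ingestion is implemented and documented but not
  exercised by the test suite, which is synthetic-only.
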