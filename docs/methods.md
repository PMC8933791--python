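# Methods

## The analysis in one paragraph

`psckit` analyses spontaneous postsynaptic currents (sEPSCs/sIPSCs) in
whole-cell voltage-clamp recordings. Events are detected when their
baseline-subtracted peak amplitude exceeds five times the root-mean-square
baseline noise; for each accepted event the package measures amplitude,
inter-event interval (IEI), 10–90% rise time and charge (area under the
waveform), and per cell the event frequency and the charge transfer per
second (frequency × mean per-event charge, an exact identity). Isolated
events (onset more than 200 ms from any other event or artifact) are aligned
at their 50%-rise point and fed to ensemble non-stationary noise analysis
(NSNA): the ensemble variance σ² at each time bin is regressed on the
ensemble mean current I through

    σ² = i·I − I²/N + b

to estimate the unitary channel current *i* (pA), the number of channels *N*
open at the peak of the mean current, and the background variance *b* (pA²).
Cohorts are compared with two-sample Kolmogorov–Smirnov tests on pooled
event-level distributions and Mann–Whitney U tests on per-cell quantities,
summarised as median, interquartile range and 5–95% interval.

## The generative model behind the simulator

No recordings ship with the package; every stage is validated by parameter
recovery on synthetic recordings. The simulator realises exactly the model
under which the NSNA parabola is the true variance–mean relation:

- each synaptic event drives `N` independent channels of unitary current `i`;
- the per-channel open probability follows a biexponential waveform
  `p(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` normalised to a peak `p_peak`;
- the number of open channels in each time bin is an independent
  `Binomial(N, p(t))` draw, so the event current has bin-wise mean `N·i·p`
  and variance `N·i²·p(1−p)`;
- event onsets form a homogeneous Poisson process, overlapping events
  superpose linearly;
- white Gaussian baseline noise of chosen RMS is added, optionally shaped by
  a 4-pole Bessel low-pass (the patch-clamp hardware convention);
- inward currents carry negative sign; all reported amplitudes and charges
  are magnitudes.

Defaults emulate the study conditions the package targets: 120 s sweeps
digitised at 20 kHz, holding potential −60 mV, τ_r = 0.5 ms, τ_d = 5 ms,
p_peak = 0.8, baseline RMS 2 pA, N = 93 channels, i = 1 pA (sEPSC-like; the
sIPSC-like presets use i = 2.9/2.1 pA for control/treated cohorts). The
cohort presets pool ≈76 events over 10 control cells and ≈278 events over 12
treated cells per 120 s (rates 0.0633 Hz and 0.193 Hz ≈ 3×), with the
treated cohort's unitary current scaled by 0.8.

What the simulator deliberately does not model: Markov channel kinetics with
dwell-time correlations (gating is bin-independent), series-resistance and
space-clamp distortion, temperature effects, receptor pharmacology, and
cell-to-cell parameter heterogeneity within a cohort. Passing recovery tests
therefore demonstrates the correctness of the estimators under their own
generative assumptions, not robustness to every biological nuisance in real
recordings.

## Detection

- **Noise RMS.** The default estimator is robust: 1.4826 × the median
  absolute deviation of the first-differenced trace, divided by √2 to undo
  the variance doubling of differencing. Differencing removes slow drift,
  and synaptic events occupy too few samples to move the median; a naive
  whole-trace standard deviation is available for comparison and is visibly
  inflated by events.
- **Candidate peaks** are picked on a lightly smoothed copy of the
  polarity-rectified trace (boxcar of a quarter of the 2 ms refractory
  distance) with `scipy.signal.find_peaks`, using the threshold as height, a
  refractory `distance`, and prominence of half the threshold so that a
  genuine event riding another event's decay is split off while shot-like
  gating noise on a single event plateau is not. Amplitude is measured on
  the smoothed trace against the local pre-onset baseline (mean of a 5 ms
  window); kinetics and charge are measured on the raw trace.
- **Onset** is the last sample below 10% of the event amplitude before the
  peak (backward scan), which feeds the 50%-rise alignment cleanly.
- **Polarity** can be fixed or inferred (`auto`) from the skewness of the
  sample distribution — events dominate one tail.
- **Artifact rules** replace manual curation with logged flags, applied in
  order: `too_fast` (onset-to-peak under 2 samples, i.e. spike-like),
  `no_decay` (no return to half amplitude within 100 ms), `saturated`
  (≥5 identical samples at the peak value, i.e. clipping), `baseline_drift`
  (pre-event baseline halves differing by more than 3×RMS). The rules are
  idempotent and conservative; on clean simulated fixtures they flag
  nothing.

## Event metrics

- **Rise time** interpolates both the 10% and 90% crossings linearly between
  samples; closed forms (τ·ln 9 for a mono-exponential) are reproduced to
  within one sampling interval.
- **Charge** integrates the polarity-corrected, baseline-subtracted current
  (trapezoid rule) from onset to the first *sustained* return to within one
  RMS of baseline — the return must hold for 1 ms so a single noise dip does
  not truncate the decay — capped at 200 ms past onset, with a flag when the
  trace ends first. The integral is signed rather than rectified:
  rectifying |current| would add ≈0.8·RMS of positive bias per low-signal
  sample, which is material at modest signal-to-noise; the signed integral
  is unbiased and is clipped at zero at the end. The sustained-return
  endpoint loses only the tail below ≈0.2·RMS (relative error ≈0.15/SNR),
  keeping recovered charge within 5% of truth at SNR ≥ 10.
- **IEIs** are within-cell only, between consecutive accepted onsets; the
  first event of a recording contributes none. Pooled distributions
  concatenate per-cell lists.

## NSNA

- **Isolation** is onset-to-onset: an event is kept when no other detected
  event *or artifact* has an onset within 200 ms on either side.
  (Edge-to-edge distance would be the stricter alternative; onset-to-onset
  is used because onsets are the robustly estimated landmarks.)
- **Alignment** shifts each event by a fractional number of samples (linear
  interpolation) so its 50%-amplitude rising crossing sits at a fixed
  column. Each row's re-measured crossing residual is its alignment quality
  score; a cell is excluded from NSNA when the median |residual| reaches
  0.5 samples.
- **Interpolation variance correction.** Under bin-independent gating, a row
  interpolated by fractional shift f has its stochastic bin variance scaled
  by (1−f)²+f² (mixing two independent draws). With crossing-measurement
  jitter of order one sample, the fractional parts are effectively uniform
  and the ensemble variance would deflate by ≈1/3, biasing i low and N high
  by the same factor. Each column's variance is therefore divided by the
  mean of (1−f)²+f² over the shifts actually applied. For real recordings
  with temporally correlated gating the factor computed this way is still
  applied but has ≈ no effect beyond the (correct) white-noise part; it is
  measured from the data, never assumed.
- **Curve construction** uses the decay phase only (from the ensemble-mean
  peak onward) — rise-phase alignment asynchrony inflates variance — and by
  default pools time bins into 10 equal-width mean-current bins. Each pooled
  point carries mean(I), mean(σ²), *and* mean(I²): the within-bin average of
  i·I − I²/N is i·mean(I) − mean(I²)/N, so using mean(I)² as the quadratic
  regressor would bias i by a few percent independent of ensemble size.
  Unbinned per-time-bin fitting is available.
- **Fit.** The parabola is linear in (i, −1/N, b), so the fit is a bounded
  weighted linear least squares (`scipy.optimize.lsq_linear`, BVLS) with
  i ≥ 0, −1/N ≤ 0, b ≥ 0 — deterministic, no initialisation. Weights follow
  Var(s²) ≈ 2σ⁴/(n−1): proportional to pooled-bin size divided by the
  squared predicted variance, iterated twice from an unweighted pass; plain
  least squares is an option, and b can alternatively be fixed to a measured
  baseline variance. A curve with no resolvable curvature returns N = ∞
  with an explicit flag rather than a spurious finite value. Preconditions:
  ≥ 5 points spanning at least half the peak mean current.
- **Per-cell fitting.** Fits are per cell (then compared across cells), not
  pooled across cells, matching how per-cell distributions of N and i are
  reported downstream.

## Cohort statistics

- **KS tests** on event-level variables pool events across a cohort's cells.
  This reproduces the classic event-pooling design (and its
  pseudoreplication) deliberately; in the simulator cells within a cohort
  are exchangeable, so the test is nominal there. The exact p-value (used
  for tie-free samples with n₁·n₂ ≤ 10⁴) is computed in-package by an
  integer lattice-path recursion identical to exhaustive permutation
  enumeration; larger or tied samples use the asymptotic formula. (scipy's
  exact method silently falls back to the asymptotic value on some small
  tie-free inputs, which is why the exact branch is native.)
- **Mann–Whitney** U uses midranks; p is exact by enumeration over all
  C(n₁+n₂, n₁) assignments when n₁+n₂ ≤ 12 (valid under ties), otherwise a
  normal approximation with tie and continuity corrections.
- **Summaries** are median, quartiles and 5–95% bounds with linear
  (type-7) interpolation, stated in output metadata. Tests are two-sided at
  α = .05 with no multiple-testing correction. An optional 100 pA amplitude
  cut-off can be applied to pooled amplitudes before testing (off by
  default; used for sIPSC-style analyses).

## Problem sizes used by the evaluation harnesses

`psckit.benchmarks` (shared by the test suite and
`scripts/acceptance.py`):

- NSNA recovery: ensembles of 250 isolated events on a ~125 s, 20 kHz trace
  (onsets on a 500 ms grid with ±20 ms jitter so every event clears the
  200 ms isolation rule), 50–100 seeded replicates.
- Detection operating point: 120 s, 20 kHz traces at 0.5 Hz event rate
  (amplitude ≈ 74 pA against a ≈10 pA threshold) plus event-free noise
  traces; onset matching tolerance 5 ms.
- Cohort studies: 10 control vs 12 treated cells, 120 s each, simulated at
  5 kHz — the package's analysis-scale choice for replicate studies; the
  rate/amplitude contrasts and the IEI, amplitude, and charge comparisons
  are sampling-rate-insensitive, and per-study results at 20 kHz agree.

## Known limitations

- The variance correction for interpolation assumes the per-bin noise is
  white at the sampling rate; heavy low-pass filtering correlates
  neighbouring bins and makes the correction slightly conservative.
- Charge under-estimates by ≈0.15/SNR·100% due to the endpoint rule; events
  truncated by the trace end are flagged but their partial charge is kept.
- The detector thresholds baseline-subtracted peak amplitude; deflections
  riding a decaying tail are measured against their local pre-onset
  baseline, so amplitudes of heavily overlapping events are approximate.
- NSNA assumes all aligned events share (N, i); heterogeneous synapses bias
  the fit toward amplitude-variance inflation (larger apparent i).
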