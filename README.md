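# psckit

Analysis of spontaneous postsynaptic currents (sEPSCs/sIPSCs) from
whole-cell voltage-clamp recordings: threshold event detection, per-event
kinetics and charge transfer, ensemble non-stationary noise analysis, and
nonparametric cohort comparison — plus a channel-level recording simulator
so that every stage can be validated by parameter recovery, without any
real recordings.

## Who it is for

Cellular electrophysiologists comparing spontaneous synaptic activity
between groups of cells (e.g. treated vs control cohorts). The pipeline
reproduces the classic analysis chain: detect events at 5× the RMS baseline
noise, measure amplitude, inter-event interval (IEI), 10–90% rise time and
per-event charge, summarise each cell by event frequency and charge
transfer per second (frequency × mean charge), and compare cohorts with
two-sample Kolmogorov–Smirnov tests on pooled event distributions and
Mann–Whitney U tests on per-cell quantities (median / IQR / 5–95%
summaries).

At its core is ensemble **non-stationary noise analysis (NSNA)**: events
more than 200 ms from any neighbour are aligned at their 50%-rise point,
and the ensemble variance σ² is regressed on the ensemble mean current I:

    σ² = i·I − I²/N + b

estimating the unitary channel current *i* (pA), the number of channels *N*
open at the peak of the mean current, and the background variance *b*
(pA²). The fit is a bounded weighted linear least squares on the parabola
(linear in i, −1/N, b), so it is deterministic and exact on noiseless data.

The simulator generates recordings under the model that makes this relation
exact — N independent channels of current i gating along a biexponential
open-probability waveform, binomially sampled per time bin, on Gaussian
baseline noise with Poisson event timing — so recovering (i, N, b) from a
simulated recording is a true end-to-end test of the pipeline.

## Worked example

```python
from psckit import (SimulationConfig, simulate_nsna_ensemble_trace,
                    detect_events, apply_artifact_rules, analyze_cell,
                    compute_event_metrics, summarize_cell)

cfg = SimulationConfig(n_channels=93, unitary_current_pa=1.0,
                       peak_open_prob=0.8, baseline_rms_pa=2.0, seed=1)
trace, truth = simulate_nsna_ensemble_trace(cfg, n_events=250)

catalog = apply_artifact_rules(detect_events(trace))
print(f"noise RMS {catalog.rms_noise_pa:.2f} pA, "
      f"{len(catalog.accepted_events)} events accepted")

table = compute_event_metrics(catalog)
cell = summarize_cell(table, trace.duration_s)
print(f"frequency {cell.frequency_hz:.3f} Hz, "
      f"charge transfer {cell.charge_transfer_pc_per_s:.3f} pC/s")

fit = analyze_cell(catalog)
print(f"i = {fit.unitary_current_pa:.3f} pA, N = {fit.n_channels:.1f}, "
      f"b = {fit.background_variance_pa2:.2f} pA^2")
```

Output:

```
noise RMS 2.04 pA, 250 events accepted
frequency 1.996 Hz, charge transfer 0.958 pC/s
i = 0.994 pA, N = 93.4, b = 4.06 pA^2
```

The detector recovers the injected noise level (2 pA), accepts all 250
simulated events, and the noise analysis recovers the simulated unitary
current (1 pA), channel count (93) and background variance (2² = 4 pA²)
to within a few percent.

A command-line surface wraps the same functions:

```bash
psc simulate --config sim.toml --out cell01.h5 --seed 42
psc detect   --trace cell01.h5 --out cell01.events.tsv
psc metrics  --trace cell01.h5 --events cell01.events.tsv --out cell01.metrics.tsv
psc nsna     --trace cell01.h5 --events cell01.events.tsv --out cell01.nsna.json
psc run      --config study.toml --out results/ --seed 7
```

Traces travel as HDF5 (`/current_pA` + header attributes) or two-column
CSV; event tables as TSV; reports as JSON; configurations as TOML. A run
manifest records configuration hashes and seeds, and identical
configuration + seed reproduces byte-identical outputs.

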