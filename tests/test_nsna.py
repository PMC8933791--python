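"""Noise analysis: isolation rule, 50%-rise alignment, variance–mean curve,
and the parabola fit σ² = iI − I²/N + b."""

import math

import numpy as np
import pytest

from conftest import FS, catalog_from_onsets, make_event, trace_with_kernels
from psckit.detect import apply_artifact_rules, detect_events
from psckit.nsna import (
    AlignmentQualityError,
    EnsembleAlignment,
    VarianceMeanCurve,
    align_events,
    analyze_cell,
    ensemble_variance_mean,
    fit_variance_mean,
    select_isolated_events,
)
from psckit.simulate import (
    SimulationConfig,
    open_probability_waveform,
    sample_event_current,
    simulate_nsna_ensemble_trace,
)


class TestIsolation:
    def test_close_pair_excluded(self):
        cat = catalog_from_onsets([0.10, 0.25, 0.60])
        kept = select_isolated_events(cat)
        assert [e.onset_index for e in kept] == [int(0.60 * FS)]

    def test_single_event_retained(self):
        assert len(select_isolated_events(catalog_from_onsets([0.5]))) == 1

    def test_well_spaced_all_retained(self):
        cat = catalog_from_onsets(np.arange(10) * 0.5 + 0.3)
        assert len(select_isolated_events(cat)) == 10

    def test_artifacts_disqualify_neighbours(self):
        cat = catalog_from_onsets(
            [0.5, 0.6, 1.5], flags=["accepted", "artifact:too_fast", "accepted"]
        )
        kept = select_isolated_events(cat)
        # the artifact at 0.6 s sits within 200 ms of the 0.5 s event
        assert [e.onset_index for e in kept] == [int(1.5 * FS)]


class TestAlignment:
    def test_identical_events_have_zero_ensemble_variance(self):
        onsets = (np.arange(8) * 0.5 * FS).astype(int) + 2000
        trace = trace_with_kernels(onsets, 50.0, duration_s=5.0, sign=-1)
        pk_off = int(np.argmax(-trace.samples[onsets[0] :]))
        events = [make_event(int(o), int(o) + pk_off, 50.0, sign=-1) for o in onsets]
        al = align_events(trace, events, window_ms=40.0)
        assert al.n_events == 8
        assert al.waveforms.var(axis=0).max() < 1e-18

    def test_single_row_mean_equals_waveform(self):
        onsets = (np.array([0.5, 2.0]) * FS).astype(int)
        trace = trace_with_kernels(onsets, 50.0, duration_s=3.0, sign=-1)
        pk_off = int(np.argmax(-trace.samples[onsets[0] :]))
        events = [make_event(int(o), int(o) + pk_off, 50.0, sign=-1) for o in onsets]
        al = align_events(trace, events, window_ms=40.0)
        assert np.allclose(al.ensemble_mean(), al.waveforms[0], atol=1e-12)

    def test_subsample_shift_residual_below_half_sample(self):
        # one kernel sampled on-grid, one shifted by 0.3 samples
        k_on = 50.0 * open_probability_waveform(0.5, 5.0, 1.0, 1000.0 / FS)
        t = np.arange(k_on.size) - 0.3
        tau_r, tau_d = 0.5 / (1000 / FS), 5.0 / (1000 / FS)
        t_star = (tau_r * tau_d / (tau_d - tau_r)) * math.log(tau_d / tau_r)
        norm = math.exp(-t_star / tau_d) - math.exp(-t_star / tau_r)
        k_off = np.where(t > 0, 50.0 * (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / norm, 0.0)
        x = np.zeros(int(3 * FS))
        x[2000 : 2000 + k_on.size] += k_on
        x[30000 : 30000 + k_off.size] += k_off
        from psckit.simulate import Trace

        trace = Trace(samples=x, sampling_rate_hz=FS)
        events = [
            make_event(2000, 2000 + int(np.argmax(k_on)), 50.0, sign=1),
            make_event(30000, 30000 + int(np.argmax(k_off)), 50.0, sign=1),
        ]
        al = align_events(trace, events, window_ms=40.0)
        assert np.abs(al.alignment_residuals).max() < 0.5

    def test_requires_two_events(self):
        trace = trace_with_kernels([1000], 50.0, duration_s=1.0)
        with pytest.raises(ValueError):
            align_events(trace, [make_event(1000, 1030, 50.0, sign=-1)])


def _alignment_from_matrix(w: np.ndarray) -> EnsembleAlignment:
    return EnsembleAlignment(
        waveforms=w,
        alignment_column=0,
        sampling_rate_hz=FS,
        fractional_shifts=np.zeros(w.shape[0]),
        alignment_residuals=np.zeros(w.shape[0]),
    )


class TestVarianceMean:
    def test_two_identical_rows_zero_variance(self):
        w = np.tile(np.linspace(10, 0, 50), (2, 1))
        curve = ensemble_variance_mean(_alignment_from_matrix(w), n_bins=None)
        assert np.all(curve.variance_pa2 == 0.0)

    def test_binomial_ensemble_on_parabola(self, rng):
        # σ² = iI − I²/N for N=50, i=2, p_peak=0.8, no baseline noise
        N, i = 50, 2.0
        p = open_probability_waveform(0.5, 5.0, 0.8, 1000.0 / FS)
        w = np.vstack([sample_event_current(p, N, i, rng) for _ in range(500)])
        curve = ensemble_variance_mean(_alignment_from_matrix(w), n_bins=None)
        theory = i * curve.mean_current_pa - curve.mean_current_pa**2 / N
        se = theory * math.sqrt(2.0 / (500 - 1)) + 1e-9
        frac_in = np.mean(np.abs(curve.variance_pa2 - theory) <= 3 * se)
        assert frac_in > 0.99
        assert np.all(np.abs(curve.variance_pa2 - theory) <= 7 * se)

    def test_additive_noise_raises_variance_by_its_variance(self, rng):
        p = open_probability_waveform(0.5, 5.0, 0.8, 1000.0 / FS)
        w = np.vstack([sample_event_current(p, 50, 2.0, rng) for _ in range(800)])
        v = 9.0
        wn = w + rng.normal(0, math.sqrt(v), size=w.shape)
        c0 = ensemble_variance_mean(_alignment_from_matrix(w), n_bins=None, decay_only=False)
        c1 = ensemble_variance_mean(_alignment_from_matrix(wn), n_bins=None, decay_only=False)
        shift = c1.variance_pa2.mean() - c0.variance_pa2.mean()
        assert shift == pytest.approx(v, rel=0.1)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            ensemble_variance_mean(_alignment_from_matrix(np.ones((1, 10))))


class TestParabolaFit:
    def test_noiseless_fit_exact_to_six_digits(self):
        i, N, b = 2.0, 50.0, 1.0
        I = np.linspace(0.0, 80.0, 25)
        s2 = i * I - I**2 / N + b
        fit = fit_variance_mean(VarianceMeanCurve(I, s2, n_events=100))
        assert fit.unitary_current_pa == pytest.approx(i, rel=1e-7)
        assert fit.n_channels == pytest.approx(N, rel=1e-7)
        assert fit.background_variance_pa2 == pytest.approx(b, rel=1e-6)
        # parabola peak at I = iN/2 with height i²N/4 + b
        I_apex = fit.unitary_current_pa * fit.n_channels / 2
        assert float(fit.predict(np.array([I_apex]))[0]) == pytest.approx(
            i**2 * N / 4 + b, rel=1e-7
        )

    def test_linear_curve_reports_unbounded_n(self):
        I = np.linspace(0.0, 40.0, 15)
        fit = fit_variance_mean(VarianceMeanCurve(I, 1.5 * I, n_events=50))
        assert fit.n_unbounded
        assert math.isinf(fit.n_channels)
        assert fit.unitary_current_pa == pytest.approx(1.5, rel=1e-6)

    def test_current_scaling_equivariance(self):
        i, N, b = 1.0, 93.0, 4.0
        I = np.linspace(0.0, 74.0, 20)
        s2 = i * I - I**2 / N + b
        c = 3.0
        fit1 = fit_variance_mean(VarianceMeanCurve(I, s2, n_events=100))
        fit2 = fit_variance_mean(VarianceMeanCurve(c * I, c**2 * s2, n_events=100))
        assert fit2.unitary_current_pa == pytest.approx(c * fit1.unitary_current_pa, rel=1e-6)
        assert fit2.n_channels == pytest.approx(fit1.n_channels, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_variance_mean(VarianceMeanCurve(np.zeros(10), np.ones(10), n_events=10))
        with pytest.raises(ValueError):
            fit_variance_mean(
                VarianceMeanCurve(np.linspace(30, 40, 10), np.ones(10), n_events=10)
            )  # spans < 50% of peak
        with pytest.raises(ValueError):
            fit_variance_mean(VarianceMeanCurve(np.arange(3.0), np.ones(3), n_events=10))


class TestEndToEndRecovery:
    def test_background_variance_recovered(self):
        cfg = SimulationConfig(baseline_rms_pa=2.0, seed=23)
        trace, _ = simulate_nsna_ensemble_trace(cfg, n_events=250)
        fit = analyze_cell(apply_artifact_rules(detect_events(trace)))
        # injected background variance = 4 pA²; allow Monte-Carlo spread
        assert fit.background_variance_pa2 == pytest.approx(4.0, rel=0.15)

    def test_estimator_consistency_in_ensemble_size(self, rng):
        # median |i − î| over seeds decreases with ensemble size
        N, i = 93, 1.0
        p = open_probability_waveform(0.5, 5.0, 0.8, 1000.0 / FS)
        sizes = (50, 100, 250, 500)
        med_err = []
        for n in sizes:
            errs = []
            for _ in range(50):
                w = i * rng.binomial(N, np.tile(p, (n, 1)))
                curve = ensemble_variance_mean(_alignment_from_matrix(w.astype(float)))
                fit = fit_variance_mean(curve)
                errs.append(abs(fit.unitary_current_pa - i))
            med_err.append(np.median(errs))
        assert all(a > b for a, b in zip(med_err, med_err[1:]))

    def test_alignment_quality_gate(self, monkeypatch):
        cfg = SimulationConfig(baseline_rms_pa=2.0, seed=29)
        trace, _ = simulate_nsna_ensemble_trace(cfg, n_events=30)
        catalog = apply_artifact_rules(detect_events(trace))

        import psckit.nsna as nsna_mod

        real_align = nsna_mod.align_events

        def misaligned(*args, **kwargs):
            al = real_align(*args, **kwargs)
            al.alignment_residuals = al.alignment_residuals + 1.0
            return al

        monkeypatch.setattr(nsna_mod, "align_events", misaligned)
        with pytest.raises(AlignmentQualityError):
            nsna_mod.analyze_cell(catalog)

    def test_too_few_isolated_events(self):
        cfg = SimulationConfig(baseline_rms_pa=2.0, seed=31)
        trace, _ = simulate_nsna_ensemble_trace(cfg, n_events=5)
        with pytest.raises(ValueError, match="isolated"):
            analyze_cell(apply_artifact_rules(detect_events(trace)))
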