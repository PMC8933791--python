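"""Shared helpers: deterministic synthetic traces and hand-built events."""

from __future__ import annotations

import numpy as np
import pytest

from psckit.detect import DetectedEvent, EventCatalog
from psckit.simulate import Trace, open_probability_waveform

FS = 20_000.0
DT_MS = 1000.0 / FS


def biexp_kernel(amplitude_pa: float, tau_rise_ms: float = 0.5, tau_decay_ms: float = 5.0,
                 fs: float = FS) -> np.ndarray:
    """Deterministic biexponential event waveform peaking at ``amplitude_pa``."""
    p = open_probability_waveform(tau_rise_ms, tau_decay_ms, 1.0, 1000.0 / fs)
    return amplitude_pa * p


def trace_with_kernels(onset_indices, amplitude_pa, duration_s=2.0, noise_sd=0.0,
                       seed=0, fs=FS, sign=-1, **kernel_kw) -> Trace:
    """Trace containing identical deterministic events at given sample onsets."""
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    k = biexp_kernel(amplitude_pa, fs=fs, **kernel_kw)
    for idx in np.atleast_1d(onset_indices):
        stop = min(idx + k.size, n)
        x[idx:stop] += sign * k[: stop - idx]
    return Trace(samples=x, sampling_rate_hz=fs)


def make_event(onset_index: int, peak_index: int, amplitude_pa: float,
               baseline_pa: float = 0.0, sign: int = 1, flag: str = "accepted") -> DetectedEvent:
    return DetectedEvent(onset_index=onset_index, peak_index=peak_index,
                         baseline_pa=baseline_pa, amplitude_pa=amplitude_pa,
                         sign=sign, flag=flag)


def catalog_from_onsets(onsets_s, fs=FS, duration_s=None, rms=1.0,
                        flags=None) -> EventCatalog:
    """Catalog of synthetic accepted events on a silent trace (for interval
    and isolation logic that only touches onsets/flags)."""
    onsets_s = np.atleast_1d(onsets_s).astype(float)
    duration_s = duration_s or (onsets_s.max() + 1.0 if onsets_s.size else 1.0)
    trace = Trace(samples=np.zeros(int(duration_s * fs)), sampling_rate_hz=fs)
    flags = flags or ["accepted"] * onsets_s.size
    events = [
        make_event(int(round(t * fs)), int(round(t * fs)) + 10, 50.0, flag=fl)
        for t, fl in zip(onsets_s, flags)
    ]
    return EventCatalog(events=events, trace=trace, rms_noise_pa=rms, threshold_pa=5 * rms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
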