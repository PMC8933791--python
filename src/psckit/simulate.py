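"""Synthetic whole-cell voltage-clamp recordings with ground-truth event catalogs.

The generative model is the one under which ensemble non-stationary noise
analysis is exact: each synaptic event drives ``N`` independent channels of
unitary current ``i`` (pA) whose open probability follows a biexponential
waveform ``p(t) ∝ exp(-t/τ_d) − exp(-t/τ_r)`` normalised to a peak open
probability ``p_peak``.  At every time bin the number of open channels is an
independent ``Binomial(N, p(t))`` draw, so the instantaneous current has mean
``N·i·p(t)`` and variance ``N·i²·p(t)(1−p(t))`` — i.e. the ensemble
variance–mean relation ``σ² = iI − I²/N`` holds exactly, with Gaussian
baseline noise adding the background-variance offset ``b``.

Event onsets form a homogeneous Poisson process; overlapping events superpose
linearly.  Traces carry physical sign (inward currents negative) and are
optionally low-pass filtered with a 4-pole Bessel filter, the convention of
patch-clamp acquisition hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal

__all__ = [
    "SimulationConfig",
    "Trace",
    "EventTrain",
    "open_probability_waveform",
    "peak_time_ms",
    "sample_event_current",
    "sample_event_times",
    "simulate_trace",
    "simulate_nsna_ensemble_trace",
    "make_cohort_fixtures",
    "nt_sepsc_config",
    "ht_sepsc_config",
    "nt_sipsc_config",
    "ht_sipsc_config",
]

Polarity = Literal["inward", "outward"]

#: Sampling-rate and duration defaults follow standard spontaneous-current
#: acquisition protocols: 120 s sweeps digitised at 20 kHz, cell held at
#: −60 mV, hardware low-pass in the 1–5 kHz range.
DEFAULT_DURATION_S = 120.0
DEFAULT_SAMPLING_RATE_HZ = 20_000.0
DEFAULT_HOLDING_POTENTIAL_MV = -60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Units are embedded in the field names.  ``n_channels`` and
    ``unitary_current_pa`` are the ground-truth targets of the downstream
    noise analysis; ``event_rate_hz`` is the mean of the Poisson event
    process.
    """

    duration_s: float = DEFAULT_DURATION_S
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    event_rate_hz: float = 0.2
    n_channels: int = 93
    unitary_current_pa: float = 1.0
    peak_open_prob: float = 0.8
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    baseline_rms_pa: float = 2.0
    polarity: Polarity = "inward"
    lowpass_cutoff_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be non-negative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.unitary_current_pa <= 0:
            raise ValueError("unitary_current_pa must be positive")
        if not 0 < self.peak_open_prob <= 1:
            raise ValueError("peak_open_prob must be in (0, 1]")
        if self.tau_rise_ms <= 0:
            raise ValueError("tau_rise_ms must be positive")
        if self.tau_decay_ms <= self.tau_rise_ms:
            raise ValueError("tau_decay_ms must exceed tau_rise_ms")
        if self.baseline_rms_pa < 0:
            raise ValueError("baseline_rms_pa must be >= 0")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        if self.lowpass_cutoff_hz is not None and not (
            0 < self.lowpass_cutoff_hz < self.sampling_rate_hz / 2
        ):
            raise ValueError("lowpass_cutoff_hz must lie below Nyquist")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def polarity_sign(self) -> int:
        return -1 if self.polarity == "inward" else +1


@dataclass
class Trace:
    """One cell's current recording: uniformly sampled current in pA.

    ``samples`` carry physical sign (inward synaptic currents are negative
    deflections).  ``metadata`` holds acquisition context (cell id, cohort,
    holding potential, recording type, filter description).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    t0_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class EventTrain:
    """Ground-truth event onsets and per-event generative parameters."""

    onset_times_s: np.ndarray
    n_channels: np.ndarray
    unitary_current_pa: np.ndarray
    tau_rise_ms: np.ndarray
    tau_decay_ms: np.ndarray
    peak_open_prob: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=np.float64)
        if np.any(np.diff(self.onset_times_s) <= 0):
            raise ValueError("onset times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.onset_times_s.size

    @classmethod
    def from_config(cls, onsets_s: np.ndarray, config: SimulationConfig) -> "EventTrain":
        n = len(onsets_s)
        return cls(
            onset_times_s=np.asarray(onsets_s, dtype=np.float64),
            n_channels=np.full(n, config.n_channels, dtype=np.int64),
            unitary_current_pa=np.full(n, config.unitary_current_pa),
            tau_rise_ms=np.full(n, config.tau_rise_ms),
            tau_decay_ms=np.full(n, config.tau_decay_ms),
            peak_open_prob=np.full(n, config.peak_open_prob),
        )


def peak_time_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time of the maximum of ``exp(-t/τ_d) − exp(-t/τ_r)``.

    Closed form: ``t* = τ_r τ_d / (τ_d − τ_r) · ln(τ_d/τ_r)``.
    """
    return (
        tau_rise_ms
        * tau_decay_ms
        / (tau_decay_ms - tau_rise_ms)
        * math.log(tau_decay_ms / tau_rise_ms)
    )


def open_probability_waveform(
    tau_rise_ms: float,
    tau_decay_ms: float,
    peak_open_prob: float,
    dt_ms: float,
    horizon_ms: float | None = None,
) -> np.ndarray:
    """Biexponential open-probability waveform sampled on a uniform grid.

    ``p(t) = p_peak · (exp(-t/τ_d) − exp(-t/τ_r)) / c`` with ``c`` the
    analytic maximum of the difference of exponentials, so ``max p = p_peak``
    exactly at the (generally off-grid) peak time.  ``p(0) = 0`` and
    ``p → 0`` as ``t → horizon``.
    """
    if tau_rise_ms <= 0 or tau_decay_ms <= 0:
        raise ValueError("time constants must be positive")
    if tau_decay_ms <= tau_rise_ms:
        raise ValueError("tau_decay_ms must exceed tau_rise_ms")
    if not 0 < peak_open_prob <= 1:
        raise ValueError("peak_open_prob must be in (0, 1]")
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if horizon_ms is None:
        # e^-12 ≈ 6e-6 of the peak: event fully decayed for all purposes here
        horizon_ms = peak_time_ms(tau_rise_ms, tau_decay_ms) + 12.0 * tau_decay_ms
    t = np.arange(0.0, horizon_ms, dt_ms)
    t_star = peak_time_ms(tau_rise_ms, tau_decay_ms)
    norm = math.exp(-t_star / tau_decay_ms) - math.exp(-t_star / tau_rise_ms)
    p = peak_open_prob * (np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)) / norm
    return np.clip(p, 0.0, 1.0)


def sample_event_current(
    p_waveform: np.ndarray,
    n_channels: int,
    unitary_current_pa: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Current (pA, magnitude) of one event: ``i · Binomial(N, p(t))`` per bin.

    Channel gating is drawn independently in every time bin, so bin-wise mean
    and variance are ``N·i·p`` and ``N·i²·p(1−p)``.
    """
    p = np.asarray(p_waveform, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty open-probability waveform")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if unitary_current_pa <= 0:
        raise ValueError("unitary_current_pa must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return unitary_current_pa * rng.binomial(n_channels, p).astype(np.float64)


def sample_event_times(
    event_rate_hz: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted onset times of a homogeneous Poisson process on [0, duration)."""
    n = rng.poisson(event_rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _bessel_lowpass(x: np.ndarray, cutoff_hz: float, fs_hz: float) -> np.ndarray:
    # 4-pole Bessel as a biquad cascade, the patch-clamp hardware convention
    sos = signal.bessel(4, cutoff_hz, btype="low", fs=fs_hz, output="sos", norm="mag")
    return signal.sosfilt(sos, x)


def _event_component(
    config: SimulationConfig, onsets_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Noiseless superposition of binomially sampled events (magnitude, pA)."""
    n = config.n_samples
    dt_ms = 1000.0 / config.sampling_rate_hz
    out = np.zeros(n)
    if onsets_s.size == 0:
        return out
    p = open_probability_waveform(
        config.tau_rise_ms, config.tau_decay_ms, config.peak_open_prob, dt_ms
    )
    for onset in onsets_s:
        start = int(round(onset * config.sampling_rate_hz))
        stop = min(start + p.size, n)
        if stop <= start:
            continue
        out[start:stop] += sample_event_current(
            p[: stop - start], config.n_channels, config.unitary_current_pa, rng
        )
    return out


def _assemble_trace(
    config: SimulationConfig,
    onsets_s: np.ndarray,
    rng: np.random.Generator,
    metadata: dict | None = None,
) -> tuple[Trace, EventTrain]:
    events = _event_component(config, onsets_s, rng)
    noise = (
        config.baseline_rms_pa * rng.standard_normal(config.n_samples)
        if config.baseline_rms_pa > 0
        else np.zeros(config.n_samples)
    )
    samples = config.polarity_sign * events + noise
    filter_desc = "none"
    if config.lowpass_cutoff_hz is not None:
        samples = _bessel_lowpass(samples, config.lowpass_cutoff_hz, config.sampling_rate_hz)
        filter_desc = f"bessel4@{config.lowpass_cutoff_hz:g}Hz"
    meta = {
        "cell_id": "sim",
        "cohort": "",
        "recording_type": "sEPSC",
        "holding_potential_mv": DEFAULT_HOLDING_POTENTIAL_MV,
        "filter": filter_desc,
    }
    if metadata:
        meta.update(metadata)
    trace = Trace(samples=samples, sampling_rate_hz=config.sampling_rate_hz, metadata=meta)
    train = EventTrain.from_config(onsets_s, config)
    return trace, train


def simulate_trace(
    config: SimulationConfig, metadata: dict | None = None
) -> tuple[Trace, EventTrain]:
    """Simulate one recording: Poisson onsets, binomial channel events,
    Gaussian baseline noise, optional Bessel low-pass, polarity sign.

    Bit-for-bit reproducible for a fixed config (the seed lives in the
    config).
    """
    rng = np.random.default_rng(config.seed)
    onsets = sample_event_times(config.event_rate_hz, config.duration_s, rng)
    return _assemble_trace(config, onsets, rng, metadata)


def simulate_nsna_ensemble_trace(
    config: SimulationConfig,
    n_events: int,
    spacing_s: float = 0.5,
    jitter_s: float = 0.02,
    metadata: dict | None = None,
) -> tuple[Trace, EventTrain]:
    """Simulate a recording of ``n_events`` well-separated events for
    ensemble noise analysis.

    Onsets sit on a regular grid of pitch ``spacing_s`` with uniform jitter
    ``±jitter_s`` so every event clears a 200 ms isolation window on both
    sides.  The trace duration is chosen to fit the train; all other
    generative parameters come from ``config``.
    """
    if spacing_s - 2 * jitter_s <= 0.4:
        raise ValueError("spacing too small to guarantee 200 ms isolation")
    rng = np.random.default_rng(config.seed)
    grid = 0.25 + spacing_s * np.arange(n_events)
    onsets = grid + rng.uniform(-jitter_s, jitter_s, size=n_events)
    duration = float(grid[-1] + 0.5) if n_events else 1.0
    config = replace(config, duration_s=duration, event_rate_hz=0.0)
    return _assemble_trace(config, onsets, rng, metadata)


# --- cohort fixture defaults -------------------------------------------------
#
# Event rates are set so the expected pooled event counts over 120 s sweeps
# match the study design being emulated: the control (NT) excitatory cohort
# pools ~76 events across 10 cells (0.0633 Hz) and the hyperthermia (HT)
# cohort ~278 events across 12 cells (0.193 Hz, ≈3× the control rate) with
# ~20% smaller unitary current.  Channel count 93 and unitary current 1 pA
# for sEPSC-like cells; 2.5 pA unitary current for sIPSC-like cells.

NT_SEPSC_RATE_HZ = 76 / (10 * 120.0)
HT_SEPSC_RATE_HZ = 278 / (12 * 120.0)


def nt_sepsc_config(**overrides) -> SimulationConfig:
    base = dict(event_rate_hz=NT_SEPSC_RATE_HZ, n_channels=93, unitary_current_pa=1.0)
    base.update(overrides)
    return SimulationConfig(**base)


def ht_sepsc_config(**overrides) -> SimulationConfig:
    base = dict(event_rate_hz=HT_SEPSC_RATE_HZ, n_channels=93, unitary_current_pa=0.8)
    base.update(overrides)
    return SimulationConfig(**base)


def nt_sipsc_config(**overrides) -> SimulationConfig:
    base = dict(event_rate_hz=573 / (7 * 120.0), n_channels=93, unitary_current_pa=2.9)
    base.update(overrides)
    return SimulationConfig(**base)


def ht_sipsc_config(**overrides) -> SimulationConfig:
    base = dict(event_rate_hz=1403 / (9 * 120.0), n_channels=93, unitary_current_pa=2.1)
    base.update(overrides)
    return SimulationConfig(**base)


def make_cohort_fixtures(
    nt_config: SimulationConfig,
    ht_config: SimulationConfig,
    cells_per_group: int | tuple[int, int],
    seed: int,
    labels: tuple[str, str] = ("NT", "HT"),
) -> tuple[list[tuple[Trace, EventTrain]], list[tuple[Trace, EventTrain]]]:
    """Simulate two cohorts of cells with per-cell seeds derived from ``seed``.

    ``cells_per_group`` may be a single count or ``(n_nt, n_ht)``.
    Deterministic: the same seed reproduces every trace bit-for-bit.
    """
    if isinstance(cells_per_group, int):
        n_a = n_b = cells_per_group
    else:
        n_a, n_b = cells_per_group
    if n_a < 1 or n_b < 1:
        raise ValueError("cells_per_group must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_a + n_b)
    # keep derived seeds small enough for the config's integer seed field
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    cohorts: list[list[tuple[Trace, EventTrain]]] = [[], []]
    for g, (cfg, n_cells, label) in enumerate(
        [(nt_config, n_a, labels[0]), (ht_config, n_b, labels[1])]
    ):
        for k in range(n_cells):
            cell_seed = child_seeds.pop(0)
            cell_cfg = replace(cfg, seed=cell_seed)
            meta = {"cell_id": f"{label.lower()}{k + 1:02d}", "cohort": label}
            cohorts[g].append(simulate_trace(cell_cfg, metadata=meta))
    return cohorts[0], cohorts[1]
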