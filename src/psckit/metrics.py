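"""Per-event kinetics and charge, and per-cell summaries.

Amplitudes and charges are reported as magnitudes so inward and outward
events are directly comparable; inter-event intervals are computed within a
cell between consecutive accepted onsets; the per-second charge transfer is
the exact product of event frequency and mean per-event charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectedEvent, EventCatalog
from .simulate import Trace

__all__ = [
    "CellSummary",
    "rise_time_10_90",
    "event_charge",
    "inter_event_intervals",
    "compute_event_metrics",
    "summarize_cell",
]

#: Charge integration stops at the first sustained return of the deflection
#: to within one RMS of baseline, capped at this many ms past the onset.
CHARGE_WINDOW_CAP_MS = 200.0
#: The return to baseline must hold for this long to end the integration
#: window; a brief noise dip into the baseline band does not truncate the
#: event's decay.
CHARGE_RETURN_HOLD_MS = 1.0


@dataclass(frozen=True)
class CellSummary:
    """Per-cell summary: event frequency and charge transfer per second.

    ``charge_transfer_pc_per_s = frequency_hz × mean_charge_per_event_pc``
    holds as an exact identity.
    """

    cell_id: str
    cohort: str
    n_events: int
    duration_s: float
    frequency_hz: float
    mean_charge_per_event_pc: float
    charge_transfer_pc_per_s: float


def _deflection(
    trace: Trace, event: DetectedEvent, lo: int = 0, hi: int | None = None
) -> np.ndarray:
    """Polarity-corrected, baseline-subtracted current (positive events) on
    ``samples[lo:hi]``; sliced before arithmetic to keep per-event cost local."""
    return event.sign * (trace.samples[lo:hi] - event.baseline_pa)


def _interp_crossing(h: np.ndarray, start: int, stop: int, level: float) -> float:
    """First upward crossing of ``level`` in ``h[start:stop]`` as a fractional
    sample index, with linear interpolation between the bracketing samples."""
    seg = h[start : stop + 1]
    above = np.nonzero(seg >= level)[0]
    if above.size == 0:
        raise ValueError("waveform never crosses the requested level")
    j = int(above[0])
    if j == 0:
        return float(start)
    y0, y1 = seg[j - 1], seg[j]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(start + j - 1 + frac)


def rise_time_10_90(trace: Trace, event: DetectedEvent) -> float:
    """10–90% rise time (ms): time between the first crossings of 10% and
    90% of the event amplitude on the rising phase, with linear sub-sample
    interpolation at both crossings."""
    if not event.accepted:
        raise ValueError("rise time is defined for accepted events only")
    lo, hi = event.onset_index, event.peak_index
    h = _deflection(trace, event, lo, hi + 1)  # local coords [0, hi-lo]
    amp = event.amplitude_pa
    if amp <= 0:
        return 0.0
    last = hi - lo
    t10 = _interp_crossing(h, 0, last, 0.10 * amp)
    try:
        t90 = _interp_crossing(h, 0, last, 0.90 * amp)
    except ValueError:
        # noise can leave the raw trace marginally below 90% of the measured
        # amplitude at the peak sample; fall back to the raw rising maximum
        local_max = float(h.max())
        if local_max <= 0.10 * amp:
            raise
        t90 = _interp_crossing(h, 0, last, 0.90 * local_max)
    dt_ms = 1000.0 / trace.sampling_rate_hz
    return max(0.0, (t90 - t10) * dt_ms)


def fifty_percent_rise_index(trace: Trace, event: DetectedEvent) -> float:
    """Fractional sample index of the 50%-amplitude crossing on the rising
    phase (the ensemble alignment point)."""
    lo = event.onset_index
    h = _deflection(trace, event, lo, event.peak_index + 1)
    return lo + _interp_crossing(h, 0, event.peak_index - lo, 0.5 * event.amplitude_pa)


def event_charge(
    trace: Trace,
    event: DetectedEvent,
    rms_noise_pa: float = 0.0,
    integration_rule: str = "trapezoid",
) -> tuple[float, bool]:
    """Charge transferred by one event (pC) and a truncation flag.

    Trapezoidal integral of the polarity-corrected, baseline-subtracted
    current from onset to the decay endpoint: the first post-peak return to
    within one RMS of baseline sustained for ``CHARGE_RETURN_HOLD_MS``,
    capped at ``CHARGE_WINDOW_CAP_MS`` past onset.  1 pA·s = 1 pC.  The flag
    is True when the trace ends before the decay endpoint.
    """
    if integration_rule != "trapezoid":
        raise ValueError(f"unknown integration rule: {integration_rule!r}")
    if not event.accepted:
        raise ValueError("charge is defined for accepted events only")
    fs = trace.sampling_rate_hz
    cap = event.onset_index + int(round(CHARGE_WINDOW_CAP_MS * fs / 1000.0))
    hold = max(1, int(round(CHARGE_RETURN_HOLD_MS * fs / 1000.0)))
    stop_limit = min(trace.n_samples, cap + 1)
    h_local = _deflection(trace, event, event.onset_index, stop_limit)

    seg = h_local[event.peak_index - event.onset_index :]
    below = seg <= rms_noise_pa
    # first index where the return to baseline holds for `hold` samples
    end = None
    if below.size >= hold:
        csum = np.cumsum(below, dtype=np.int64)
        runsum = csum[hold - 1 :].copy()
        runsum[1:] -= csum[:-hold]
        hits = np.nonzero(runsum == hold)[0]
        if hits.size:
            end = event.peak_index + int(hits[0])
    if end is None:
        end = stop_limit - 1
        truncated = stop_limit == trace.n_samples and cap + 1 > trace.n_samples
    else:
        truncated = False
    window = h_local[: end + 1 - event.onset_index]
    charge_pa_s = float(np.trapezoid(window, dx=1.0 / fs))
    return max(charge_pa_s, 0.0), bool(truncated)


def inter_event_intervals(catalog: EventCatalog) -> np.ndarray:
    """Intervals (ms) between consecutive accepted onsets; empty if < 2."""
    onsets = catalog.onset_times_s(accepted_only=True)
    if onsets.size < 2:
        return np.empty(0)
    return np.diff(onsets) * 1000.0


def compute_event_metrics(catalog: EventCatalog) -> pd.DataFrame:
    """Per-event metrics table for the accepted events of one catalog.

    Columns: onset_s, amplitude_pa, iei_ms (NaN for the first event),
    rise_10_90_ms, charge_pc, charge_truncated.
    """
    trace = catalog.trace
    events = catalog.accepted_events
    rows = []
    prev_onset_s: float | None = None
    for ev in events:
        onset_s = trace.t0_s + ev.onset_index / trace.sampling_rate_hz
        charge, truncated = event_charge(trace, ev, catalog.rms_noise_pa)
        rows.append(
            {
                "onset_s": onset_s,
                "amplitude_pa": ev.amplitude_pa,
                "iei_ms": (onset_s - prev_onset_s) * 1000.0 if prev_onset_s is not None else np.nan,
                "rise_10_90_ms": rise_time_10_90(trace, ev),
                "charge_pc": charge,
                "charge_truncated": truncated,
            }
        )
        prev_onset_s = onset_s
    columns = ["onset_s", "amplitude_pa", "iei_ms", "rise_10_90_ms", "charge_pc", "charge_truncated"]
    return pd.DataFrame(rows, columns=columns)


def summarize_cell(
    metrics_table: pd.DataFrame,
    duration_s: float,
    cell_id: str = "",
    cohort: str = "",
) -> CellSummary:
    """Cell-level frequency and charge transfer per second.

    ``frequency_hz = n_events / duration_s`` and the charge transfer is the
    exact product ``frequency_hz × mean charge per event``; both are 0 for an
    empty table.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = len(metrics_table)
    frequency = n / duration_s
    mean_charge = float(metrics_table["charge_pc"].mean()) if n else 0.0
    return CellSummary(
        cell_id=cell_id,
        cohort=cohort,
        n_events=n,
        duration_s=duration_s,
        frequency_hz=frequency,
        mean_charge_per_event_pc=mean_charge,
        charge_transfer_pc_per_s=frequency * mean_charge,
    )
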