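"""Seeded end-to-end evaluation harnesses.

These run the full pipeline on simulated recordings with known ground truth
and measure how well each stage recovers it: NSNA parameter recovery,
detection sensitivity/precision and false-positive rate, and the power and
type-I error of the cohort comparison.  Tests and the reproduction script
share these entry points so the measured numbers always come from the same
code paths as ordinary use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detect import apply_artifact_rules, detect_events
from .metrics import compute_event_metrics, summarize_cell
from .nsna import analyze_cell
from .simulate import (
    SimulationConfig,
    ht_sepsc_config,
    make_cohort_fixtures,
    nt_sepsc_config,
    simulate_nsna_ensemble_trace,
    simulate_trace,
)
from .stats import CellResult, ComparisonPlan, compare_cohorts

__all__ = [
    "NSNARecoveryResult",
    "DetectionOperatingPoint",
    "CohortRejectionRates",
    "nsna_recovery_benchmark",
    "detection_benchmark",
    "cohort_comparison_benchmark",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class NSNARecoveryResult:
    unitary_current_pa: np.ndarray  # per run
    n_channels: np.ndarray
    background_variance_pa2: np.ndarray
    true_unitary_pa: float
    true_n_channels: int
    true_background_pa2: float

    @property
    def i_relative_error(self) -> np.ndarray:
        return np.abs(self.unitary_current_pa - self.true_unitary_pa) / self.true_unitary_pa

    @property
    def n_relative_error(self) -> np.ndarray:
        return np.abs(self.n_channels - self.true_n_channels) / self.true_n_channels

    def recovery_rate(self, i_tol: float = 0.10, n_tol: float = 0.15) -> float:
        ok = (self.i_relative_error <= i_tol) & (self.n_relative_error <= n_tol)
        return float(np.mean(ok))


def nsna_recovery_benchmark(
    n_runs: int = 100,
    n_events: int = 250,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> NSNARecoveryResult:
    """Recover (i, N, b) through detect → isolate → align → fit on seeded
    ensembles of isolated events.

    The default generative conditions are the ones the estimates should
    reproduce: N=93 channels, i=1 pA, p_peak=0.8, τr=0.5 ms, τd=5 ms,
    baseline RMS 2 pA, 20 kHz sampling.
    """
    base = config or SimulationConfig()
    i_hat, n_hat, b_hat = [], [], []
    for s in _child_seeds(seed, n_runs):
        trace, _ = simulate_nsna_ensemble_trace(replace(base, seed=s), n_events=n_events)
        catalog = apply_artifact_rules(detect_events(trace))
        fit = analyze_cell(catalog)
        i_hat.append(fit.unitary_current_pa)
        n_hat.append(fit.n_channels)
        b_hat.append(fit.background_variance_pa2)
    return NSNARecoveryResult(
        unitary_current_pa=np.asarray(i_hat),
        n_channels=np.asarray(n_hat),
        background_variance_pa2=np.asarray(b_hat),
        true_unitary_pa=base.unitary_current_pa,
        true_n_channels=base.n_channels,
        true_background_pa2=base.baseline_rms_pa**2,
    )


@dataclass
class DetectionOperatingPoint:
    sensitivity: float
    precision: float
    false_positive_rate_per_s: float
    n_true_events: int
    n_detected: int


def detection_benchmark(
    n_event_traces: int = 50,
    n_noise_traces: int = 50,
    seed: int = 0,
    event_rate_hz: float = 0.5,
    duration_s: float = 120.0,
    match_tolerance_ms: float = 5.0,
    config: SimulationConfig | None = None,
) -> DetectionOperatingPoint:
    """Detection sensitivity/precision against simulator ground truth, plus
    the false-positive rate on event-free noise traces.

    A detection matches a true event when their onsets agree within
    ``match_tolerance_ms`` (greedy one-to-one matching in time order).
    """
    base = config or SimulationConfig(duration_s=duration_s, event_rate_hz=event_rate_hz)
    seeds = _child_seeds(seed, n_event_traces + n_noise_traces)
    tol_s = match_tolerance_ms / 1000.0

    n_true = n_det = n_matched = 0
    for s in seeds[:n_event_traces]:
        trace, train = simulate_trace(replace(base, seed=s))
        catalog = apply_artifact_rules(detect_events(trace))
        det = catalog.onset_times_s()
        n_true += train.n_events
        n_det += det.size
        n_matched += _greedy_match_count(train.onset_times_s, det, tol_s)

    fp = 0
    noise_cfg = replace(base, event_rate_hz=0.0)
    for s in seeds[n_event_traces:]:
        trace, _ = simulate_trace(replace(noise_cfg, seed=s))
        fp += len(apply_artifact_rules(detect_events(trace)).accepted_events)
    fp_rate = fp / (n_noise_traces * base.duration_s) if n_noise_traces else 0.0

    return DetectionOperatingPoint(
        sensitivity=n_matched / n_true if n_true else 1.0,
        precision=n_matched / n_det if n_det else 1.0,
        false_positive_rate_per_s=fp_rate,
        n_true_events=n_true,
        n_detected=n_det,
    )


def _greedy_match_count(true_s: np.ndarray, det_s: np.ndarray, tol_s: float) -> int:
    matched = 0
    j = 0
    for t in true_s:
        while j < det_s.size and det_s[j] < t - tol_s:
            j += 1
        if j < det_s.size and abs(det_s[j] - t) <= tol_s:
            matched += 1
            j += 1
    return matched


@dataclass
class CohortRejectionRates:
    rejection_rate: dict  # variable -> fraction of runs with p < alpha
    n_runs: int
    alpha: float


def cohort_comparison_benchmark(
    n_runs: int = 100,
    seed: int = 0,
    effect: bool = True,
    cells: tuple[int, int] = (10, 12),
    sampling_rate_hz: float = 5_000.0,
    alpha: float = 0.05,
) -> CohortRejectionRates:
    """Rejection rates of the cohort comparison over seeded replicate studies.

    With ``effect=True`` the second cohort has ~3× the event rate and 0.8×
    the unitary current of the control (the emulated study contrast, 10 vs 12
    cells of 120 s each); with ``effect=False`` both cohorts share the
    control configuration, so rejections measure type-I error.
    """
    nt = nt_sepsc_config(sampling_rate_hz=sampling_rate_hz)
    ht = ht_sepsc_config(sampling_rate_hz=sampling_rate_hz) if effect else nt
    plan = ComparisonPlan(mw_variables=("charge_transfer_pc_per_s",), alpha=alpha)
    counts: dict[str, int] = {}
    for s in _child_seeds(seed, n_runs):
        groups = []
        for cohort in make_cohort_fixtures(nt, ht, cells, seed=s):
            cells_out = []
            for trace, _ in cohort:
                catalog = apply_artifact_rules(detect_events(trace))
                table = compute_event_metrics(catalog)
                summary = summarize_cell(
                    table,
                    trace.duration_s,
                    cell_id=str(trace.metadata.get("cell_id", "")),
                    cohort=str(trace.metadata.get("cohort", "")),
                )
                cells_out.append(
                    CellResult(
                        cell_id=summary.cell_id,
                        cohort=summary.cohort,
                        metrics=table,
                        summary=summary,
                    )
                )
            groups.append(cells_out)
        for comp in compare_cohorts(groups[0], groups[1], plan):
            counts[comp.variable] = counts.get(comp.variable, 0) + (comp.p_value < alpha)
    return CohortRejectionRates(
        rejection_rate={k: v / n_runs for k, v in counts.items()},
        n_runs=n_runs,
        alpha=alpha,
    )
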