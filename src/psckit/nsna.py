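"""Ensemble non-stationary noise analysis (NSNA).

Isolated events are aligned at their 50%-rise point, the ensemble mean
current I and variance σ² are computed per time bin on the decay phase, and
the parabola

    σ² = i·I − I²/N + b

is fitted to estimate the unitary current ``i`` (pA), the number of channels
``N`` open at the peak of the mean current, and the background variance
``b`` (pA²).  The model is linear in ``(i, −1/N, b)``, so the fit is a
bounded weighted linear least squares problem with no initialisation
sensitivity; weights follow the large-sample variance of a sample variance,
Var(s²) ≈ 2σ⁴/(n−1), iterated twice from the observed values.

Alignment uses linear sub-sample interpolation.  Because channel gating in
the generative model is independent between time bins, interpolating a row
by a fractional shift f multiplies its bin-wise stochastic variance by
(1−f)² + f²; the ensemble variance is divided by the mean of this factor
over rows so that i and b remain unbiased (for real recordings with
correlated gating the factor is ≈1 and the correction is inert — it is
computed from the shifts actually applied, not assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .detect import DetectedEvent, EventCatalog
from .metrics import fifty_percent_rise_index
from .simulate import Trace

__all__ = [
    "EnsembleAlignment",
    "VarianceMeanCurve",
    "NSNAFit",
    "select_isolated_events",
    "align_events",
    "ensemble_variance_mean",
    "fit_variance_mean",
    "analyze_cell",
    "AlignmentQualityError",
]

ISOLATION_MS_DEFAULT = 200.0
MIN_EVENTS_FOR_FIT = 20
#: cells whose median |50%-crossing residual| after alignment exceeds this
#: (in samples) are excluded as imprecisely aligned
ALIGNMENT_RESIDUAL_MAX_SAMPLES = 0.5


class AlignmentQualityError(RuntimeError):
    """Raised when a cell fails the precise-alignment inclusion criterion."""


@dataclass
class EnsembleAlignment:
    """Aligned, baseline-subtracted event waveforms (rows = events).

    The 50%-rise point of every row sits at column ``alignment_column``.
    ``fractional_shifts`` records the sub-sample part of each row's shift
    (used for the interpolation variance correction) and
    ``alignment_residuals`` the re-measured 50%-crossing offset per row, in
    samples (the per-event alignment quality score).
    """

    waveforms: np.ndarray  # (n_events, n_bins), positive deflections (pA)
    alignment_column: int
    sampling_rate_hz: float
    fractional_shifts: np.ndarray
    alignment_residuals: np.ndarray

    @property
    def n_events(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_bins(self) -> int:
        return self.waveforms.shape[1]

    def ensemble_mean(self) -> np.ndarray:
        return self.waveforms.mean(axis=0)

    def interpolation_variance_factor(self) -> float:
        f = self.fractional_shifts
        return float(np.mean((1.0 - f) ** 2 + f**2)) if f.size else 1.0


@dataclass
class VarianceMeanCurve:
    """Ensemble mean current vs variance samples feeding the parabola fit."""

    mean_current_pa: np.ndarray  # I, magnitudes
    variance_pa2: np.ndarray  # σ²
    n_events: int
    weights: np.ndarray = field(default=None)  # relative fit weights (bin pooling)
    #: per point, the pooled mean of I² (equals I² for unpooled points); using
    #: it as the quadratic regressor keeps bin pooling unbiased, since the
    #: within-bin average of iI − I²/N is i·mean(I) − mean(I²)/N
    mean_sq_current_pa2: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.mean_current_pa = np.asarray(self.mean_current_pa, dtype=np.float64)
        self.variance_pa2 = np.asarray(self.variance_pa2, dtype=np.float64)
        if self.mean_current_pa.shape != self.variance_pa2.shape:
            raise ValueError("mean and variance arrays must match")
        if np.any(self.variance_pa2 < 0) or np.any(self.mean_current_pa < 0):
            raise ValueError("mean current and variance must be non-negative")
        if self.weights is None:
            self.weights = np.ones_like(self.mean_current_pa)
        if self.mean_sq_current_pa2 is None:
            self.mean_sq_current_pa2 = self.mean_current_pa**2

    @property
    def n_points(self) -> int:
        return self.mean_current_pa.size


@dataclass
class NSNAFit:
    """Fitted (i, N, b) with diagnostics.

    ``n_channels`` is ``inf`` (with ``n_unbounded=True``) when the curve has
    no measurable curvature — the σ² = iI regime.
    """

    unitary_current_pa: float
    n_channels: float
    background_variance_pa2: float
    channels_open_at_peak: float
    r_squared: float
    residual_sd_pa2: float
    covariance: np.ndarray | None
    n_points: int
    n_events: int
    n_unbounded: bool = False
    warning: str | None = None

    def predict(self, mean_current_pa: np.ndarray) -> np.ndarray:
        I = np.asarray(mean_current_pa, dtype=np.float64)
        quad = I**2 / self.n_channels if math.isfinite(self.n_channels) else 0.0
        return self.unitary_current_pa * I - quad + self.background_variance_pa2


def select_isolated_events(
    catalog: EventCatalog, isolation_ms: float = ISOLATION_MS_DEFAULT
) -> list[DetectedEvent]:
    """Accepted events whose onset is more than ``isolation_ms`` from the
    onset of every other detected event or artifact, on both sides."""
    fs = catalog.trace.sampling_rate_hz
    min_gap = isolation_ms / 1000.0 * fs
    onsets = np.array([e.onset_index for e in catalog.events], dtype=np.float64)
    keep: list[DetectedEvent] = []
    for k, ev in enumerate(catalog.events):
        if not ev.accepted:
            continue
        left_ok = k == 0 or (onsets[k] - onsets[k - 1]) > min_gap
        right_ok = k == len(onsets) - 1 or (onsets[k + 1] - onsets[k]) > min_gap
        if left_ok and right_ok:
            keep.append(ev)
    return keep


def align_events(
    trace: Trace,
    isolated_events: list[DetectedEvent],
    window_ms: float = 50.0,
    pre_fraction: float = 0.2,
) -> EnsembleAlignment:
    """Align isolated events at their 50%-rise crossing.

    Each event is baseline-subtracted (local pre-event baseline), polarity
    corrected, and resampled by linear sub-sample interpolation so its
    50%-of-amplitude rising crossing sits exactly at the alignment column
    (``pre_fraction`` of the way into a ``window_ms`` window).  Events whose
    window would extend past the trace boundary are dropped.
    """
    if len(isolated_events) < 2:
        raise ValueError("alignment requires at least 2 isolated events")
    fs = trace.sampling_rate_hz
    n_bins = int(round(window_ms * fs / 1000.0))
    k0 = int(round(pre_fraction * n_bins))
    grid = np.arange(n_bins, dtype=np.float64) - k0  # offsets from alignment point

    rows, fracs, residuals = [], [], []
    for ev in isolated_events:
        t50 = fifty_percent_rise_index(trace, ev)
        pos = t50 + grid
        if pos[0] < 0 or pos[-1] > trace.n_samples - 1:
            continue  # truncated by the trace boundary
        lo = int(math.floor(pos[0]))
        hi = int(math.ceil(pos[-1])) + 1
        h = ev.sign * (trace.samples[lo:hi] - ev.baseline_pa)
        row = np.interp(pos - lo, np.arange(hi - lo, dtype=np.float64), h)
        rows.append(row)
        fracs.append(t50 - math.floor(t50))
        # re-measure the 50% crossing on the aligned row near the alignment
        # column; the offset from k0 is the per-event alignment residual
        residuals.append(_crossing_residual(row, k0, 0.5 * ev.amplitude_pa))
    if len(rows) < 2:
        raise ValueError("fewer than 2 events survive the window boundaries")
    return EnsembleAlignment(
        waveforms=np.vstack(rows),
        alignment_column=k0,
        sampling_rate_hz=fs,
        fractional_shifts=np.asarray(fracs),
        alignment_residuals=np.asarray(residuals),
    )


def _crossing_residual(row: np.ndarray, k0: int, level: float) -> float:
    """Signed offset (samples) of the upward `level` crossing nearest k0."""
    lo = max(0, k0 - 3)
    hi = min(row.size - 1, k0 + 3)
    best = np.nan
    for j in range(lo, hi):
        y0, y1 = row[j], row[j + 1]
        if y0 <= level <= y1 and y1 > y0:
            x = j + (level - y0) / (y1 - y0)
            if np.isnan(best) or abs(x - k0) < abs(best):
                best = x - k0
    return float(best) if not np.isnan(best) else float(hi - k0)


def ensemble_variance_mean(
    alignment: EnsembleAlignment,
    n_bins: int | None = 10,
    decay_only: bool = True,
    interpolation_correction: bool = True,
) -> VarianceMeanCurve:
    """Ensemble mean current and variance per time bin, optionally pooled
    into equal-width mean-current bins on the decay phase.

    Per column: I = |mean|, σ² = unbiased variance across events, divided by
    the interpolation variance factor (see module docstring) when
    ``interpolation_correction`` is on.  With ``n_bins`` set, columns are
    pooled into equal-width bins of I; each point's weight records how many
    columns it pools.
    """
    w = alignment.waveforms
    if w.shape[0] < 2:
        raise ValueError("variance requires at least 2 aligned events")
    mean = w.mean(axis=0)
    var = w.var(axis=0, ddof=1)
    if interpolation_correction:
        var = var / alignment.interpolation_variance_factor()
    if decay_only:
        start = int(np.argmax(mean))
        mean, var = mean[start:], var[start:]
    mean = np.abs(mean)
    if n_bins is None:
        order = np.argsort(mean)
        return VarianceMeanCurve(
            mean_current_pa=mean[order],
            variance_pa2=np.maximum(var[order], 0.0),
            n_events=w.shape[0],
        )
    lo, hi = float(mean.min()), float(mean.max())
    if hi <= lo:
        raise ValueError("degenerate ensemble: mean current has no range")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(mean, edges) - 1, 0, n_bins - 1)
    I_b, I2_b, v_b, w_b = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        I_b.append(mean[sel].mean())
        I2_b.append((mean[sel] ** 2).mean())
        v_b.append(var[sel].mean())
        w_b.append(sel.sum())
    return VarianceMeanCurve(
        mean_current_pa=np.asarray(I_b),
        variance_pa2=np.maximum(np.asarray(v_b), 0.0),
        n_events=w.shape[0],
        weights=np.asarray(w_b, dtype=np.float64),
        mean_sq_current_pa2=np.asarray(I2_b),
    )


def fit_variance_mean(
    curve: VarianceMeanCurve,
    weighting: str = "inverse_variance",
    fixed_background_pa2: float | None = None,
) -> NSNAFit:
    """Fit σ² = iI − I²/N + b by bounded weighted linear least squares.

    The model is linear in (i, c, b) with c = −1/N, bounded to i ≥ 0,
    c ≤ 0, b ≥ 0.  ``weighting='inverse_variance'`` iterates weights
    w ∝ n/σ̂⁴ twice (the variance of a sample variance); ``'none'`` is plain
    least squares.  ``fixed_background_pa2`` pins b instead of fitting it.
    Requires ≥ 5 points spanning at least 50% of the peak mean current.
    A curve with no resolvable curvature yields ``n_channels = inf`` with
    ``n_unbounded=True`` rather than a spurious finite N.
    """
    I = curve.mean_current_pa
    s2 = curve.variance_pa2.copy()
    if curve.n_points < 5:
        raise ValueError("need at least 5 variance-mean points")
    I_peak = float(I.max())
    if I_peak <= 0:
        raise ValueError("degenerate curve: all mean currents are ~0")
    if (I.max() - I.min()) < 0.5 * I_peak:
        raise ValueError("mean-current range spans less than 50% of the peak")
    if weighting not in ("inverse_variance", "none"):
        raise ValueError(f"unknown weighting: {weighting!r}")

    I2 = curve.mean_sq_current_pa2
    fit_b = fixed_background_pa2 is None
    if not fit_b:
        s2 = s2 - fixed_background_pa2
        X = np.column_stack([I, I2])
        lower, upper = [0.0, -np.inf], [np.inf, 0.0]
    else:
        X = np.column_stack([I, I2, np.ones_like(I)])
        lower, upper = [0.0, -np.inf, 0.0], [np.inf, 0.0, np.inf]

    w = curve.weights.astype(np.float64).copy()
    n_iter = 3 if weighting == "inverse_variance" else 1
    coef = None
    for it in range(n_iter):
        sw = np.sqrt(w / w.mean())
        res = lsq_linear(X * sw[:, None], s2 * sw, bounds=(lower, upper), method="bvls")
        coef = res.x
        if weighting == "inverse_variance" and it < n_iter - 1:
            pred = X @ coef
            pred = np.maximum(pred + (0.0 if fit_b else fixed_background_pa2), 1e-12)
            w = curve.weights / pred**2

    i_hat = float(coef[0])
    c_hat = float(coef[1])
    b_hat = float(coef[2]) if fit_b else float(fixed_background_pa2)
    warning = None
    if i_hat <= 0:
        raise ValueError("degenerate fit: unitary current estimate is not positive")

    # curvature resolvability: |c| must exceed its own scale on this design
    curv_tol = 1e-12 / max(I_peak, 1.0)
    if c_hat > -curv_tol:
        n_hat = math.inf
        n_unbounded = True
        warning = "no measurable curvature: N is unbounded (sigma^2 ~ i*I regime)"
    else:
        n_hat = -1.0 / c_hat
        n_unbounded = False

    pred_full = i_hat * I + c_hat * I2 + b_hat
    obs = curve.variance_pa2
    resid = obs - pred_full
    ss_res = float(np.sum(curve.weights * resid**2))
    mean_obs = float(np.average(obs, weights=curve.weights))
    ss_tot = float(np.sum(curve.weights * (obs - mean_obs) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(curve.n_points - X.shape[1], 1)
    resid_sd = math.sqrt(ss_res / float(curve.weights.sum()) * curve.n_points / dof)

    covariance = None
    try:
        Xw = X * np.sqrt(w / w.mean())[:, None]
        s2_resid = ss_res / dof / float(curve.weights.mean())
        covariance = s2_resid * np.linalg.inv(Xw.T @ Xw)
    except np.linalg.LinAlgError:
        covariance = None

    if np.any(np.diff(obs[np.argsort(I)]) > 0) and c_hat >= 0 and warning is None:
        warning = "variance increases superlinearly with mean current"

    return NSNAFit(
        unitary_current_pa=i_hat,
        n_channels=n_hat,
        background_variance_pa2=max(b_hat, 0.0),
        channels_open_at_peak=I_peak / i_hat,
        r_squared=r2,
        residual_sd_pa2=resid_sd,
        covariance=covariance,
        n_points=curve.n_points,
        n_events=curve.n_events,
        n_unbounded=n_unbounded,
        warning=warning,
    )


def analyze_cell(
    catalog: EventCatalog,
    isolation_ms: float = ISOLATION_MS_DEFAULT,
    window_ms: float = 50.0,
    min_events: int = MIN_EVENTS_FOR_FIT,
    n_bins: int | None = 10,
    weighting: str = "inverse_variance",
    fixed_background_pa2: float | None = None,
) -> NSNAFit:
    """Full per-cell NSNA: isolate, align, quality-check, build the
    variance–mean curve, fit the parabola.

    Raises ``ValueError`` if fewer than ``min_events`` isolated events exist
    and ``AlignmentQualityError`` if the cell fails the precise-alignment
    criterion (median |50%-crossing residual| ≥ 0.5 sample).
    """
    isolated = select_isolated_events(catalog, isolation_ms)
    if len(isolated) < min_events:
        raise ValueError(
            f"only {len(isolated)} isolated events; need >= {min_events} for NSNA"
        )
    alignment = align_events(catalog.trace, isolated, window_ms=window_ms)
    med_resid = float(np.median(np.abs(alignment.alignment_residuals)))
    if med_resid >= ALIGNMENT_RESIDUAL_MAX_SAMPLES:
        raise AlignmentQualityError(
            f"median 50%-crossing residual {med_resid:.2f} samples >= "
            f"{ALIGNMENT_RESIDUAL_MAX_SAMPLES}; cell excluded from NSNA"
        )
    curve = ensemble_variance_mean(alignment, n_bins=n_bins)
    return fit_variance_mean(curve, weighting=weighting, fixed_background_pa2=fixed_background_pa2)
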