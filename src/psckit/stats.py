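"""Cohort statistics: pooled cumulative distributions compared with the
two-sample Kolmogorov–Smirnov test, per-cell quantities compared with the
Mann–Whitney U test, and median / IQR / 5–95% summaries.

Event-level variables (amplitude, inter-event interval, rise time) are
pooled across the cells of a cohort before the KS test; cell-level variables
(charge transfer per second, NSNA channel count and unitary current) are
compared with one value per cell.  All tests are two-sided; quantiles use
linear interpolation between order statistics (type 7).

The Mann–Whitney p-value is exact — enumerated over all group assignments of
the midranks — whenever the combined sample is small (n₁+n₂ ≤ 12, ties
allowed); larger samples use the normal approximation with tie correction
and continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CellSummary
from .nsna import NSNAFit

__all__ = [
    "PooledDistribution",
    "CohortComparison",
    "ComparisonPlan",
    "CellResult",
    "ecdf",
    "ks_two_sample",
    "mann_whitney",
    "summarize",
    "compare_cohorts",
]

EXACT_MW_MAX_N = 12
EXACT_KS_MAX_PRODUCT = 10_000


@dataclass
class PooledDistribution:
    """Event-level values pooled across the cells of one cohort."""

    cohort: str
    variable: str
    values: np.ndarray
    cutoff_pa: float | None = None
    n_before_cutoff: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pooled values must be finite")
        if self.cutoff_pa is not None and self.cutoff_pa <= 0:
            raise ValueError("cutoff must be strictly positive")


@dataclass
class SummaryFiveNumber:
    median: float
    q1: float
    q3: float
    p5: float
    p95: float

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "p5": self.p5,
            "p95": self.p95,
        }


@dataclass
class CohortComparison:
    """One variable's between-cohort test with group summaries."""

    variable: str
    test: str  # "ks" or "mw"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    summary_a: SummaryFiveNumber
    summary_b: SummaryFiveNumber

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of range")
        if self.test == "ks" and not 0.0 <= self.statistic <= 1.0:
            raise ValueError("KS statistic out of range")
        if self.test == "mw" and not 0.0 <= self.statistic <= self.n_a * self.n_b:
            raise ValueError("U statistic out of range")


@dataclass(frozen=True)
class ComparisonPlan:
    """Which variables get which test, plus the optional amplitude cut-off
    (pA) applied to the pooled amplitude distribution before testing."""

    ks_variables: tuple[str, ...] = ("amplitude_pa", "iei_ms", "rise_10_90_ms")
    mw_variables: tuple[str, ...] = (
        "charge_transfer_pc_per_s",
        "n_channels",
        "unitary_current_pa",
    )
    amplitude_cutoff_pa: float | None = None
    alpha: float = 0.05


@dataclass
class CellResult:
    """Everything the cohort comparison needs from one cell."""

    cell_id: str
    cohort: str
    metrics: pd.DataFrame  # per-event table from metrics.compute_event_metrics
    summary: CellSummary
    nsna: NSNAFit | None = None


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities k/n at the
    k-th order statistic (right-continuous convention)."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise ValueError("ecdf of empty sample")
    return v, np.arange(1, v.size + 1) / v.size


def _ks_integer_statistic(a: np.ndarray, b: np.ndarray) -> int:
    """max |i·m − j·n| over the combined order, i.e. D·n·m as an exact integer."""
    n, m = a.size, b.size
    sa, sb = np.sort(a), np.sort(b)
    allv = np.concatenate([sa, sb])
    i = np.searchsorted(sa, allv, side="right")
    j = np.searchsorted(sb, allv, side="right")
    return int(np.max(np.abs(i * m - j * n)))


def _ks_exact_p(h: int, n: int, m: int) -> float:
    """P(D ≥ h/(n·m)) under the permutation null for a tie-free sample.

    Counts monotone lattice paths from (0,0) to (n,m) that keep
    |i·m − j·n| < h at every point (integer arithmetic, so the result equals
    exhaustive enumeration over all C(n+m, n) label assignments exactly).
    """
    good = [[0] * (m + 1) for _ in range(n + 1)]
    good[0][0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * m - j * n) >= h:
                continue
            good[i][j] = (good[i - 1][j] if i else 0) + (good[i][j - 1] if j else 0)
    total = math.comb(n + m, n)
    return float((total - good[n][m]) / total)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov–Smirnov test.

    D = sup|ECDF_a − ECDF_b|.  The p-value is exact (integer lattice-path
    recursion, identical to exhaustive permutation enumeration) when
    n_a·n_b ≤ 10⁴ and the combined sample is tie-free, asymptotic otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    n, m = a.size, b.size
    h = _ks_integer_statistic(a, b)
    d = h / (n * m)
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    if n * m <= EXACT_KS_MAX_PRODUCT and tie_free:
        return d, _ks_exact_p(h, n, m)
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _mw_u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U test with midrank tie handling.

    Returns (U, p) where U counts pairs won by sample ``a``.  Exact p by
    enumeration over all C(n₁+n₂, n₁) group assignments when n₁+n₂ ≤ 12
    (valid under ties); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("Mann-Whitney test requires non-empty samples")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u1 = _mw_u_from_ranks(ranks[:n1], n1)

    if n1 + n2 <= EXACT_MW_MAX_N:
        us = np.array(
            [
                _mw_u_from_ranks(ranks[list(idx)], n1)
                for idx in combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        if alternative == "two-sided":
            center = n1 * n2 / 2.0
            p = float(np.mean(np.abs(us - center) >= abs(u1 - center) - eps))
        elif alternative == "greater":
            p = float(np.mean(us >= u1 - eps))
        else:
            p = float(np.mean(us <= u1 + eps))
        return u1, p

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return u1, 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sigma
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
        p = sps.norm.sf(z)
    else:
        z = (u1 - mu + 0.5) / sigma
        p = sps.norm.cdf(z)
    return u1, float(min(p, 1.0))


def summarize(values) -> SummaryFiveNumber:
    """Median, quartiles, and 5–95% bounds (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("summary of empty sample")
    p5, q1, med, q3, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    return SummaryFiveNumber(median=float(med), q1=float(q1), q3=float(q3), p5=float(p5), p95=float(p95))


def _pool_event_values(
    cells: list[CellResult], variable: str, cutoff_pa: float | None
) -> PooledDistribution:
    chunks = []
    n_before = 0
    for cell in cells:
        col = cell.metrics[variable].to_numpy(dtype=np.float64)
        col = col[np.isfinite(col)]  # first event of a cell has no IEI
        n_before += col.size
        if cutoff_pa is not None and variable == "amplitude_pa":
            col = col[col <= cutoff_pa]
        chunks.append(col)
    values = np.concatenate(chunks) if chunks else np.empty(0)
    cohort = cells[0].cohort if cells else ""
    return PooledDistribution(
        cohort=cohort,
        variable=variable,
        values=values,
        cutoff_pa=cutoff_pa if variable == "amplitude_pa" else None,
        n_before_cutoff=n_before,
    )


def _cell_values(cells: list[CellResult], variable: str) -> np.ndarray:
    out = []
    for cell in cells:
        if hasattr(cell.summary, variable):
            out.append(getattr(cell.summary, variable))
        elif cell.nsna is not None and hasattr(cell.nsna, variable):
            val = getattr(cell.nsna, variable)
            if math.isfinite(val):
                out.append(val)
        # cells without an NSNA fit contribute nothing to NSNA variables
    return np.asarray(out, dtype=np.float64)


def compare_cohorts(
    group_a_cells: list[CellResult],
    group_b_cells: list[CellResult],
    plan: ComparisonPlan | None = None,
) -> list[CohortComparison]:
    """Run the full between-cohort plan.

    KS tests on event-level distributions pooled within each cohort; MW tests
    on per-cell quantities.  Raises ``ValueError`` naming the variable when a
    group contributes no data to a planned test.
    """
    plan = plan or ComparisonPlan()
    if not group_a_cells or not group_b_cells:
        raise ValueError("both cohorts need at least one cell")
    results: list[CohortComparison] = []
    for variable in plan.ks_variables:
        pa = _pool_event_values(group_a_cells, variable, plan.amplitude_cutoff_pa)
        pb = _pool_event_values(group_b_cells, variable, plan.amplitude_cutoff_pa)
        if pa.values.size == 0 or pb.values.size == 0:
            raise ValueError(f"no pooled events for KS variable {variable!r}")
        d, p = ks_two_sample(pa.values, pb.values)
        results.append(
            CohortComparison(
                variable=variable,
                test="ks",
                statistic=d,
                p_value=p,
                n_a=pa.values.size,
                n_b=pb.values.size,
                summary_a=summarize(pa.values),
                summary_b=summarize(pb.values),
            )
        )
    for variable in plan.mw_variables:
        va = _cell_values(group_a_cells, variable)
        vb = _cell_values(group_b_cells, variable)
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"no per-cell values for MW variable {variable!r}")
        u, p = mann_whitney(va, vb)
        results.append(
            CohortComparison(
                variable=variable,
                test="mw",
                statistic=u,
                p_value=p,
                n_a=va.size,
                n_b=vb.size,
                summary_a=summarize(va),
                summary_b=summarize(vb),
            )
        )
    return results
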