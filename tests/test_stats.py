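"""Cohort statistics against exhaustive enumeration oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from psckit.metrics import CellSummary
from psckit.stats import (
    CellResult,
    ComparisonPlan,
    compare_cohorts,
    ecdf,
    ks_two_sample,
    mann_whitney,
    summarize,
)


# --- independent brute-force oracles -----------------------------------------


def ks_d(a, b):
    a, b = np.sort(a), np.sort(b)
    allv = np.concatenate([a, b])
    fa = np.searchsorted(a, allv, side="right") / a.size
    fb = np.searchsorted(b, allv, side="right") / b.size
    return np.max(np.abs(fa - fb))


def ks_exact_p_bruteforce(a, b):
    """P(D ≥ d_obs) over all C(n+m, n) equally likely label assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    d_obs = ks_d(np.asarray(a), np.asarray(b))
    total = hits = 0
    idx_all = set(range(len(pooled)))
    for idx in combinations(range(len(pooled)), n):
        aa = pooled[list(idx)]
        bb = pooled[list(idx_all - set(idx))]
        total += 1
        if ks_d(aa, bb) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def mw_u(ranks_a, n_a):
    return ranks_a.sum() - n_a * (n_a + 1) / 2


def mw_exact_p_bruteforce(a, b):
    """Two-sided exact p over all group assignments of the midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = mw_u(ranks[:n1], n1)
    center = n1 * len(b) / 2
    total = hits = 0
    for idx in combinations(range(len(pooled)), n1):
        u = mw_u(ranks[list(idx)], n1)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return hits / total


# --- tests --------------------------------------------------------------------


class TestEcdf:
    def test_basic_steps(self):
        x, p = ecdf([3, 1, 2])
        assert np.array_equal(x, [1, 2, 3])
        assert np.allclose(p, [1 / 3, 2 / 3, 1.0])

    def test_single_value(self):
        x, p = ecdf([5.0])
        assert np.array_equal(x, [5.0]) and np.array_equal(p, [1.0])

    def test_ties(self):
        x, p = ecdf([1, 1, 2])
        # cumulative probability reaches 2/3 at the tied value
        assert p[np.searchsorted(x, 1, side="right") - 1] == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_exact_p_matches_enumeration_4v5(self, rng):
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        _, p = ks_two_sample(a, b)
        assert p == pytest.approx(ks_exact_p_bruteforce(a, b), abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 4), (5, 4)])
    def test_exact_p_all_small_shapes(self, na, nb, rng):
        a = rng.normal(size=na)
        b = rng.normal(size=nb) + 0.5
        _, p = ks_two_sample(a, b)
        assert p == pytest.approx(ks_exact_p_bruteforce(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_with_ties(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # midranks
        assert p == 1.0

    def test_exact_p_is_multiple_of_one_twentieth(self, rng):
        # 3 vs 3 tie-free: 20 equally likely rank configurations
        a, b = rng.normal(size=3), rng.normal(size=3)
        _, p = mann_whitney(a, b)
        assert (p * 20) == pytest.approx(round(p * 20), abs=1e-9)

    @pytest.mark.parametrize("na,nb,tie", [(3, 4, False), (4, 4, True), (5, 3, True), (2, 6, False)])
    def test_exact_p_matches_enumeration(self, na, nb, tie, rng):
        a = rng.integers(0, 6 if tie else 1000, size=na).astype(float)
        b = rng.integers(0, 6 if tie else 1000, size=nb).astype(float)
        u, p = mann_whitney(a, b)
        assert p == pytest.approx(mw_exact_p_bruteforce(a, b), abs=1e-12)

    def test_large_sample_path_matches_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=25) + 0.4
        u, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_u_complement_identity_on_random_inputs(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 15, size=2)
            a = rng.normal(size=n1)
            b = np.round(rng.normal(size=n2), 1)
            u1, _ = mann_whitney(a, b)
            u2, _ = mann_whitney(b, a)
            assert u1 + u2 == pytest.approx(n1 * n2, abs=1e-9)


class TestSummaries:
    def test_linear_interpolation_quantiles(self):
        s = summarize(np.arange(1, 101, dtype=float))
        assert s.median == pytest.approx(50.5)
        assert (s.q1, s.q3) == (pytest.approx(25.75), pytest.approx(75.25))
        assert (s.p5, s.p95) == (pytest.approx(5.95), pytest.approx(95.05))

    def test_constant_vector(self):
        s = summarize([7.0] * 10)
        assert s.median == s.q1 == s.q3 == s.p5 == s.p95 == 7.0

    def test_two_values(self):
        assert summarize([2.0, 4.0]).median == pytest.approx(3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_quantile_monotonicity(self, values):
        s = summarize(values)
        assert s.p5 <= s.q1 <= s.median <= s.q3 <= s.p95


def _cell(cell_id, cohort, amplitudes, ieis=None, charge=1.0):
    n = len(amplitudes)
    table = pd.DataFrame(
        {
            "amplitude_pa": amplitudes,
            "iei_ms": ([np.nan] + list(ieis or [100.0] * (n - 1)))[:n],
            "rise_10_90_ms": [1.0] * n,
            "charge_pc": [charge] * n,
        }
    )
    summary = CellSummary(
        cell_id=cell_id, cohort=cohort, n_events=n, duration_s=120.0,
        frequency_hz=n / 120.0, mean_charge_per_event_pc=charge,
        charge_transfer_pc_per_s=n / 120.0 * charge,
    )
    return CellResult(cell_id=cell_id, cohort=cohort, metrics=table, summary=summary)


class TestCompareCohorts:
    def test_plan_produces_one_comparison_per_variable(self):
        a = [_cell("a1", "NT", [10, 20, 30]), _cell("a2", "NT", [12, 22])]
        b = [_cell("b1", "HT", [11, 19, 31]), _cell("b2", "HT", [13, 21])]
        plan = ComparisonPlan(mw_variables=("charge_transfer_pc_per_s",))
        out = compare_cohorts(a, b, plan)
        assert [(c.variable, c.test) for c in out] == [
            ("amplitude_pa", "ks"),
            ("iei_ms", "ks"),
            ("rise_10_90_ms", "ks"),
            ("charge_transfer_pc_per_s", "mw"),
        ]
        assert all(0 <= c.p_value <= 1 for c in out)

    def test_amplitude_cutoff_filters_pool_but_not_iei(self):
        a = [_cell("a1", "NT", [10, 150, 30], ieis=[50.0, 60.0])]
        b = [_cell("b1", "HT", [11, 19, 31])]
        plan = ComparisonPlan(
            ks_variables=("amplitude_pa", "iei_ms"),
            mw_variables=("charge_transfer_pc_per_s",),
            amplitude_cutoff_pa=100.0,
        )
        out = compare_cohorts(a, b, plan)
        amp = next(c for c in out if c.variable == "amplitude_pa")
        iei = next(c for c in out if c.variable == "iei_ms")
        assert amp.n_a == 2  # 150 pA event removed
        assert iei.n_a == 2  # intervals untouched
        assert amp.summary_a.p95 <= 100.0

    def test_empty_group_raises_naming_variable(self):
        a = [_cell("a1", "NT", [10, 20])]
        b = [_cell("b1", "HT", [])]
        with pytest.raises(ValueError, match="amplitude_pa"):
            compare_cohorts(a, b, ComparisonPlan(mw_variables=()))

    def test_missing_cohort_rejected(self):
        with pytest.raises(ValueError):
            compare_cohorts([], [_cell("b1", "HT", [1.0])], ComparisonPlan())
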