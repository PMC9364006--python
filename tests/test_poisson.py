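"""Poisson-abundance design formulas: published values, minimality, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from detectdesign import (
    INFINITE,
    n_finite,
    n_finite_delta,
    n_infinite,
    n_infinite_delta,
    nondetect_prob,
    overestimation_bound,
)
from conftest import BETAS, DELTAS, scan_min_n_poisson


@pytest.mark.parametrize(
    "beta, lam, expected",
    [(0.05, 0.001, 2996), (0.05, 0.01, 300)],
)
def test_unbounded_area_published_values(beta, lam, expected):
    n = n_infinite(beta, lam)
    assert n == expected
    # minimality against the defining inequality
    assert math.exp(-lam * n) <= beta < math.exp(-lam * (n - 1))


def test_unbounded_area_exact_boundary():
    # beta = exp(-lam) makes -log(beta)/lam = 1 exactly, for any lam
    for lam in [0.001, 0.3, 2.0]:
        assert n_infinite(math.exp(-lam), lam) == 1


@pytest.mark.parametrize(
    "beta, lam, N, expected",
    [
        (0.05, 0.001, 3000, 2330),
        (0.05, 0.01, 300, 233),
        (0.05, 0.001, 5000, 2876),
    ],
)
def test_finite_area_published_values(beta, lam, N, expected):
    assert n_finite(beta, lam, N) == expected


@pytest.mark.parametrize(
    "beta, lam, N, delta, expected",
    [
        (0.05, 0.001, 3500, 0.1, 2825),
        (0.05, 0.001, 6000, 0.5, 5900),
        (0.05, 0.001, 3500, 0.0, 2543),
    ],
)
def test_finite_area_with_detection_error_published_values(beta, lam, N, delta, expected):
    result = n_finite_delta(beta, lam, N, delta)
    assert result.n == expected
    assert result.feasible
    assert result.achieved_prob <= beta


@pytest.mark.parametrize(
    "beta, lam, delta, expected",
    [
        (0.05, 0.001, 0.1, 3329),
        (0.05, 0.001, 0.5, 5992),
        (0.05, 0.001, 0.0, 2996),
    ],
)
def test_unbounded_area_with_detection_error_published_values(beta, lam, delta, expected):
    assert n_infinite_delta(beta, lam, delta) == expected


def test_minimality_on_grid(grid):
    """Every closed-form n equals the brute-force linear-scan minimum."""
    for beta, lam, N, delta in grid:
        oracle = scan_min_n_poisson(beta, lam, N, delta)
        assert n_finite_delta(beta, lam, N, delta).n == oracle, (beta, lam, N, delta)
    for beta, lam, _, delta in grid:
        assert n_infinite_delta(beta, lam, delta) == scan_min_n_poisson(
            beta, lam, np.inf, delta
        )


def test_finite_area_bound_and_delta0_reductions(grid):
    for beta, lam, N, delta in grid:
        n0 = n_finite(beta, lam, N)
        assert 1 <= n0 <= N  # guaranteed without detection error
        res = n_finite_delta(beta, lam, N, 0.0)
        assert res.n == n0 and res.feasible
    for beta in BETAS:
        for lam in [0.001, 0.1]:
            assert n_infinite_delta(beta, lam, 0.0) == n_infinite(beta, lam)


def test_monotonicity_on_grid():
    lam, N = 0.01, 300
    n_by_beta = [n_finite_delta(b, lam, N, 0.1).n for b in [0.01, 0.05, 0.2]]
    assert n_by_beta == sorted(n_by_beta, reverse=True)
    n_by_lam = [n_finite_delta(0.05, l, N, 0.1).n for l in [0.001, 0.01, 0.1]]
    assert n_by_lam == sorted(n_by_lam, reverse=True)
    n_by_N = [n_finite_delta(0.05, lam, N_, 0.1).n for N_ in [100, 300, 1000, 10_000]]
    assert n_by_N == sorted(n_by_N)  # larger area -> larger n, up to the unbounded limit
    n_by_delta = [n_finite_delta(0.05, lam, N, d).n for d in DELTAS]
    assert n_by_delta == sorted(n_by_delta)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    beta=st.floats(0.001, 0.5),
    lam=st.floats(1e-4, 2.0),
    N=st.integers(1, 5000),
    delta=st.floats(0.0, 0.9),
)
def test_minimality_property(beta, lam, N, delta):
    assert n_finite_delta(beta, lam, N, delta).n == scan_min_n_poisson(beta, lam, N, delta)


def test_infeasible_design_reported_uncapped():
    # beta=0.05, lam=0.01, N=300, delta=0.5: the requirement exceeds the area
    res = n_finite_delta(0.05, 0.01, 300, 0.5)
    assert res.n > 300
    assert not res.feasible
    # achieved_prob reports the best possible: sampling the whole area
    assert res.achieved_prob == pytest.approx(nondetect_prob(0.01, 300, 300, 0.5))
    assert res.achieved_prob > 0.05


def test_nondetect_prob_whole_area_perfect_detection_is_zero():
    assert nondetect_prob(0.01, 300, 300, 0.0) == 0.0


def test_nondetect_prob_at_recommended_n():
    p = nondetect_prob(0.001, 3000, 2330, 0.0)
    assert p <= 0.05
    assert abs(p - 0.05) < 1e-3


def test_nondetect_prob_against_pmf_summation():
    """Cross-check the closed form against term-by-term Poisson summation.

    P(S_n = 0 and S_rest > 0) / P(Y > 0), with S_n ~ Pois(lam*n),
    S_rest ~ Pois(lam*(N-n)), Y ~ Pois(lam*N), each tail summed over the pmf.
    """
    lam, N, n = 0.01, 300, 233
    j = np.arange(1, 200)  # tails beyond 200 are < 1e-300 here
    p_rest_pos = stats.poisson.pmf(j, lam * (N - n)).sum()
    p_y_pos = stats.poisson.pmf(j, lam * N).sum()
    oracle = stats.poisson.pmf(0, lam * n) * p_rest_pos / p_y_pos
    assert nondetect_prob(lam, N, n) == pytest.approx(oracle, rel=1e-10)


def test_nondetect_prob_monotone_in_delta():
    for delta_lo, delta_hi in [(0.0, 0.1), (0.1, 0.5), (0.5, 0.9)]:
        assert nondetect_prob(0.01, 300, 100, delta_lo) < nondetect_prob(
            0.01, 300, 100, delta_hi
        )


def test_nondetect_prob_infinite_area():
    assert nondetect_prob(0.01, INFINITE, 100, 0.0) == pytest.approx(math.exp(-1.0))


def test_overestimation_bound_published_value_attained():
    assert overestimation_bound(0.05, 0.001, 3000) == 666
    assert n_infinite(0.05, 0.001) - n_finite(0.05, 0.001, 3000) == 666


def test_overestimation_bound_on_grid(grid):
    for beta, lam, N, delta in grid:
        diff = n_infinite_delta(beta, lam, delta) - n_finite_delta(beta, lam, N, delta).n
        assert 0 <= diff <= overestimation_bound(beta, lam, N, delta), (beta, lam, N, delta)


def test_overestimation_difference_stabilizes_at_bound_minus_one():
    """For large enough N the overestimation equals the bound minus one."""
    beta, lam = 0.05, 0.001
    n_inf = n_infinite(beta, lam)
    tail = []
    for N in range(8000, 15001, 250):
        diff = n_inf - n_finite(beta, lam, N)
        tail.append(diff == overestimation_bound(beta, lam, N) - 1)
    assert all(tail[-8:])  # stabilized


def test_finite_converges_to_unbounded():
    for beta, lam in [(0.05, 0.001), (0.05, 0.01), (0.2, 0.1)]:
        n_inf = n_infinite(beta, lam)
        big_N = int(30 / lam)
        assert n_finite(beta, lam, big_N) == n_inf


@pytest.mark.parametrize(
    "call",
    [
        lambda: n_infinite(0.0, 0.01),
        lambda: n_infinite(1.0, 0.01),
        lambda: n_infinite(0.05, 0.0),
        lambda: n_finite(0.05, 0.01, 0),
        lambda: n_finite_delta(0.05, 0.01, 300, 1.0),
        lambda: n_finite_delta(0.05, 0.01, 300, -0.1),
        lambda: nondetect_prob(0.01, 300, 301),
        lambda: nondetect_prob(0.01, 300, 0),
    ],
)
def test_domain_errors(call):
    with pytest.raises(ValueError):
        call()
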