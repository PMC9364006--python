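"""Sample-size formulas under Poisson per-quadrat abundance (model A).

The area comprises N unit-area quadrats whose counts X_1, ..., X_N are i.i.d.
Poisson(lam); Y = sum X_i ~ Poisson(lam * N) is the total population. The
design question: the smallest n such that

    P(no individual detected in n sampled quadrats | Y > 0) <= beta,

optionally with each individual independently missed with probability delta
(binomial thinning, so the detected count in the n quadrats is
Poisson(lam * n * (1 - delta))). All logarithms are natural.
"""

from __future__ import annotations

import math

from ._types import (
    INFINITE,
    AreaSize,
    SampleSizeResult,
    is_infinite,
    validate_area_size,
    validate_beta,
    validate_delta,
    validate_lam,
)

__all__ = [
    "n_infinite",
    "n_finite",
    "n_infinite_delta",
    "n_finite_delta",
    "nondetect_prob",
    "overestimation_bound",
]

# FP guard around the ceiling: a real-valued bound landing within this of an
# integer is re-adjudicated against the defining inequality.
_CEIL_EPS = 1e-9


def _verified_ceil(x: float, satisfies) -> int:
    """Smallest integer n >= 1 with satisfies(n), seeded by ceil(x).

    The closed forms are exact in real arithmetic; double precision can put x
    within rounding noise of an integer and flip the ceiling. The candidate
    (and its neighbours) is therefore checked against the defining inequality
    itself, which is monotone in n.
    """
    n = max(1, math.ceil(x - _CEIL_EPS))
    while not satisfies(n):
        n += 1
    while n > 1 and satisfies(n - 1):
        n -= 1
    return n


def nondetect_prob(lam: float, N: AreaSize, n: int, delta: float = 0.0) -> float:
    """Conditional probability of detecting nothing in n of N quadrats.

    Returns P(zero individuals detected in the n sampled quadrats | Y > 0)
    = (exp(-lam*n*(1-delta)) - exp(-lam*N)) / (1 - exp(-lam*N)).

    For an infinite area the conditioning is vacuous and the value
    degenerates to exp(-lam*n*(1-delta)).
    """
    lam = validate_lam(lam)
    N = validate_area_size(N)
    delta = validate_delta(delta)
    if not (isinstance(n, int) or (isinstance(n, float) and float(n).is_integer())):
        raise ValueError(f"n must be an integer, got {n!r}")
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not is_infinite(N) and n > N:
        raise ValueError(f"n={n} exceeds the number of quadrats N={N}")
    top = math.exp(-lam * n * (1.0 - delta))
    if is_infinite(N):
        return top
    pN = math.exp(-lam * N)
    return max(0.0, (top - pN) / (1.0 - pN))


def n_infinite(beta: float, lam: float) -> int:
    """Minimum n for an unbounded area with perfect detection.

    n = ceil(-log(beta) / lam): the classical answer, obtained by requiring
    exp(-lam * n) <= beta.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    return _verified_ceil(
        -math.log(beta) / lam,
        lambda m: math.exp(-lam * m) <= beta,
    )


def n_finite(beta: float, lam: float, N: int) -> int:
    """Minimum n for a known finite area of N quadrats, perfect detection.

    n = ceil(-(1/lam) * log(beta + (1 - beta) * exp(-lam * N))). Always
    satisfies 1 <= n <= N, and never exceeds the infinite-area answer.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    N = validate_area_size(N)
    if is_infinite(N):
        return n_infinite(beta, lam)
    thresh = beta + (1.0 - beta) * math.exp(-lam * N)
    return _verified_ceil(
        -math.log(thresh) / lam,
        lambda m: math.exp(-lam * m) <= thresh,
    )


def n_infinite_delta(beta: float, lam: float, delta: float) -> int:
    """Minimum n for an unbounded area when each individual is missed w.p. delta.

    n = ceil(-log(beta) / (lam * (1 - delta))); reduces to `n_infinite` at
    delta = 0.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    delta = validate_delta(delta)
    rate = lam * (1.0 - delta)
    return _verified_ceil(
        -math.log(beta) / rate,
        lambda m: math.exp(-rate * m) <= beta,
    )


def n_finite_delta(beta: float, lam: float, N: int, delta: float) -> SampleSizeResult:
    """Minimum n for a finite area with imperfect detectability.

    n = ceil(-(1/(lam*(1-delta))) * log(beta + (1-beta) * exp(-lam*N))).

    The guarantee n <= N holds only for delta = 0; with detection error the
    requirement can exceed the area itself, in which case the uncapped n is
    returned with ``feasible=False`` and ``achieved_prob`` evaluated at
    n = N (the best any design can do). The n is never silently capped.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    N = validate_area_size(N)
    delta = validate_delta(delta)
    if is_infinite(N):
        n = n_infinite_delta(beta, lam, delta)
        return SampleSizeResult(
            n=n,
            formula_id="4.4" if delta > 0 else "1.1",
            feasible=True,
            achieved_prob=nondetect_prob(lam, INFINITE, n, delta),
        )
    thresh = beta + (1.0 - beta) * math.exp(-lam * N)
    rate = lam * (1.0 - delta)
    n = _verified_ceil(
        -math.log(thresh) / rate,
        lambda m: math.exp(-rate * m) <= thresh,
    )
    feasible = n <= N
    return SampleSizeResult(
        n=n,
        formula_id="4.1" if delta > 0 else "2.1",
        feasible=feasible,
        achieved_prob=nondetect_prob(lam, N, n if feasible else N, delta),
    )


def overestimation_bound(beta: float, lam: float, N: int, delta: float = 0.0) -> int:
    """Upper bound on the excess of the infinite-area n over the finite-area n.

    Returns ceil((1/(lam*(1-delta))) * log(1 + ((1-beta)/beta) * exp(-lam*N))).
    The difference n_infinite_delta - n_finite_delta lies in [0, bound] for
    every (beta, lam, N, delta), and equals bound - 1 for N large enough.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    N = validate_area_size(N)
    delta = validate_delta(delta)
    if is_infinite(N):
        return 0
    x = math.log1p((1.0 - beta) / beta * math.exp(-lam * N)) / (lam * (1.0 - delta))
    return math.ceil(x - _CEIL_EPS)
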