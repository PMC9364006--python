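"""Sample-size formulas under Negative Binomial abundance (model B).

Overdispersed and/or zero-inflated per-quadrat counts are modelled as i.i.d.
NB(r, p). We work in the mean parameterization (r, lam) with
lam = r*p/(1-p), i.e. p = lam/(r+lam), which is the convenient one for
moment estimation. Key facts used throughout:

* P(X = 0) = (1 + lam/r)^(-r) > exp(-lam): excess zero mass relative to a
  Poisson of the same mean, shrinking to exp(-lam) as r -> infinity.
* Sums are closed: sum of n i.i.d. NB(r, p) is NB(r*n, p), so the sampled
  total and the unsampled remainder are NB(r*n, p) and NB(r*(N-n), p).
* Variance/mean = 1 + lam/r, the dispersion index (> 1; 1 for the Poisson).
* As r -> infinity, NB(r, lam/(r+lam)) -> Poisson(lam), and every formula
  below converges to its Poisson counterpart.

Powers (1 + lam/r)^(-r*m) are evaluated as exp(-r*m*log1p(lam/r)) so the
r -> infinity and large-N regimes stay accurate.

Imperfect detectability (per-individual miss probability delta) thins the
detected count in m quadrats to NB(r*m, mean lam*(1-delta)*m). Two variants
of the finite-area formula are offered, differing in whether the
presence-conditioning terms P(Y > 0) also use the thinned mean:

* ``printed``  — lam*(1-delta) substituted everywhere (the published form);
* ``consistent`` — the thinned mean appears only in the detection term,
  while P(Y > 0) keeps the true abundance lam, mirroring the Poisson
  treatment (thinning cannot change whether the species is present). Only
  this variant recovers the Poisson delta-formula in the r -> infinity limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._types import (
    INFINITE,
    AreaSize,
    SampleSizeResult,
    is_infinite,
    validate_area_size,
    validate_beta,
    validate_delta,
    validate_lam,
    validate_r,
)
from .poisson import _verified_ceil

__all__ = [
    "NegBinParams",
    "nb_n_finite",
    "nb_n_infinite",
    "nb_n_finite_delta",
    "nb_n_infinite_delta",
    "nb_nondetect_prob",
    "DELTA_VARIANTS",
]

DELTA_VARIANTS = ("printed", "consistent")


@dataclass(frozen=True)
class NegBinParams:
    """Negative Binomial parameters in the (r, lam) mean parameterization."""

    r: float
    lam: float

    def __post_init__(self) -> None:
        validate_r(self.r)
        validate_lam(self.lam)

    @property
    def p(self) -> float:
        """Success parameter of the classical (r, p) parameterization."""
        return self.lam / (self.r + self.lam)

    @property
    def dispersion_index(self) -> float:
        """Variance-to-mean ratio, 1 + lam/r (> 1)."""
        return 1.0 + self.lam / self.r

    @property
    def variance(self) -> float:
        return self.lam * self.dispersion_index


def _zero_prob(lam: float, r: float, m: float) -> float:
    """P(NB(r*m, mean lam*m) = 0) = (1 + lam/r)^(-r*m), overflow-safe."""
    return math.exp(-r * m * math.log1p(lam / r))


def _check_variant(variant: str) -> None:
    if variant not in DELTA_VARIANTS:
        raise ValueError(f"variant must be one of {DELTA_VARIANTS}, got {variant!r}")


def nb_nondetect_prob(
    lam: float,
    r: float,
    N: AreaSize,
    n: int,
    delta: float = 0.0,
    variant: str = "printed",
) -> float:
    """Conditional non-detection probability under NB abundance.

    For delta = 0:
        ((1+lam/r)^(-r*n) - (1+lam/r)^(-r*N)) / (1 - (1+lam/r)^(-r*N)).

    For delta > 0 the detection term uses the thinned mean lam*(1-delta);
    the P(Y>0) terms use lam*(1-delta) (``printed``) or lam (``consistent``).
    """
    lam = validate_lam(lam)
    r = validate_r(r)
    N = validate_area_size(N)
    delta = validate_delta(delta)
    _check_variant(variant)
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not is_infinite(N) and n > N:
        raise ValueError(f"n={n} exceeds the number of quadrats N={N}")
    lam_det = lam * (1.0 - delta)
    top = _zero_prob(lam_det, r, n)
    if is_infinite(N):
        return top
    lam_area = lam_det if variant == "printed" else lam
    pN = _zero_prob(lam_area, r, N)
    return max(0.0, (top - pN) / (1.0 - pN))


def nb_n_finite(beta: float, lam: float, r: float, N: int) -> int:
    """Minimum n for a finite area of N quadrats, perfect detection.

    n = ceil(-(1/r) * log(beta + (1-beta)*(1+lam/r)^(-r*N)) / log(1+lam/r)),
    always in [1, N]; recovers the Poisson finite-area answer as r -> inf.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    r = validate_r(r)
    N = validate_area_size(N)
    if is_infinite(N):
        return nb_n_infinite(beta, lam, r)
    thresh = beta + (1.0 - beta) * _zero_prob(lam, r, N)
    denom = r * math.log1p(lam / r)
    return _verified_ceil(
        -math.log(thresh) / denom,
        lambda m: _zero_prob(lam, r, m) <= thresh,
    )


def nb_n_infinite(beta: float, lam: float, r: float) -> int:
    """Minimum n for an unbounded area, perfect detection.

    n = ceil(-(1/r) * log(beta) / log(1 + lam/r)).
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    r = validate_r(r)
    denom = r * math.log1p(lam / r)
    return _verified_ceil(
        -math.log(beta) / denom,
        lambda m: _zero_prob(lam, r, m) <= beta,
    )


def nb_n_finite_delta(
    beta: float,
    lam: float,
    r: float,
    N: int,
    delta: float,
    variant: str = "printed",
) -> SampleSizeResult:
    """Minimum n for a finite area with imperfect detectability, NB abundance.

    Both variants reduce to `nb_n_finite` at delta = 0. As with the Poisson
    case, n <= N is only guaranteed at delta = 0; an infeasible requirement
    is returned uncapped with feasible=False and the probability at n = N.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    r = validate_r(r)
    N = validate_area_size(N)
    delta = validate_delta(delta)
    _check_variant(variant)
    if is_infinite(N):
        n = nb_n_infinite_delta(beta, lam, r, delta)
        return SampleSizeResult(
            n=n,
            formula_id="5.5" if delta > 0 else "5.3",
            feasible=True,
            achieved_prob=nb_nondetect_prob(lam, r, INFINITE, n, delta, variant),
        )
    lam_det = lam * (1.0 - delta)
    lam_area = lam_det if variant == "printed" else lam
    thresh = beta + (1.0 - beta) * _zero_prob(lam_area, r, N)
    denom = r * math.log1p(lam_det / r)
    n = _verified_ceil(
        -math.log(thresh) / denom,
        lambda m: _zero_prob(lam_det, r, m) <= thresh,
    )
    feasible = n <= N
    return SampleSizeResult(
        n=n,
        formula_id="5.4" if delta > 0 else "5.2",
        feasible=feasible,
        achieved_prob=nb_nondetect_prob(lam, r, N, n if feasible else N, delta, variant),
    )


def nb_n_infinite_delta(beta: float, lam: float, r: float, delta: float) -> int:
    """Minimum n for an unbounded area with imperfect detectability.

    n = ceil(-(1/r) * log(beta) / log(1 + lam*(1-delta)/r)); converges to the
    Poisson answer -log(beta)/(lam*(1-delta)) as r -> infinity.
    """
    beta = validate_beta(beta)
    lam = validate_lam(lam)
    r = validate_r(r)
    delta = validate_delta(delta)
    lam_det = lam * (1.0 - delta)
    denom = r * math.log1p(lam_det / r)
    return _verified_ceil(
        -math.log(beta) / denom,
        lambda m: _zero_prob(lam_det, r, m) <= beta,
    )
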