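"""Monte Carlo validation of the sample-size formulas, plus count generators.

Each replicate realises the abundance of the species over the whole area,
conditions on actual presence (total Y > 0) by rejection, applies the
per-individual detection error, and records whether the n sampled quadrats
yielded no detection at all. The fraction of failures among accepted
replicates estimates the conditional non-detection probability that the
closed forms bound by beta.

Two modes:

* ``aggregated`` (default) — draws only the two sufficient totals per
  replicate: the sampled-quadrat total (Poisson(lam*n) or NB(r*n, .)) and
  the unsampled remainder (Poisson(lam*(N-n)) or NB(r*(N-n), .)), using the
  additivity of both families; the detected total is a Binomial thinning of
  the sampled total, since per-individual misses commute with summation.
* ``per_quadrat`` — draws all N per-quadrat counts and thins each sampled
  quadrat individually, i.e. the simulation algorithm taken literally. Meant
  for small N; it certifies the aggregated shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._types import validate_delta, validate_lam, validate_r
from .estimation import CountData

__all__ = [
    "MCConfig",
    "MCResult",
    "simulate_nondetect_poisson",
    "simulate_nondetect_negbin",
    "generate_counts",
    "DEFAULT_SEED",
]

#: Default RNG seed used by the CLI when none is given.
DEFAULT_SEED = 20220046

# Replicates (aggregated) / matrix cells (per-quadrat) drawn per chunk.
_CHUNK = 1_000_000
_PER_QUADRAT_MAX_N = 100_000


@dataclass(frozen=True)
class MCConfig:
    """Replication settings: K iterations, RNG seed, simulation mode."""

    iterations: int = 1_000_000
    seed: int = DEFAULT_SEED
    mode: Literal["aggregated", "per_quadrat"] = "aggregated"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.mode not in ("aggregated", "per_quadrat"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class MCResult:
    """Estimated conditional non-detection probability with its uncertainty."""

    p_hat: float
    accepted: int
    failures: int
    stderr: float

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "accepted": self.accepted,
            "failures": self.failures,
            "stderr": self.stderr,
        }


def _finish(failures: int, accepted: int) -> MCResult:
    if accepted == 0:
        raise RuntimeError(
            "no replicate had the species present (Y > 0); "
            "lam * N is too small for conditional estimation"
        )
    p_hat = failures / accepted
    stderr = math.sqrt(p_hat * (1.0 - p_hat) / accepted)
    return MCResult(p_hat=p_hat, accepted=int(accepted), failures=int(failures), stderr=stderr)


def _nb_p(lam: float, r: float) -> float:
    # numpy's negative_binomial(n, p) counts failures before n successes,
    # mean n*(1-p)/p; mean lam at size r needs p = r/(r+lam).
    return r / (r + lam)


def _validate_common(lam: float, N: int, n: int, delta: float) -> tuple[float, int, int, float]:
    lam = validate_lam(lam)
    delta = validate_delta(delta)
    N = int(N)
    n = int(n)
    if N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    if not 1 <= n <= N:
        raise ValueError(f"n must satisfy 1 <= n <= N={N}, got {n}")
    return lam, N, n, delta


def _simulate_aggregated(draw_totals, delta: float, config: MCConfig) -> MCResult:
    rng = np.random.default_rng(config.seed)
    accepted = 0
    failures = 0
    remaining = config.iterations
    while remaining > 0:
        k = min(_CHUNK, remaining)
        sampled, rest = draw_totals(rng, k)
        detected = rng.binomial(sampled, 1.0 - delta) if delta > 0.0 else sampled
        present = (sampled + rest) > 0
        accepted += int(present.sum())
        failures += int((present & (detected == 0)).sum())
        remaining -= k
    return _finish(failures, accepted)


def _simulate_per_quadrat(draw_matrix, delta: float, n: int, config: MCConfig) -> MCResult:
    rng = np.random.default_rng(config.seed)
    accepted = 0
    failures = 0
    remaining = config.iterations
    while remaining > 0:
        k = min(max(1, _CHUNK // max(1, draw_matrix.N)), remaining)
        counts = draw_matrix(rng, k)  # k x N per-quadrat counts
        sampled = counts[:, :n]
        if delta > 0.0:
            detected = rng.binomial(sampled, 1.0 - delta)
        else:
            detected = sampled
        present = counts.sum(axis=1) > 0
        accepted += int(present.sum())
        failures += int((present & (detected.sum(axis=1) == 0)).sum())
        remaining -= k
    return _finish(failures, accepted)


def simulate_nondetect_poisson(
    lam: float, N: int, n: int, delta: float = 0.0, config: MCConfig = MCConfig()
) -> MCResult:
    """Estimate P(no detection in n of N quadrats | Y > 0), Poisson abundance."""
    lam, N, n, delta = _validate_common(lam, N, n, delta)
    if config.mode == "aggregated":
        def draw_totals(rng, k):
            return rng.poisson(lam * n, size=k), rng.poisson(lam * (N - n), size=k)

        return _simulate_aggregated(draw_totals, delta, config)

    if N > _PER_QUADRAT_MAX_N:
        raise ValueError(f"per_quadrat mode enumerates quadrats; N={N} is too large")

    def draw_matrix(rng, k):
        return rng.poisson(lam, size=(k, N))

    draw_matrix.N = N
    return _simulate_per_quadrat(draw_matrix, delta, n, config)


def simulate_nondetect_negbin(
    lam: float, r: float, N: int, n: int, delta: float = 0.0, config: MCConfig = MCConfig()
) -> MCResult:
    """Estimate P(no detection in n of N quadrats | Y > 0), NB abundance."""
    lam, N, n, delta = _validate_common(lam, N, n, delta)
    r = validate_r(r)
    p = _nb_p(lam, r)
    if config.mode == "aggregated":
        def draw_totals(rng, k):
            sampled = rng.negative_binomial(r * n, p, size=k)
            rest = (
                rng.negative_binomial(r * (N - n), p, size=k)
                if N > n
                else np.zeros(k, dtype=np.int64)
            )
            return sampled, rest

        return _simulate_aggregated(draw_totals, delta, config)

    if N > _PER_QUADRAT_MAX_N:
        raise ValueError(f"per_quadrat mode enumerates quadrats; N={N} is too large")

    def draw_matrix(rng, k):
        return rng.negative_binomial(r, p, size=(k, N))

    draw_matrix.N = N
    return _simulate_per_quadrat(draw_matrix, delta, n, config)


def generate_counts(
    model: str,
    lam: float,
    r: float | None = None,
    delta: float = 0.0,
    n0: int = 1000,
    seed: int = DEFAULT_SEED,
) -> CountData:
    """Synthetic per-quadrat *detected* counts for estimator checks.

    True counts are Poisson(lam) or NB(r, mean lam); each individual is then
    observed independently with probability 1 - delta (binomial thinning).
    """
    lam = validate_lam(lam)
    delta = validate_delta(delta)
    if n0 < 1:
        raise ValueError(f"n0 must be >= 1, got {n0}")
    rng = np.random.default_rng(seed)
    if model == "poisson":
        true_counts = rng.poisson(lam, size=n0)
    elif model == "negbin":
        if r is None:
            raise ValueError("r is required for the negbin model")
        r = validate_r(r)
        true_counts = rng.negative_binomial(r, _nb_p(lam, r), size=n0)
    else:
        raise ValueError(f"model must be 'poisson' or 'negbin', got {model!r}")
    detected = rng.binomial(true_counts, 1.0 - delta) if delta > 0.0 else true_counts
    return CountData(detected.tolist())
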