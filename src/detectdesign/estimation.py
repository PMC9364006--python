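"""Abundance-parameter estimation from per-quadrat survey data.

Two kinds of field input are supported:

* a detection summary — n0 quadrats surveyed, w of them with at least one
  detection — which identifies the Poisson mean through the zero class:
  1 - w/n0 estimates P(no detection per quadrat) = exp(-lam*(1-delta));
* full per-quadrat detected counts, from which the Negative Binomial (r, lam)
  pair is recovered by the natural (biased) moment estimators. Binomial
  thinning leaves r untouched and scales the mean by 1 - delta, so only
  lam needs the 1/(1-delta) correction.

delta is treated as known and user-supplied; it is never estimated here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import math

import numpy as np
import pandas as pd

from ._types import validate_delta
from .negbin import NegBinParams

__all__ = [
    "DetectionSummary",
    "CountData",
    "estimate_poisson_lambda",
    "estimate_negbin",
    "read_counts_csv",
]


@dataclass(frozen=True)
class DetectionSummary:
    """Presence/absence outcome of a pilot survey.

    n0: number of quadrats surveyed; w: number of them with >= 1 detection.
    """

    n0: int
    w: int

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError(f"n0 must be >= 1, got {self.n0}")
        if not 0 <= self.w <= self.n0:
            raise ValueError(f"w must lie in [0, n0={self.n0}], got {self.w}")

    @property
    def detection_rate(self) -> float:
        return self.w / self.n0


@dataclass(frozen=True)
class CountData:
    """Per-quadrat detected counts x_1, ..., x_{n0}."""

    counts: tuple[int, ...]

    def __init__(self, counts: Sequence[int]) -> None:
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if len(counts) < 1:
            raise ValueError("counts must be non-empty")
        object.__setattr__(self, "counts", counts)

    @property
    def n0(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def variance(self) -> float:
        """Sample variance with the 1/n0 divisor (no Bessel correction)."""
        if self.n0 < 2:
            raise ValueError("at least 2 counts are needed for a variance")
        return float(np.var(self.counts, ddof=0))

    def to_summary(self) -> DetectionSummary:
        """Collapse counts to the presence/absence summary."""
        return DetectionSummary(n0=self.n0, w=int(np.count_nonzero(self.counts)))


def estimate_poisson_lambda(summary: DetectionSummary, delta: float = 0.0) -> float:
    """Poisson mean from the fraction of quadrats with a detection.

    lam_hat = -log(1 - w/n0) / (1 - delta).

    w = n0 (every quadrat had a detection) makes the estimate unbounded and
    raises; w = 0 returns 0.0 with a warning, since every design formula
    assumes lam > 0.
    """
    delta = validate_delta(delta)
    if summary.w == summary.n0:
        raise ValueError(
            "all surveyed quadrats contained the species: "
            "the estimate is unbounded; increase n0"
        )
    if summary.w == 0:
        warnings.warn(
            "no quadrat contained the species: lambda estimated as 0, "
            "but all design formulas require lambda > 0",
            stacklevel=2,
        )
        return 0.0
    return -math.log(1.0 - summary.detection_rate) / (1.0 - delta)


def estimate_negbin(counts: CountData, delta: float = 0.0) -> NegBinParams:
    """Moment estimators of (r, lam) from per-quadrat detected counts.

    lam_hat = x_bar / (1 - delta),  r_hat = x_bar**2 / (s2 - x_bar),

    with x_bar the sample mean and s2 the uncorrected (1/n0) sample variance
    of the detected counts. Requires observed overdispersion (s2 > x_bar);
    otherwise the Poisson model is the appropriate one and an error says so.
    """
    delta = validate_delta(delta)
    xbar = counts.mean
    if xbar == 0.0:
        raise ValueError("no individuals detected; cannot estimate abundance")
    s2 = counts.variance
    if s2 <= xbar:
        raise ValueError(
            f"no overdispersion in the counts (s2={s2:.6g} <= mean={xbar:.6g}); "
            "use the Poisson model instead"
        )
    return NegBinParams(r=xbar**2 / (s2 - xbar), lam=xbar / (1.0 - delta))


def read_counts_csv(path: str | Path) -> CountData:
    """Read per-quadrat counts from a one-column CSV.

    Expected dialect: a header line ``count``, then one nonnegative integer
    per row. Blank lines are ignored; anything non-integer is a hard error.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if list(df.columns) != ["count"]:
        raise ValueError(
            f"expected a single CSV column named 'count', got {list(df.columns)}"
        )
    values = []
    for raw in df["count"].dropna():
        text = str(raw).strip()
        if not text:
            continue
        try:
            value = int(text)
        except ValueError:
            raise ValueError(f"non-integer count in {path}: {text!r}") from None
        values.append(value)
    return CountData(values)
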