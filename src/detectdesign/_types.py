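"""Shared domain types for survey-design questions and their answers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Union

#: Sentinel for an unbounded study area (the classical infinite-area setting).
INFINITE = math.inf

AreaSize = Union[int, float]  # positive int, or INFINITE


def is_infinite(area_size: AreaSize) -> bool:
    return area_size == INFINITE


def validate_area_size(area_size: AreaSize) -> AreaSize:
    if is_infinite(area_size):
        return INFINITE
    if not (isinstance(area_size, (int,)) or (isinstance(area_size, float) and area_size.is_integer())):
        raise ValueError(f"area_size must be a positive integer or infinite, got {area_size!r}")
    n = int(area_size)
    if n < 1:
        raise ValueError(f"area_size must be >= 1, got {n}")
    return n


def validate_beta(beta: float) -> float:
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    return float(beta)


def validate_lam(lam: float) -> float:
    if not lam > 0.0:
        raise ValueError(f"lam must be positive, got {lam}")
    return float(lam)


def validate_delta(delta: float) -> float:
    # delta = 1 means individuals are never detected: the required n diverges.
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    return float(delta)


def validate_r(r: float) -> float:
    if not r > 0.0:
        raise ValueError(f"r must be positive, got {r}")
    return float(r)


@dataclass(frozen=True)
class DesignSpec:
    """A survey-design question.

    Parameters
    ----------
    beta : float
        Maximum tolerated probability of failing to detect the species from
        the samples, given that it is present in the area. In (0, 1).
    lam : float
        Mean number of individuals per unit-area quadrat (Poisson rate, or
        Negative Binomial mean). Positive.
    area_size : int or math.inf
        Number of non-overlapping quadrats the area comprises (N), or
        ``INFINITE`` for the unbounded-area setting.
    delta : float
        Per-individual false-negative probability, in [0, 1). False positives
        are assumed impossible.
    model : {"poisson", "negbin"}
        Per-quadrat abundance model.
    r : float, optional
        Negative Binomial size parameter; required iff model == "negbin".
    """

    beta: float
    lam: float
    area_size: AreaSize = INFINITE
    delta: float = 0.0
    model: Literal["poisson", "negbin"] = "poisson"
    r: float | None = None

    def __post_init__(self) -> None:
        validate_beta(self.beta)
        validate_lam(self.lam)
        object.__setattr__(self, "area_size", validate_area_size(self.area_size))
        validate_delta(self.delta)
        if self.model not in ("poisson", "negbin"):
            raise ValueError(f"model must be 'poisson' or 'negbin', got {self.model!r}")
        if self.model == "negbin":
            if self.r is None:
                raise ValueError("r is required for the negbin model")
            validate_r(self.r)


@dataclass(frozen=True)
class SampleSizeResult:
    """A recommended number of quadrats with its provenance.

    Attributes
    ----------
    n : int
        Recommended minimum number of quadrats to sample.
    formula_id : str
        Identifier of the closed-form expression used
        (one of "1.1", "2.1", "4.1", "4.4", "5.2", "5.3", "5.4", "5.5").
    feasible : bool
        True iff n <= N (vacuously true for an infinite area). Under
        imperfect detectability the requirement can exceed the area itself;
        the raw n is then reported uncapped with feasible=False.
    achieved_prob : float
        Closed-form conditional non-detection probability at the returned n
        (evaluated at n = N when infeasible).
    """

    n: int
    formula_id: str
    feasible: bool
    achieved_prob: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "formula_id": self.formula_id,
            "feasible": self.feasible,
            "achieved_prob": self.achieved_prob,
        }
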