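"""Dispatch from a survey-design question to the right closed-form answer.

The decision grid is model (Poisson / NB) x area size (finite N / unbounded)
x detectability (perfect / imperfect); each of the eight cells maps to
exactly one formula id.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from ._types import INFINITE, DesignSpec, SampleSizeResult, is_infinite
from . import negbin, poisson

__all__ = ["recommend", "spec_from_estimate", "FORMULA_GRID"]

logger = logging.getLogger("detectdesign")

#: (model, finite N?, delta > 0?) -> formula id
FORMULA_GRID = {
    ("poisson", True, True): "4.1",
    ("poisson", True, False): "2.1",
    ("poisson", False, True): "4.4",
    ("poisson", False, False): "1.1",
    ("negbin", True, True): "5.4",
    ("negbin", True, False): "5.2",
    ("negbin", False, True): "5.5",
    ("negbin", False, False): "5.3",
}


def recommend(spec: DesignSpec, nb_delta_variant: str = "printed") -> SampleSizeResult:
    """Minimum sample size for a design question, with formula provenance."""
    finite = not is_infinite(spec.area_size)
    formula_id = FORMULA_GRID[(spec.model, finite, spec.delta > 0.0)]

    if spec.model == "poisson":
        if finite:
            result = poisson.n_finite_delta(spec.beta, spec.lam, spec.area_size, spec.delta)
        else:
            n = poisson.n_infinite_delta(spec.beta, spec.lam, spec.delta)
            result = SampleSizeResult(
                n=n,
                formula_id=formula_id,
                feasible=True,
                achieved_prob=poisson.nondetect_prob(spec.lam, INFINITE, n, spec.delta),
            )
    else:
        if finite:
            result = negbin.nb_n_finite_delta(
                spec.beta, spec.lam, spec.r, spec.area_size, spec.delta, nb_delta_variant
            )
        else:
            n = negbin.nb_n_infinite_delta(spec.beta, spec.lam, spec.r, spec.delta)
            result = SampleSizeResult(
                n=n,
                formula_id=formula_id,
                feasible=True,
                achieved_prob=negbin.nb_nondetect_prob(
                    spec.lam, spec.r, INFINITE, n, spec.delta, nb_delta_variant
                ),
            )

    assert result.formula_id == formula_id
    logger.info(
        "recommend: model=%s beta=%g lam=%g N=%s delta=%g r=%s -> "
        "n=%d (formula %s), achieved_prob=%.8f, feasible=%s",
        spec.model, spec.beta, spec.lam, spec.area_size, spec.delta, spec.r,
        result.n, result.formula_id, result.achieved_prob, result.feasible,
    )
    return result


def spec_from_estimate(
    path: str | Path,
    beta: float,
    area_size=INFINITE,
    delta: float | None = None,
    model: str | None = None,
) -> DesignSpec:
    """Build a DesignSpec from an `estimate` JSON record.

    The JSON supplies lambda (and r, for the NB model) plus the delta it was
    computed under; beta and the area size come from the caller. A delta or
    model given both here and in the file must agree.
    """
    with open(path) as fh:
        record = json.load(fh)
    if "lambda_hat" not in record:
        raise ValueError(f"{path} is not an estimate record (no 'lambda_hat')")
    file_model = "negbin" if record.get("r_hat") is not None else "poisson"
    if model is not None and model != file_model:
        raise ValueError(
            f"conflicting models: requested {model!r} but {path} holds a "
            f"{file_model} estimate"
        )
    file_delta = record.get("delta", 0.0)
    if delta is not None and delta != file_delta:
        raise ValueError(
            f"conflicting delta: {delta} given but the estimate used {file_delta}"
        )
    return DesignSpec(
        beta=beta,
        lam=record["lambda_hat"],
        area_size=area_size,
        delta=file_delta,
        model=file_model,
        r=record.get("r_hat"),
    )
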