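"""Shared oracles and parameter grids.

The scan oracles recompute the minimal sample size by brute force: evaluate
the conditional non-detection expression at m = 1, 2, 3, ... and return the
first m meeting the tolerance. They share no code path with the closed-form
ceilings they check.
"""

import itertools

import numpy as np
import pytest

# model-agnostic grid used by the minimality / monotonicity / limit checks
BETAS = [0.2, 0.05, 0.01]
LAMS = [0.001, 0.01, 0.1, 1.0]
AREA_SIZES = [10, 300, 3000]
DELTAS = [0.0, 0.1, 0.5]

GRID = list(itertools.product(BETAS, LAMS, AREA_SIZES, DELTAS))


def scan_min_n_poisson(beta, lam, N, delta=0.0):
    """Linear-scan minimal m with the Poisson conditional probability <= beta.

    N may be np.inf. The scan extends beyond N when detectability error makes
    the requirement infeasible, evaluating the same analytic expression the
    design inverts.
    """
    m_max = int(np.ceil(-np.log(beta) / (lam * (1.0 - delta)))) + 2
    m = np.arange(1, m_max + 1)
    top = np.exp(-lam * (1.0 - delta) * m)
    if np.isinf(N):
        p = top
    else:
        pN = np.exp(-lam * N)
        p = (top - pN) / (1.0 - pN)
    hits = np.nonzero(p <= beta)[0]
    assert hits.size > 0, "scan bound too small"
    return int(m[hits[0]])


def scan_min_n_negbin(beta, lam, r, N, delta=0.0, variant="printed"):
    """Linear-scan minimal m under Negative Binomial abundance."""
    lam_det = lam * (1.0 - delta)
    denom = r * np.log1p(lam_det / r)
    m_max = int(np.ceil(-np.log(beta) / denom)) + 2
    m = np.arange(1, m_max + 1)
    top = np.exp(-denom * m)
    if np.isinf(N):
        p = top
    else:
        lam_area = lam_det if variant == "printed" else lam
        pN = np.exp(-r * N * np.log1p(lam_area / r))
        p = (top - pN) / (1.0 - pN)
    hits = np.nonzero(p <= beta)[0]
    assert hits.size > 0, "scan bound too small"
    return int(m[hits[0]])


@pytest.fixture(scope="session")
def grid():
    return GRID
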