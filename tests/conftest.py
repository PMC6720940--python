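import numpy as np
import pytest

import sigrefit as sr


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic toy FASTA/VCF/BED/signature fixtures (hand-tallied)."""
    out = tmp_path_factory.mktemp("fixtures")
    return sr.make_fixtures(out)


@pytest.fixture(scope="session")
def orthogonal_P():
    """Five synthetic signatures with disjoint channel support (orthogonal)."""
    return sr.synthetic_signature_matrix(n_signatures=5, seed=11, overlap=0.0)


@pytest.fixture(scope="session")
def overlapping_P():
    """Five redundant synthetic signatures sharing a common background."""
    return sr.synthetic_signature_matrix(n_signatures=5, seed=11, overlap=0.6)


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All points of the n-simplex on a regular grid of the given step.

    Independent brute-force oracle for the constrained fits: enumerates
    integer compositions of 1/step into n parts.
    """
    k = int(round(1.0 / step))
    if n == 1:
        return np.ones((1, 1))
    grids = []
    # compositions of k into n non-negative parts, built recursively
    def rec(prefix, remaining, depth):
        if depth == n - 1:
            grids.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, depth + 1)

    rec([], k, 0)
    return np.asarray(grids, dtype=float) / k


def grid_min_objective(P: np.ndarray, m: np.ndarray, step: float) -> float:
    """Smallest ||m - P e||_2 over the simplex grid (vectorized)."""
    grid = simplex_grid(P.shape[1], step)
    residuals = m[None, :] - grid @ P.T
    return float(np.sqrt((residuals**2).sum(axis=1)).min())
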