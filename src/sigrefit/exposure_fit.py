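"""Constrained least-squares exposure estimation and redundancy diagnostics.

Given a catalogue m (as channel frequencies) and a column-stochastic
signature matrix P, the exposure vector e minimizes ||m - P e||_2 subject to
e >= 0, and by default also sum(e) = 1 so exposures are reported directly as
proportions of the mutational load. The pure non-negative mode is kept as an
option, with proportions obtained by renormalizing the minimizer.

Published signature sets are not orthogonal: some signatures can be
reconstructed almost perfectly from the others, which makes their estimated
exposures sensitive to small changes in the catalogue. Two diagnostics
quantify this redundancy: the pairwise cosine-similarity matrix, and the
leave-one-out reconstruction stability (the cosine similarity of each
signature with its best non-negative reconstruction from the remaining
columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .catalogue_io import (
    LOW_COUNT_THRESHOLD,
    LowCountWarning,
    MutationalCatalogue,
    SignatureMatrix,
)

__all__ = [
    "ExposureEstimate",
    "estimate_exposure",
    "reconstruct",
    "cosine_similarity_matrix",
    "reconstruction_stability",
    "exposures_to_frame",
]

#: solver negatives below this magnitude are numerical noise and are clipped
_CLIP_TOL = 1e-10

#: smallest Gram-submatrix eigenvalue below which the optimum is flagged as
#: non-unique (flat directions on the feasible set)
_DEGENERACY_TOL = 1e-12


@dataclass
class ExposureEstimate:
    """Result of fitting one catalogue against a signature matrix.

    ``raw_weights`` is the constrained minimizer; ``proportions`` is its
    renormalization to sum 1 (identical in simplex mode; all zero when the
    minimizer is zero). ``residual_norm`` is the Euclidean norm
    ||m_freq - P @ raw_weights|| at the minimizer, i.e. the objective value.
    """

    sample_id: str
    signature_names: list[str]
    raw_weights: np.ndarray
    residual_norm: float
    constraint_mode: str
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_weights = np.asarray(self.raw_weights, dtype=float)
        if self.raw_weights.shape != (len(self.signature_names),):
            raise ValueError("raw_weights length does not match signature names")
        if np.any(self.raw_weights < 0):
            raise ValueError("raw_weights must be non-negative")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")

    @property
    def proportions(self) -> np.ndarray:
        total = self.raw_weights.sum()
        if total == 0:
            return np.zeros_like(self.raw_weights)
        return self.raw_weights / total

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.proportions, index=list(self.signature_names), name=self.sample_id
        )


def _prepare_frequencies(m: MutationalCatalogue) -> np.ndarray:
    if m.total <= 0:
        raise ValueError(f"catalogue {m.sample_id!r} has zero total; cannot fit")
    if m.scale == "counts" and m.total < LOW_COUNT_THRESHOLD:
        warnings.warn(
            f"catalogue {m.sample_id!r} has only {m.total:.0f} mutations "
            f"(< {LOW_COUNT_THRESHOLD}); exposure estimates will be unstable",
            LowCountWarning,
            stacklevel=3,
        )
    return m.as_frequencies().values


def _objective(P: np.ndarray, m: np.ndarray, e: np.ndarray) -> float:
    return float(np.linalg.norm(m - P @ e))


def _polish_simplex(
    P: np.ndarray, m: np.ndarray, e: np.ndarray
) -> np.ndarray | None:
    """Refine a simplex solution by solving the KKT system on its free set.

    Fixes the apparent active set (entries ~0), solves the
    equality-constrained least-squares problem on the remaining coordinates,
    and returns the refined point if it stays feasible.
    """
    free = e > 1e-7
    if not free.any():
        return None
    Pf = P[:, free]
    k = Pf.shape[1]
    G = Pf.T @ Pf
    c = Pf.T @ m
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * c, [1.0]])
    try:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return None
    ef = sol[:k]
    if np.any(ef < -_CLIP_TOL):
        return None
    out = np.zeros_like(e)
    out[free] = np.clip(ef, 0.0, None)
    s = out.sum()
    if s <= 0:
        return None
    return out / s


def _solve_simplex(P: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Minimize ||m - P e|| over the probability simplex."""
    n = P.shape[1]
    if n == 1:
        return np.ones(1)
    G = P.T @ P
    c = P.T @ m

    def fun(e: np.ndarray) -> float:
        r = P @ e - m
        return float(r @ r)

    def jac(e: np.ndarray) -> np.ndarray:
        return 2.0 * (G @ e - c)

    x0 = np.full(n, 1.0 / n)
    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                      "jac": lambda e: np.ones(n)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    e = np.clip(res.x, 0.0, None)
    s = e.sum()
    e = e / s if s > 0 else np.full(n, 1.0 / n)
    polished = _polish_simplex(P, m, e)
    if polished is not None and fun(polished) < fun(e):
        e = polished
    return e


def _solve_nonneg(P: np.ndarray, m: np.ndarray) -> np.ndarray:
    e, _ = scipy.optimize.nnls(P, m)
    return e


def _is_degenerate(P: np.ndarray, e: np.ndarray) -> bool:
    """Flat directions at the optimum: near-zero Gram eigenvalue on the
    support of the solution (a movement there changes the objective by ~0)."""
    support = e > _CLIP_TOL
    if support.sum() < 2:
        return False
    G = P[:, support].T @ P[:, support]
    return bool(np.linalg.eigvalsh(G)[0] < _DEGENERACY_TOL)


def estimate_exposure(
    catalogues: MutationalCatalogue | list[MutationalCatalogue],
    P: SignatureMatrix,
    constraint_mode: str = "simplex",
) -> ExposureEstimate | list[ExposureEstimate]:
    """Estimate signature exposures for one or more catalogues.

    Catalogues in counts scale are converted to frequencies internally.
    ``constraint_mode="simplex"`` (default) solves
    argmin ||m - P e|| s.t. e >= 0, sum(e) = 1;
    ``"nonneg"`` drops the sum constraint. Solver negatives below 1e-10 are
    clipped to zero (and renormalized in simplex mode). A warning is emitted
    for catalogues with fewer than 125 mutations.

    Returns a single estimate for a single catalogue, a list for a list.
    """
    single = isinstance(catalogues, MutationalCatalogue)
    items = [catalogues] if single else list(catalogues)
    if constraint_mode not in ("simplex", "nonneg"):
        raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
    results = []
    for m in items:
        freqs = _prepare_frequencies(m)
        if constraint_mode == "simplex":
            e = _solve_simplex(P.matrix, freqs)
        else:
            e = _solve_nonneg(P.matrix, freqs)
        e = np.where(e < _CLIP_TOL, 0.0, e)
        if constraint_mode == "simplex" and e.sum() > 0:
            e = e / e.sum()
        results.append(
            ExposureEstimate(
                sample_id=m.sample_id,
                signature_names=list(P.names),
                raw_weights=e,
                residual_norm=_objective(P.matrix, freqs, e),
                constraint_mode=constraint_mode,
                degenerate=_is_degenerate(P.matrix, e),
                provenance={"catalogue": dict(m.provenance)},
            )
        )
    return results[0] if single else results


def reconstruct(
    m: np.ndarray | MutationalCatalogue, P: SignatureMatrix, e: np.ndarray
) -> tuple[np.ndarray, float]:
    """Reconstructed profile P @ e and the residual norm ||m - P e||."""
    vec = m.values if isinstance(m, MutationalCatalogue) else np.asarray(m, dtype=float)
    e = np.asarray(e, dtype=float)
    if vec.shape != (P.matrix.shape[0],):
        raise ValueError(f"profile has shape {vec.shape}, expected ({P.matrix.shape[0]},)")
    if e.shape != (P.n_signatures,):
        raise ValueError(
            f"exposure vector has shape {e.shape}, expected ({P.n_signatures},)"
        )
    recon = P.matrix @ e
    return recon, float(np.linalg.norm(vec - recon))


def cosine_similarity_matrix(P: SignatureMatrix) -> pd.DataFrame:
    """Pairwise cosine similarity of signature columns (N x N, diagonal 1)."""
    norms = np.linalg.norm(P.matrix, axis=0)
    if np.any(norms == 0):
        bad = [n for n, v in zip(P.names, norms) if v == 0]
        raise ValueError(f"zero signature column(s): {', '.join(bad)}")
    unit = P.matrix / norms
    sim = np.clip(unit.T @ unit, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=list(P.names), columns=list(P.names))


def reconstruction_stability(P: SignatureMatrix) -> pd.Series:
    """Leave-one-out reconstruction similarity per signature.

    Each column is fitted (non-negatively) against the remaining columns; the
    returned value is the cosine similarity between the column and its
    reconstruction. Signatures near 1 are redundant: their profile is almost
    entirely expressible by the others. A zero reconstruction scores 0.
    """
    if P.n_signatures < 2:
        raise ValueError("reconstruction stability needs at least 2 signatures")
    out = {}
    for j, name in enumerate(P.names):
        target = P.matrix[:, j]
        others = np.delete(P.matrix, j, axis=1)
        e, _ = scipy.optimize.nnls(others, target)
        recon = others @ e
        denom = np.linalg.norm(target) * np.linalg.norm(recon)
        out[name] = float(target @ recon / denom) if denom > 0 else 0.0
    return pd.Series(out, name="loo_cosine_similarity")


def exposures_to_frame(estimates: list[ExposureEstimate]) -> pd.DataFrame:
    """Samples x signatures table of proportions, plus a residual column."""
    df = pd.DataFrame([est.to_series() for est in estimates])
    df["residual_norm"] = [est.residual_norm for est in estimates]
    return df
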