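"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Decomposes a preprocessed mixture matrix X (n_samples x n_channels) into
bilinear concentration profiles C (n x k) and spectral profiles S (p x k),
alternating constrained least-squares half-steps.  The working mode of the
pipeline is the SNV + first-derivative domain, where non-negativity is
applied to C only (derivative spectra are signed).  Recovered profiles carry
the usual scale/permutation ambiguity; component-to-analyte assignment is by
maximum spectral correlation against reference profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from scipy import stats

from .preprocess import PreprocessingChain, apply_chain
from .synthetic import PureComponentLibrary
from .types import SpectraSet

__all__ = [
    "MCRResult",
    "fit_mcr_als",
    "initialize_from_pure",
    "assign_components",
    "regress_profiles",
]


@dataclass
class MCRResult:
    C: np.ndarray                    # n_samples x k, arbitrary scale
    S: np.ndarray                    # n_channels x k, unit-norm columns
    lof_trace: list[float]           # % lack of fit per accepted iteration
    converged: bool
    n_iter: int
    assignment: dict = field(default_factory=dict)   # analyte -> (comp idx, corr)
    regressions: dict = field(default_factory=dict)  # analyte -> (slope, intercept, r2)

    @property
    def lof(self) -> float:
        return self.lof_trace[-1]

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S.T


def _lof(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    resid = X - C @ S.T
    return 100.0 * float(np.sqrt((resid**2).sum() / (X**2).sum()))


def _solve_c(X: np.ndarray, S: np.ndarray, nonneg: bool) -> np.ndarray:
    if not nonneg:
        return np.linalg.lstsq(S, X.T, rcond=None)[0].T
    C = np.empty((X.shape[0], S.shape[1]))
    for i, row in enumerate(X):
        C[i], _ = nnls(S, row)
    return C


def _solve_s(X: np.ndarray, C: np.ndarray, nonneg: bool) -> np.ndarray:
    if not nonneg:
        return np.linalg.lstsq(C, X, rcond=None)[0].T
    S = np.empty((X.shape[1], C.shape[1]))
    for j in range(X.shape[1]):
        S[j], _ = nnls(C, X[:, j])
    return S


def fit_mcr_als(
    X: np.ndarray,
    S_init: np.ndarray,
    nonneg_c: bool = True,
    nonneg_s: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MCRResult:
    """Alternate C <- argmin ||X - C S^T|| given S, then S given C, applying
    the active constraints at each half-step.

    Stops when the relative lack-of-fit change drops below ``tol`` or after
    ``max_iter`` iterations; a LOF increase beyond round-off stops the run
    with ``converged=False``.  S columns are renormalised to unit length each
    iteration (the scale ambiguity is pushed into C).
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(S_init, dtype=float).copy()
    if S.ndim != 2 or S.shape[0] != X.shape[1]:
        raise ValueError("S_init must be n_channels x n_components")
    k = S.shape[1]
    if np.linalg.matrix_rank(S) < k:
        raise ValueError("S_init columns are rank deficient (linearly dependent)")
    norms = np.linalg.norm(S, axis=0)
    S = S / norms
    lof_trace: list[float] = []
    converged = False
    C = _solve_c(X, S, nonneg_c)
    prev = _lof(X, C, S)
    lof_trace.append(prev)
    it = 0
    for it in range(1, max_iter + 1):
        S = _solve_s(X, C, nonneg_s)
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = 1.0
        S = S / norms
        C = _solve_c(X, S, nonneg_c)
        cur = _lof(X, C, S)
        if cur > prev * (1.0 + 1e-9) + 1e-12:
            converged = False
            lof_trace.append(cur)
            break
        lof_trace.append(cur)
        if prev == 0.0 or (prev - cur) / max(prev, 1e-300) < tol:
            converged = True
            break
        prev = cur
    else:
        converged = False
    return MCRResult(C=C, S=S, lof_trace=lof_trace, converged=converged, n_iter=it)


def initialize_from_pure(
    library_or_set,
    chain: PreprocessingChain,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Initial spectral profiles: the pure component spectra pushed through
    the same preprocessing chain as the mixtures, as columns.

    ``extra`` appends additional initial profiles (e.g. one background
    component taken from the mean processed mixture spectrum).
    """
    import pandas as pd

    if isinstance(library_or_set, PureComponentLibrary):
        lib = library_or_set
        n = lib.n_components
        pure = SpectraSet(
            axis=lib.axis,
            intensities=lib.pure_matrix(),
            concentrations=pd.DataFrame(np.eye(n), columns=lib.names),
            metadata=pd.DataFrame(
                {
                    "spectrum_id": [f"pure_{m}" for m in lib.names],
                    "sample_id": [f"pure_{m}" for m in lib.names],
                    "replicate": 1,
                    "batch": "pure",
                }
            ),
        )
    else:
        pure = library_or_set
    processed = apply_chain(pure, chain)
    S = processed.intensities.T  # p x k
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != S.shape[0]:  # accept profiles given as rows
            extra = extra.T
        S = np.hstack([S, extra])
    return S


def assign_components(
    S: np.ndarray, reference: np.ndarray, names: list[str]
) -> dict[str, tuple[int, float]]:
    """Match recovered profile columns to reference profiles (columns) by
    maximum Pearson correlation (one-to-one, Hungarian assignment)."""
    k_ref = reference.shape[1]
    if len(names) != k_ref:
        raise ValueError("one name per reference column required")
    corr = np.zeros((k_ref, S.shape[1]))
    for i in range(k_ref):
        for j in range(S.shape[1]):
            sj = S[:, j]
            if sj.std() == 0 or reference[:, i].std() == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(reference[:, i], sj)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return {names[i]: (int(j), float(corr[i, j])) for i, j in zip(rows, cols)}


def regress_profiles(
    C: np.ndarray,
    known,
    assignment: dict[str, tuple[int, float]],
) -> dict[str, tuple[float, float, float]]:
    """OLS of each assigned concentration profile against its analyte's known
    concentrations: analyte -> (slope, intercept, R^2).  Analytes without an
    assigned component are omitted."""
    out: dict[str, tuple[float, float, float]] = {}
    for analyte, (comp, _) in assignment.items():
        if comp < 0 or comp >= C.shape[1]:
            continue
        x = np.asarray(known[analyte], dtype=float)
        y = C[:, comp]
        res = stats.linregress(x, y)
        out[analyte] = (float(res.slope), float(res.intercept), float(res.rvalue**2))
    return out
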