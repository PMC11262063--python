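"""PCA of preprocessed spectra and PC-loading-based peak selection.

Scores visualise concentration trends; local extrema of the PC-1 loading
nominate bands for univariate limit-of-detection work.  Component signs are
fixed deterministically (largest-magnitude loading element positive) so
repeated runs agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .types import SpectraSet

__all__ = ["PCAResult", "PeakSelection", "fit_pca", "select_peaks_from_loadings"]


@dataclass
class PCAResult:
    scores: np.ndarray          # n_samples x n_components
    loadings: np.ndarray        # n_channels x n_components, orthonormal columns
    explained_variance_pct: np.ndarray  # TEV per component, %
    mean: np.ndarray            # centering vector
    axis: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class PeakSelection:
    """Selected loading extrema: rows of (wavenumber, channel, loading, sign),
    ranked by |loading|, ties broken toward lower wavenumber."""

    wavenumbers: np.ndarray
    channels: np.ndarray
    loadings: np.ndarray
    signs: np.ndarray
    component: int

    def __len__(self) -> int:
        return len(self.channels)


def fit_pca(sset: SpectraSet, n_components: int | None = None) -> PCAResult:
    """Column-mean-centred PCA of the intensity matrix (no per-channel
    scaling, standard for spectra)."""
    X = sset.intensities
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # p x k
    # deterministic sign: largest-magnitude loading element made positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=100.0 * model.explained_variance_ratio_,
        mean=model.mean_,
        axis=sset.axis.copy(),
    )


def select_peaks_from_loadings(
    result: PCAResult,
    component: int = 0,
    max_peaks: int = 3,
    min_prominence: float = 0.10,
) -> PeakSelection:
    """Local extrema of |loading| ranked by magnitude.

    ``min_prominence`` is relative to max |loading|.  A flat loading (no
    extremum above the prominence floor) yields an empty selection with a
    warning.
    """
    if not 0 <= component < result.n_components:
        raise IndexError(f"component {component} out of range 0..{result.n_components - 1}")
    load = result.loadings[:, component]
    mag = np.abs(load)
    empty = PeakSelection(
        np.empty(0), np.empty(0, dtype=int), np.empty(0), np.empty(0), component
    )
    if max_peaks == 0:
        return empty
    top = mag.max()
    if top == 0:
        warnings.warn("flat loading: no peaks selected", stacklevel=2)
        return empty
    idx, _ = find_peaks(mag, prominence=min_prominence * top)
    if idx.size == 0:
        warnings.warn("no loading extremum above prominence threshold", stacklevel=2)
        return empty
    # magnitude-descending, tie-break by lower wavenumber (lower index)
    order = sorted(range(idx.size), key=lambda k: (-mag[idx[k]], idx[k]))
    keep = idx[order][:max_peaks]
    return PeakSelection(
        wavenumbers=result.axis[keep],
        channels=keep,
        loadings=load[keep],
        signs=np.sign(load[keep]),
        component=component,
    )
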