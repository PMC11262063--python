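"""Core in-memory containers: a single spectrum and a sample x channel set.

A :class:`Spectrum` is one Raman/SERS trace on a uniform, ascending
wavenumber axis.  A :class:`SpectraSet` is the canonical object passed
between pipeline stages: an ``n_samples x n_channels`` intensity matrix, a
shared axis, an aligned concentration table (ppm per analyte) and per-row
sample metadata (sample id, replicate index, batch label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectraSet", "check_axis"]


def check_axis(axis: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Validate a wavenumber axis: finite, strictly increasing, uniform."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 3:
        raise ValueError("axis must be 1-D with at least 3 channels")
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis contains non-finite values")
    d = np.diff(axis)
    if np.any(d <= 0):
        raise ValueError("axis must be strictly increasing")
    if np.max(np.abs(d - d[0])) > rtol * abs(d[0]):
        raise ValueError("axis must be uniformly spaced")
    return axis


@dataclass
class Spectrum:
    """One spectrum: uniform ascending axis (cm^-1) and matching intensities."""

    axis: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = check_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.axis.shape:
            raise ValueError(
                f"intensity length {self.intensities.size} != axis length {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    @property
    def spacing(self) -> float:
        return float(self.axis[1] - self.axis[0])


@dataclass
class SpectraSet:
    """A stack of spectra on a shared axis with an aligned concentration table.

    Attributes
    ----------
    axis : (n_channels,) wavenumber axis, cm^-1.
    intensities : (n_samples, n_channels) intensity matrix.
    concentrations : DataFrame, one ppm column per analyte, one row per spectrum.
    metadata : DataFrame with at least ``spectrum_id``, ``sample_id``,
        ``replicate`` and ``batch`` columns, one row per spectrum.
    clean_signal : optional (n_samples, n_channels) noiseless analyte response
        recorded by the synthetic generator (None for measured/processed data).
    processing : names of preprocessing operators already applied, in order.
    """

    axis: np.ndarray
    intensities: np.ndarray
    concentrations: pd.DataFrame
    metadata: pd.DataFrame
    clean_signal: np.ndarray | None = None
    processing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = check_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D sample x channel matrix")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError("channel count does not match axis length")
        n = self.intensities.shape[0]
        if len(self.concentrations) != n:
            raise ValueError(
                f"concentration table has {len(self.concentrations)} rows, expected {n}"
            )
        if len(self.metadata) != n:
            raise ValueError(f"metadata has {len(self.metadata)} rows, expected {n}")
        if self.concentrations.isna().any().any():
            raise ValueError("concentration table contains missing values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        self.concentrations = self.concentrations.reset_index(drop=True)
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def spacing(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def spectrum(self, i: int) -> Spectrum:
        meta = self.metadata.iloc[i].to_dict()
        meta["concentrations_ppm"] = self.concentrations.iloc[i].to_dict()
        return Spectrum(self.axis, self.intensities[i], meta)

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=self.intensities.copy(),
            concentrations=self.concentrations.copy(),
            metadata=self.metadata.copy(),
            clean_signal=None if self.clean_signal is None else self.clean_signal.copy(),
            processing=list(self.processing),
        )

    def subset(self, rows: np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows)
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=self.intensities[rows],
            concentrations=self.concentrations.iloc[rows].reset_index(drop=True),
            metadata=self.metadata.iloc[rows].reset_index(drop=True),
            clean_signal=None if self.clean_signal is None else self.clean_signal[rows],
            processing=list(self.processing),
        )
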