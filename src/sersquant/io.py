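"""CSV dialect for spectra and concentration tables.

Spectra are written wide: first column ``wavenumber_cm1``, then one column
per spectrum id.  A companion concentrations CSV is keyed by ``spectrum_id``
and carries ``sample_id``, ``replicate``, ``batch`` and one ppm column per
analyte.  The round-trip is lossless to float precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SpectraSet, check_axis

__all__ = ["write_spectra_csv", "read_spectra_csv"]

META_COLUMNS = ("spectrum_id", "sample_id", "replicate", "batch")
FLOAT_FORMAT = "%.12g"


def write_spectra_csv(sset: SpectraSet, path, concentrations_path=None) -> None:
    """Write a SpectraSet to the wide spectra CSV (and, optionally, its
    companion concentrations CSV)."""
    ids = sset.metadata["spectrum_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate spectrum ids: {dupes}")
    wide = pd.DataFrame({"wavenumber_cm1": sset.axis})
    for i, sid in enumerate(ids):
        wide[sid] = sset.intensities[i]
    wide.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if concentrations_path is not None:
        meta = sset.metadata[list(META_COLUMNS)].copy()
        conc = pd.concat([meta, sset.concentrations], axis=1)
        conc.to_csv(concentrations_path, index=False, float_format=FLOAT_FORMAT)


def read_spectra_csv(path, concentrations_path=None) -> SpectraSet:
    """Read the wide spectra CSV (plus companion concentrations, if given)
    back into a SpectraSet.

    Descending axes are accepted and re-sorted ascending with a warning;
    ragged rows, duplicate ids, missing cells and non-uniform axes are
    rejected with row/column context.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if header[0] != "wavenumber_cm1":
        raise ValueError(f"{path}: first column must be 'wavenumber_cm1', got {header[0]!r}")
    sample_ids = header[1:]
    dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids in header: {dupes}")
    wide = pd.read_csv(path)
    if wide.shape[1] != len(header):
        raise ValueError(f"{path}: ragged rows detected")
    axis = wide["wavenumber_cm1"].to_numpy(dtype=float)
    X = wide[sample_ids].to_numpy(dtype=float).T
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ValueError(
            f"{path}: missing intensity for sample {sample_ids[i]!r} "
            f"at {axis[j]:g} cm^-1"
        )
    if axis.size > 1 and axis[0] > axis[-1]:
        warnings.warn(f"{path}: descending wavenumber axis; re-sorting ascending",
                      stacklevel=2)
        order = np.argsort(axis)
        axis = axis[order]
        X = X[:, order]
    axis = check_axis(axis)

    if concentrations_path is not None:
        conc = pd.read_csv(concentrations_path)
        missing = [c for c in META_COLUMNS if c not in conc.columns]
        if missing:
            raise ValueError(f"{concentrations_path}: missing columns {missing}")
        conc = conc.set_index("spectrum_id")
        unknown = [s for s in sample_ids if s not in conc.index]
        if unknown:
            raise ValueError(
                f"{concentrations_path}: no concentration rows for spectra {unknown}"
            )
        conc = conc.loc[sample_ids].reset_index()
        meta = conc[list(META_COLUMNS)].copy()
        analyte_cols = [c for c in conc.columns if c not in META_COLUMNS]
        table = conc[analyte_cols].astype(float)
    else:
        meta = pd.DataFrame(
            {
                "spectrum_id": sample_ids,
                "sample_id": sample_ids,
                "replicate": 1,
                "batch": "unknown",
            }
        )
        table = pd.DataFrame(index=range(len(sample_ids)))
    return SpectraSet(axis=axis, intensities=X, concentrations=table, metadata=meta)
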