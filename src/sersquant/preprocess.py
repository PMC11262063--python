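"""Spectral pre-treatment operators and the three named preprocessing chains.

Chains (applied row-wise, strictly in order):

* ``pca_chain``  — AsLS baseline correction, Savitzky-Golay smoothing
  (window 11, order 2), vector normalisation.
* ``pls_chain``  — vector normalisation only.
* ``mcr_chain``  — SNV normalisation, then Savitzky-Golay first derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .types import SpectraSet

__all__ = [
    "asls_baseline",
    "savgol_smooth",
    "vector_normalize",
    "snv_normalize",
    "first_derivative",
    "PreprocessingChain",
    "pca_chain",
    "pls_chain",
    "mcr_chain",
    "apply_chain",
]


def asls_baseline(
    spectrum: np.ndarray,
    lam: float = 1e5,
    p: float = 0.001,
    max_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric-least-squares baseline (Eilers-Boelens style).

    The baseline z minimises ``sum_k w_k (y_k - z_k)^2 + lam * sum (D2 z)^2``
    with asymmetric weights ``w_k = p`` where ``y_k > z_k`` else ``1 - p``,
    iterated from uniform weights until the weight vector stops changing or
    ``max_iter`` passes.  Returns ``(baseline, spectrum - baseline)``.

    ``lam`` is expressed in units of the channel index grid (the conventional
    formulation); with the default 2 cm^-1 spacing, lam = 1e5 suppresses
    structure broader than roughly a hundred channels.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("spectrum must be 1-D with >= 3 channels")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0.0 < p < 1.0:
        raise ValueError("asymmetry p must be in (0, 1)")
    m = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(m)
    z = y
    for _ in range(max_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z, y - z


def savgol_smooth(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial of the given
    order evaluated at the window centre; edges use a polynomial fit to the
    first/last window (no padding, no fabricated signal)."""
    y = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if y.size < window:
        raise ValueError(f"spectrum shorter ({y.size}) than window ({window})")
    return savgol_filter(y, window, polyorder, mode="interp")


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm."""
    y = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("cannot vector-normalise an all-zero spectrum")
    return y / norm


def snv_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to unit sd
    (sample sd, n - 1 denominator, the chemometrics convention)."""
    y = np.asarray(spectrum, dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot SNV-normalise a constant spectrum (zero sd)")
    return (y - y.mean()) / sd


def first_derivative(
    spectrum: np.ndarray,
    axis: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky-Golay first derivative in intensity per cm^-1 (a linear ramp
    maps to its slope).  Requires a uniform axis."""
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if d.size == 0 or np.any(d <= 0) or np.max(np.abs(d - d[0])) > 1e-6 * abs(d[0]):
        raise ValueError("first_derivative requires a uniform ascending axis")
    y = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if y.size < window:
        raise ValueError(f"spectrum shorter ({y.size}) than window ({window})")
    return savgol_filter(y, window, polyorder, deriv=1, delta=float(d[0]), mode="interp")


# ---------------------------------------------------------------------------
# chains

def _op_asls(Y, axis, **kw):
    return np.vstack([asls_baseline(row, **kw)[1] for row in Y])


def _op_savgol(Y, axis, **kw):
    return np.vstack([savgol_smooth(row, **kw) for row in Y])


def _op_vecnorm(Y, axis, **kw):
    return np.vstack([vector_normalize(row) for row in Y])


def _op_snv(Y, axis, **kw):
    return np.vstack([snv_normalize(row) for row in Y])


def _op_deriv(Y, axis, **kw):
    return np.vstack([first_derivative(row, axis, **kw) for row in Y])


OPERATORS = {
    "asls": _op_asls,
    "savgol": _op_savgol,
    "vector_normalize": _op_vecnorm,
    "snv": _op_snv,
    "first_derivative": _op_deriv,
}


@dataclass
class PreprocessingChain:
    """An ordered list of (operator name, parameter dict) steps."""

    name: str = "custom"
    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for op, _ in self.steps:
            if op not in OPERATORS:
                raise ValueError(f"unknown operator {op!r}; known: {sorted(OPERATORS)}")

    def to_config(self) -> dict:
        return {"name": self.name, "steps": [[op, dict(kw)] for op, kw in self.steps]}

    @classmethod
    def from_config(cls, cfg) -> "PreprocessingChain":
        """Build from a name ('pca_chain'/'pls_chain'/'mcr_chain'/'none') or
        an explicit {name, steps} mapping."""
        if isinstance(cfg, str):
            named = {"pca_chain": pca_chain, "pls_chain": pls_chain, "mcr_chain": mcr_chain}
            if cfg in named:
                return named[cfg]()
            if cfg in ("none", "identity"):
                return cls("none", [])
            raise ValueError(f"unknown chain name {cfg!r}")
        return cls(cfg.get("name", "custom"), [(op, dict(kw)) for op, kw in cfg["steps"]])


def pca_chain(lam: float = 1e5, p: float = 0.001, window: int = 11, polyorder: int = 2) -> PreprocessingChain:
    """AsLS baseline correction + SG smoothing + vector normalisation."""
    return PreprocessingChain(
        "pca_chain",
        [
            ("asls", {"lam": lam, "p": p}),
            ("savgol", {"window": window, "polyorder": polyorder}),
            ("vector_normalize", {}),
        ],
    )


def pls_chain() -> PreprocessingChain:
    """Vector normalisation only (no further pre-processing)."""
    return PreprocessingChain("pls_chain", [("vector_normalize", {})])


def mcr_chain(window: int = 11, polyorder: int = 2) -> PreprocessingChain:
    """SNV normalisation followed by the SG first derivative."""
    return PreprocessingChain(
        "mcr_chain",
        [("snv", {}), ("first_derivative", {"window": window, "polyorder": polyorder})],
    )


def apply_chain(sset: SpectraSet, chain: PreprocessingChain) -> SpectraSet:
    """Apply a chain row-wise; the concentration table and axis are never
    altered.  Failures are re-raised with the offending sample id."""
    Y = sset.intensities
    for op, kw in chain.steps:
        fn = OPERATORS[op]
        try:
            Y = fn(Y, sset.axis, **kw)
        except Exception as exc:  # locate the failing row for the message
            for i, row in enumerate(Y):
                try:
                    fn(row[None, :], sset.axis, **kw)
                except Exception:
                    sid = sset.metadata["spectrum_id"].iloc[i]
                    raise type(exc)(f"operator {op!r} failed on spectrum {sid!r}: {exc}") from exc
            raise
    out = sset.copy()
    out.intensities = Y
    out.clean_signal = None
    out.processing = list(sset.processing) + [op for op, _ in chain.steps]
    return out
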