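"""Synthetic SERS spectrum generator for the four malodour thiols.

The study's raw spectra are not deposited, so this module emulates their
statistical structure: bilinear concentration-response mixtures of four
pure-component spectra (one dominant nu(C-S) band per thiol plus weaker
secondary bands), a fluorescence-like background (fixed low-order polynomial
profile plus a smooth seeded random component), one multiplicative intensity
factor per replicate, additive homoscedastic channel noise, a batch-level
enhancement factor for blind-test sets, and a monolayer-competition
nonlinearity above a total-concentration capacity.

The generator is bit-for-bit reproducible from its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import THIOLS, MixtureDesign, dilution_design
from .types import SpectraSet, Spectrum, check_axis

__all__ = [
    "default_axis",
    "PeakDefinition",
    "PureComponentLibrary",
    "NoiseModel",
    "default_thiol_library",
    "build_pure_spectrum",
    "simulate_mixture_set",
    "simulate_dilution_series",
    "apply_monolayer_competition",
    "apply_batch_effect",
]

#: Intensity units per ppm of a dominant nu(C-S) band (arbitrary scale).
DOMINANT_AMPLITUDE = 100.0
#: Dominant : secondary band amplitude ratio.
SECONDARY_RATIO = 3.0
DEFAULT_FWHM = 12.0

#: Dominant nu(C-S) band position per thiol (cm^-1) and secondary bands.
THIOL_BANDS: dict[str, tuple[float, tuple[float, ...]]] = {
    "3M3MH": (591.0, (926.0, 1137.0)),
    "2M3MB": (639.0, (910.0, 1089.0)),
    "3MH": (634.0, (887.0, 1107.0)),
    "2M3MP": (642.0, (706.0, 963.0, 1053.0, 1234.0)),
}


def default_axis(start: float = 200.0, stop: float = 2000.0, n_channels: int = 901) -> np.ndarray:
    """Uniform wavenumber grid, default 200-2000 cm^-1 at 2 cm^-1 spacing."""
    return np.linspace(start, stop, n_channels)


@dataclass(frozen=True)
class PeakDefinition:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), amplitude
    (intensity units per ppm) and line shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"peak at {self.center} cm^-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"peak at {self.center} cm^-1: amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"peak at {self.center} cm^-1: unknown shape {self.shape!r}")

    def validate_axis(self, axis: np.ndarray) -> None:
        if not (axis[0] <= self.center <= axis[-1]):
            raise ValueError(
                f"peak center {self.center} cm^-1 is off-axis "
                f"({axis[0]:.1f}-{axis[-1]:.1f} cm^-1)"
            )

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Band profile at unit (1 ppm) concentration; peak value = amplitude."""
        x = axis - self.center
        if self.shape == "gaussian":
            sigma = self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        gamma = self.fwhm / 2.0
        return self.amplitude * gamma**2 / (x**2 + gamma**2)


@dataclass
class PureComponentLibrary:
    """Pure-component spectra: per-analyte peak lists on a shared axis."""

    names: list[str]
    peaks: dict[str, list[PeakDefinition]]
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = check_axis(self.axis)
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        missing = [n for n in self.names if n not in self.peaks]
        if missing:
            raise ValueError(f"no peaks defined for components: {missing}")
        for name in self.names:
            for pk in self.peaks[name]:
                pk.validate_axis(self.axis)

    @property
    def n_components(self) -> int:
        return len(self.names)

    def pure_spectrum(self, name: str) -> Spectrum:
        if name not in self.peaks:
            raise KeyError(f"unknown component {name!r}; known: {self.names}")
        return build_pure_spectrum(self.peaks[name], self.axis)

    def pure_matrix(self) -> np.ndarray:
        """(n_components, n_channels) pure spectra at 1 ppm each."""
        return np.vstack([self.pure_spectrum(n).intensities for n in self.names])

    def dominant_band(self, name: str) -> PeakDefinition:
        """The highest-amplitude band of a component (the nu(C-S) band for
        the default thiol library)."""
        return max(self.peaks[name], key=lambda p: p.amplitude)


def default_thiol_library(axis: np.ndarray | None = None) -> PureComponentLibrary:
    """Default four-thiol library: dominant nu(C-S) band per thiol plus
    secondary bands at a 3:1 amplitude ratio, lorentzian, FWHM 12 cm^-1."""
    if axis is None:
        axis = default_axis()
    peaks: dict[str, list[PeakDefinition]] = {}
    for name in THIOLS:
        dom, secondary = THIOL_BANDS[name]
        plist = [PeakDefinition(dom, DEFAULT_FWHM, DOMINANT_AMPLITUDE)]
        for c in secondary:
            plist.append(
                PeakDefinition(c, DEFAULT_FWHM, DOMINANT_AMPLITUDE / SECONDARY_RATIO)
            )
        peaks[name] = plist
    return PureComponentLibrary(list(THIOLS), peaks, axis)


@dataclass(frozen=True)
class NoiseModel:
    """Noise and background parameters of a simulated measurement.

    additive_sd : homoscedastic channel noise, intensity units.
    multiplicative_sd : per-replicate intensity factor sd (dimensionless).
    baseline_amplitude : peak amplitude of the fixed background profile.
    baseline_smoothness : characteristic width of the random background, cm^-1.
    baseline_variation : sd of the random background as a fraction of
        ``baseline_amplitude``.
    seed : RNG seed; identical seed + parameters reproduce output bit-for-bit.
    """

    additive_sd: float = 1.0
    multiplicative_sd: float = 0.02
    baseline_amplitude: float = 300.0
    baseline_smoothness: float = 200.0
    baseline_variation: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_sd", "baseline_amplitude",
                     "baseline_variation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_smoothness <= 0:
            raise ValueError("baseline_smoothness must be > 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        """Fully deterministic model: no noise, no background."""
        return cls(0.0, 0.0, 0.0, 200.0, 0.0, seed)

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=seed)


def build_pure_spectrum(peaks: list[PeakDefinition], axis: np.ndarray) -> Spectrum:
    """Noise-free unit-concentration spectrum: sum of band profiles."""
    axis = check_axis(axis)
    y = np.zeros_like(axis)
    for pk in peaks:
        pk.validate_axis(axis)
        y += pk.profile(axis)
    return Spectrum(axis, y)


def _fixed_baseline(axis: np.ndarray, amplitude: float) -> np.ndarray:
    """Fluorescence-like fixed background: low-order polynomial in the
    normalised wavenumber, decreasing towards high wavenumber."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return amplitude * (1.0 - 0.55 * u + 0.15 * u**2)


def _random_baseline(axis: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Smooth seeded background component with sd
    ``baseline_variation * baseline_amplitude``."""
    sd = noise.baseline_variation * noise.baseline_amplitude
    if sd == 0:
        return np.zeros_like(axis)
    spacing = axis[1] - axis[0]
    raw = rng.standard_normal(axis.size)
    smooth = gaussian_filter1d(raw, sigma=noise.baseline_smoothness / spacing, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth * (sd / s)
    return smooth


def apply_monolayer_competition(
    concentrations: np.ndarray,
    affinities: np.ndarray | None = None,
    capacity: float = 20.0,
) -> np.ndarray:
    """Competitive surface-capacity reallocation.

    Below the total-concentration capacity the surface response is linear and
    the input is returned unchanged; above it, the effective concentrations
    are the capacity shared in proportion to affinity-weighted abundance:
    ``out_i = capacity * a_i c_i / sum_j a_j c_j``.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    if affinities is None:
        a = np.ones_like(c)
    else:
        a = np.asarray(affinities, dtype=float)
        if np.any(a <= 0):
            raise ValueError("affinities must be > 0")
    total = c.sum()
    if total <= capacity:
        return c.copy()
    w = a * c
    return capacity * w / w.sum()


def simulate_mixture_set(
    library: PureComponentLibrary,
    design: MixtureDesign,
    noise: NoiseModel,
    replicates: int = 3,
    batch: str = "train",
    signal_gain: float = 1.0,
    capacity: float | None = 20.0,
    affinities: np.ndarray | None = None,
    sample_prefix: str = "s",
) -> SpectraSet:
    """Simulate a SpectraSet from a concentration design.

    Each spectrum is ``gain * f_rep * sum_i c_eff_i * pure_i + background +
    additive noise`` where ``c_eff`` is the monolayer-competition-adjusted
    concentration vector (identity below ``capacity``), ``f_rep`` a
    per-replicate multiplicative factor and the background the fixed profile
    plus a smooth random component.  The known (nominal) concentrations are
    stored in the table; the clean analyte response is retained in
    ``clean_signal``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    missing = [a for a in design.analytes if a not in library.names]
    if missing:
        raise ValueError(f"design analytes missing from library: {missing}")
    axis = library.axis
    pures = {name: library.pure_spectrum(name).intensities for name in design.analytes}
    rng = np.random.default_rng(noise.seed)
    fixed_base = _fixed_baseline(axis, noise.baseline_amplitude)

    n_out = design.n_samples * replicates
    X = np.empty((n_out, axis.size))
    clean = np.empty_like(X)
    conc_rows, meta_rows = [], []
    row = 0
    for i in range(design.n_samples):
        c_nominal = design.concentrations.iloc[i].to_numpy(dtype=float)
        if capacity is not None:
            c_eff = apply_monolayer_competition(c_nominal, affinities, capacity)
        else:
            c_eff = c_nominal
        signal = np.zeros_like(axis)
        for a, c in zip(design.analytes, c_eff):
            if c != 0.0:
                signal = signal + c * pures[a]
        signal = signal_gain * signal
        for r in range(replicates):
            f = 1.0 + noise.multiplicative_sd * rng.standard_normal()
            base = fixed_base + _random_baseline(axis, noise, rng)
            eps = (
                noise.additive_sd * rng.standard_normal(axis.size)
                if noise.additive_sd > 0
                else 0.0
            )
            clean[row] = f * signal
            X[row] = f * signal + base + eps
            conc_rows.append(c_nominal)
            meta_rows.append(
                {
                    "spectrum_id": f"{sample_prefix}{i:03d}_r{r + 1}",
                    "sample_id": f"{sample_prefix}{i:03d}",
                    "replicate": r + 1,
                    "batch": batch,
                }
            )
            row += 1
    conc = pd.DataFrame(conc_rows, columns=design.analytes)
    meta = pd.DataFrame(meta_rows)
    return SpectraSet(axis, X, conc, meta, clean_signal=clean)


def simulate_dilution_series(
    library: PureComponentLibrary,
    analyte: str,
    concentrations,
    noise: NoiseModel,
    replicates: int = 3,
    include_blank: bool = True,
    batch: str = "lod",
) -> SpectraSet:
    """Single-analyte dilution series (with blanks) for LoD workflows."""
    if analyte not in library.names:
        raise KeyError(f"unknown analyte {analyte!r}; known: {library.names}")
    design = dilution_design(analyte, concentrations, include_blank=include_blank)
    return simulate_mixture_set(
        library, design, noise, replicates=replicates, batch=batch, sample_prefix="d"
    )


def apply_batch_effect(sset: SpectraSet, gain: float, seed: int = 0) -> SpectraSet:
    """Scale the analyte response of every spectrum by a batch-level factor
    ``1 +/- gain`` (random sign per batch, shared within a batch).

    Emulates day-to-day variation of the SERS enhancement: the factor acts on
    the analyte-response component (kept by the generator in
    ``clean_signal``), leaving background and noise untouched, so it is not
    removed by per-spectrum normalisation.  Without a stored clean signal the
    whole spectrum is scaled.  Known concentrations are unchanged.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    out = sset.copy()
    out.clean_signal = None if sset.clean_signal is None else sset.clean_signal.copy()
    if gain == 0:
        return out
    rng = np.random.default_rng(seed)
    batches = list(dict.fromkeys(out.metadata["batch"]))
    factors = {b: 1.0 + gain * rng.choice((-1.0, 1.0)) for b in batches}
    fvec = out.metadata["batch"].map(factors).to_numpy(dtype=float)[:, None]
    if out.clean_signal is not None:
        out.intensities = out.intensities + (fvec - 1.0) * out.clean_signal
        out.clean_signal = fvec * out.clean_signal
    else:
        out.intensities = fvec * out.intensities
    return out
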