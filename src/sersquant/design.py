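"""Concentration designs: Latin hypercube multiplex sets, random blind-test
sets and single-analyte dilution series.

All designs are pure functions of their parameters and seed, expressed as a
:class:`MixtureDesign` holding an ``n_samples x n_analytes`` ppm table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "THIOLS",
    "DEFAULT_RANGE_PPM",
    "PAPER_DILUTION_LEVELS_PPM",
    "MixtureDesign",
    "lhs_design",
    "random_design",
    "dilution_design",
    "paper_dilution_design",
]

#: The four axillary-malodour thiols modelled throughout the package:
#: 3-methyl-3-mercaptohexan-1-ol, 2-methyl-3-mercaptobutan-1-ol,
#: 3-mercaptohexan-1-ol and 2-methyl-3-mercaptopentan-1-ol.
THIOLS = ("3M3MH", "2M3MB", "3MH", "2M3MP")

#: Per-analyte concentration range of the multiplex calibration design, ppm.
DEFAULT_RANGE_PPM = (0.05, 1.0)

#: Ten two-fold dilutions from 3 ppm, at printed precision (ascending, ppm).
PAPER_DILUTION_LEVELS_PPM = (
    0.0058,
    0.0117,
    0.0234,
    0.0469,
    0.0938,
    0.1875,
    0.375,
    0.75,
    1.5,
    3.0,
)


def _normalize_ranges(analytes, ranges) -> dict[str, tuple[float, float]]:
    if isinstance(ranges, dict):
        out = {a: tuple(map(float, ranges[a])) for a in analytes}
    else:
        lo, hi = ranges
        out = {a: (float(lo), float(hi)) for a in analytes}
    for a, (lo, hi) in out.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"invalid concentration range {lo}..{hi} for {a}")
        if lo < 0:
            raise ValueError(f"negative concentration bound for {a}")
    return out


@dataclass
class MixtureDesign:
    """A concentration design: ppm matrix plus provenance."""

    concentrations: pd.DataFrame  # n_samples x n_analytes, ppm
    design_type: str  # lhs | random | dilution | explicit
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = self.concentrations.to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("design concentrations must be finite and >= 0")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def n_samples(self) -> int:
        return len(self.concentrations)


def lhs_design(
    n_samples: int = 120,
    analytes=THIOLS,
    ranges=DEFAULT_RANGE_PPM,
    seed: int | None = 0,
    rule: str = "uniform",
) -> MixtureDesign:
    """Latin hypercube design: per analyte, each of ``n_samples`` equal-width
    strata of [min, max] is occupied exactly once, independently permuted.

    ``rule`` places the value uniformly within its stratum (default) or at
    the stratum midpoint (``"midpoint"``).
    """
    if n_samples < 2:
        raise ValueError("LHS needs n_samples >= 2")
    if rule not in ("uniform", "midpoint"):
        raise ValueError(f"unknown LHS rule {rule!r}")
    analytes = list(analytes)
    rng_map = _normalize_ranges(analytes, ranges)
    for a, (lo, hi) in rng_map.items():
        if lo >= hi:
            raise ValueError(f"LHS range must have min < max for {a}")
    rng = np.random.default_rng(seed)
    cols = {}
    for a in analytes:
        lo, hi = rng_map[a]
        strata = rng.permutation(n_samples)
        if rule == "midpoint":
            u = np.full(n_samples, 0.5)
        else:
            u = rng.uniform(size=n_samples)
        frac = (strata + u) / n_samples
        cols[a] = lo + frac * (hi - lo)
    return MixtureDesign(pd.DataFrame(cols), "lhs", rng_map, seed)


def random_design(
    n_samples: int = 15,
    analytes=THIOLS,
    ranges=DEFAULT_RANGE_PPM,
    seed: int | None = 0,
) -> MixtureDesign:
    """I.i.d. uniform draws per cell within the per-analyte range."""
    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    analytes = list(analytes)
    rng_map = _normalize_ranges(analytes, ranges)
    rng = np.random.default_rng(seed)
    cols = {}
    for a in analytes:
        lo, hi = rng_map[a]
        cols[a] = lo + rng.uniform(size=n_samples) * (hi - lo)
    return MixtureDesign(pd.DataFrame(cols), "random", rng_map, seed)


def dilution_design(
    analyte: str,
    levels,
    include_blank: bool = True,
) -> MixtureDesign:
    """Single-analyte dilution series, optionally with a 0-ppm blank row
    prepended. Levels are sorted ascending."""
    levels = sorted(float(v) for v in levels)
    if any(v < 0 for v in levels):
        raise ValueError("dilution levels must be >= 0")
    rows = ([0.0] if include_blank else []) + levels
    df = pd.DataFrame({analyte: rows})
    lo = min(rows) if rows else 0.0
    hi = max(rows) if rows else 0.0
    return MixtureDesign(df, "dilution", {analyte: (lo, hi)}, None)


def paper_dilution_design(analyte: str, include_blank: bool = True) -> MixtureDesign:
    """The standard single-analyte LoD series: 0.0058-3 ppm two-fold steps."""
    return dilution_design(analyte, PAPER_DILUTION_LEVELS_PPM, include_blank)
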