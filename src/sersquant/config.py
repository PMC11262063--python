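"""Run configuration: every workflow is reproducible from a RunConfig plus
its root seed alone.  Configs round-trip through YAML and are echoed into
every output directory."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .design import DEFAULT_RANGE_PPM, PAPER_DILUTION_LEVELS_PPM, THIOLS

__all__ = [
    "GeneratorConfig",
    "PLSConfig",
    "LoDConfig",
    "MultiplexConfig",
    "BlindConfig",
    "MCRConfig",
    "RunConfig",
]


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class GeneratorConfig:
    axis_start: float = 200.0
    axis_stop: float = 2000.0
    n_channels: int = 901
    additive_sd: float = 1.0
    multiplicative_sd: float = 0.02
    baseline_amplitude: float = 300.0
    baseline_smoothness: float = 200.0
    baseline_variation: float = 0.06
    capacity_ppm: float = 20.0


@dataclass
class PLSConfig:
    max_candidate_lv: int = 15
    n_bootstrap: int = 1000
    max_outer_folds: int | None = 10   # folds over concentration levels
    max_inner_folds: int | None = 5
    fixed_lvs: dict | None = None      # analyte -> LV override for PLS-1
    fixed_lv_pls2: int | None = None


@dataclass
class LoDConfig:
    k: float = 3.0                     # multiplier in LoD = k * SD / m
    # The dilution series emulates a single-session acquisition: constant
    # background (no run-to-run drift) and lower channel noise than the
    # multi-day multiplex campaign.
    additive_sd: float = 0.3
    baseline_variation: float = 0.0
    half_width_cm1: float = 10.0
    n_lowest: int = 5
    max_peaks: int = 3
    min_prominence: float = 0.10
    levels_ppm: list = field(default_factory=lambda: list(PAPER_DILUTION_LEVELS_PPM))
    replicates: int = 3
    max_candidate_lv: int = 4


@dataclass
class MultiplexConfig:
    n_samples: int = 120
    replicates: int = 3
    conc_min_ppm: float = DEFAULT_RANGE_PPM[0]
    conc_max_ppm: float = DEFAULT_RANGE_PPM[1]
    analytes: list = field(default_factory=lambda: list(THIOLS))


@dataclass
class BlindConfig:
    n_samples: int = 15
    replicates: int = 3
    batch_gain: float = 0.05


@dataclass
class MCRConfig:
    tol: float = 1e-6
    max_iter: int = 100
    extra_components: int = 1          # background components beyond analytes
    # SNV rescales every spectrum by 1/sd; the recovered background
    # component carries that per-sample factor, so dividing the analyte
    # profiles by it restores a common concentration scale (internal
    # intensity standard).
    reference_correction: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pls: PLSConfig = field(default_factory=PLSConfig)
    lod: LoDConfig = field(default_factory=LoDConfig)
    multiplex: MultiplexConfig = field(default_factory=MultiplexConfig)
    blind: BlindConfig = field(default_factory=BlindConfig)
    mcr: MCRConfig = field(default_factory=MCRConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "generator": GeneratorConfig,
            "pls": PLSConfig,
            "lod": LoDConfig,
            "multiplex": MultiplexConfig,
            "blind": BlindConfig,
            "mcr": MCRConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                kwargs[key] = _from_dict(sub[key], val) if isinstance(val, dict) else val
            else:
                kwargs[key] = val
        return _from_dict(cls, kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
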