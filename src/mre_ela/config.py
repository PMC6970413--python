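"""Run configuration: validated parameter blocks for the whole pipeline.

Defaults carry the acquisition constants of the targeted protocol (900 Hz
drive, 8 dynamics per period, matrix 128 over 25 mm FOV; variable-TR array
230...7500 ms for T1 mapping).  TE and the anatomical TR are metadata only
and play no part in the computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Tuple

import yaml

from .waves import DIRECTIONS

__all__ = [
    "AcquisitionConfig",
    "FilterConfig",
    "InversionConfig",
    "SimulateConfig",
    "T1Config",
    "StatsConfig",
    "RunConfig",
]

PAPER_TR_ARRAY_MS = (230.0, 460.0, 1061.0, 1485.0, 2080.0, 3080.0, 7500.0)


@dataclass
class AcquisitionConfig:
    drive_frequency: float = 900.0   # Hz
    n_dynamics: int = 8
    matrix_size: int = 128
    fov: float = 0.025               # m
    density: float = 1000.0          # kg/m^3
    te_ms: float = 14.3              # metadata only
    tr_ms: float = 166.0             # metadata only

    def validate(self) -> None:
        if self.drive_frequency <= 0:
            raise ValueError("drive_frequency must be positive")
        if self.n_dynamics < 4:
            raise ValueError("n_dynamics must be >= 4")
        if self.matrix_size < 16:
            raise ValueError("matrix_size must be >= 16")
        if self.fov <= 0 or self.density <= 0:
            raise ValueError("fov and density must be positive")


@dataclass
class FilterConfig:
    butter_order: int = 3
    k_low: float = 0.0        # cycles/m; 0 disables the high-pass factor
    k_high: float = 2000.0    # cycles/m
    direction: str = "bottom_to_top"
    taper_width: float = 400.0  # cycles/m
    use_directional: bool = True

    def validate(self) -> None:
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if not 0 <= self.k_low < self.k_high:
            raise ValueError("need 0 <= k_low < k_high")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        if self.taper_width < 0:
            raise ValueError("taper_width must be >= 0")


@dataclass
class InversionConfig:
    laplacian_mask_threshold: float = 3.0
    stencil_correction: bool = False
    averaging: str = "complex"
    erode: int = 2
    boundary_exclusion: int = 3  # pixels dropped either side of the region junction

    def validate(self) -> None:
        if self.laplacian_mask_threshold < 0:
            raise ValueError("laplacian_mask_threshold must be >= 0")
        if self.averaging not in ("complex", "magnitude"):
            raise ValueError("averaging must be 'complex' or 'magnitude'")
        if self.erode < 0 or self.boundary_exclusion < 0:
            raise ValueError("erode and boundary_exclusion must be >= 0")


@dataclass
class SimulateConfig:
    anterior_modulus: Tuple[float, float] = (4000.0, 1200.0)   # (Re, Im) Pa
    posterior_modulus: Tuple[float, float] = (2800.0, 900.0)
    junction_frac: float = 0.5
    reflection_coefficient: float = 0.0
    noise_sd: float = 0.05
    encoding_gain: float = 2.0
    background_scale: float = 0.5
    source_edge: str = "bottom"

    def validate(self) -> None:
        for g in (self.anterior_modulus, self.posterior_modulus):
            if g[0] <= 0 or g[1] < 0:
                raise ValueError("moduli need Re > 0 and Im >= 0")
        if not 0 < self.junction_frac < 1:
            raise ValueError("junction_frac must lie in (0, 1)")
        if not 0 <= self.reflection_coefficient <= 1:
            raise ValueError("reflection_coefficient must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class T1Config:
    tr_list_ms: Tuple[float, ...] = PAPER_TR_ARRAY_MS
    model: str = "2param"

    def validate(self) -> None:
        import numpy as np

        tr = np.asarray(self.tr_list_ms, dtype=float)
        if tr.size < 3 or np.any(np.diff(tr) <= 0):
            raise ValueError("tr_list_ms must be >= 3 strictly increasing values")
        if self.model not in ("2param", "3param"):
            raise ValueError("t1 model must be '2param' or '3param'")


@dataclass
class StatsConfig:
    pairs: List[Tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("score", "gstar_abs", "spearman"),
            ("score", "gstar_real", "spearman"),
            ("score", "gstar_imag", "spearman"),
            ("score", "phi", "spearman"),
            ("delta_t1", "gstar_abs", "pearson"),
            ("si_pct", "gstar_abs", "pearson"),
            ("fold_fibronectin", "gstar_abs", "pearson"),
        ]
    )
    symptomatic_only: bool = True
    region: str = "whole"

    def validate(self) -> None:
        for p in self.pairs:
            if len(p) != 3 or p[2] not in ("spearman", "pearson"):
                raise ValueError(f"bad correlation pair {p!r}")


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    t1: T1Config = field(default_factory=T1Config)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        for block in (self.acquisition, self.filters, self.inversion, self.simulate, self.t1, self.stats):
            block.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def _load(block_cls, key):
            d = dict(raw.get(key, {}))
            for k, v in d.items():
                if k == "pairs":
                    d[k] = [tuple(p) for p in v]
                elif isinstance(v, list):
                    d[k] = tuple(tuple(e) if isinstance(e, list) else e for e in v)
            return block_cls(**d)

        cfg = cls(
            acquisition=_load(AcquisitionConfig, "acquisition"),
            filters=_load(FilterConfig, "filters"),
            inversion=_load(InversionConfig, "inversion"),
            simulate=_load(SimulateConfig, "simulate"),
            t1=_load(T1Config, "t1"),
            stats=_load(StatsConfig, "stats"),
            seed=int(raw.get("seed", 0)),
        )
        return cfg.validate()
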