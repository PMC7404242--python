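"""Simulation configuration for the synthetic screen.

All generators draw their parameters from a single :class:`SimulationConfig`
so that an entire synthetic study (tetrads, plate-reader curves, microscope
fields, morphology database) is reproducible from one seed.  Randomness is
split into named per-stage substreams via :func:`stage_rng`, so re-running a
single stage reproduces its output without replaying the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthParams",
    "ImageParams",
    "MorphdbParams",
    "SimulationConfig",
    "ConfigurationError",
    "stage_rng",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth-curve parameters.

    ``lag_min`` is the lag phase in minutes, ``max_rate_per_min`` the maximum
    specific growth rate (per minute; doubling time = ln2 / rate),
    ``carrying_capacity_od`` the saturation OD600 and ``noise_sd`` the
    additive Gaussian read noise of the plate reader.
    """

    lag_min: float = 120.0
    max_rate_per_min: float = float(np.log(2) / 100.0)
    carrying_capacity_od: float = 1.2
    initial_od: float = 0.05
    noise_sd: float = 0.01


@dataclass(frozen=True)
class ImageParams:
    """Synthetic microscope-field parameters (512-px camera sensor)."""

    width_px: int = 512
    height_px: int = 512
    n_cells: int = 25
    axis_ratio_range: tuple[float, float] = (1.0, 4.0)
    noise_sd: float = 0.02


@dataclass(frozen=True)
class MorphdbParams:
    """Morphology-database generator parameters.

    The database emulates a genome-scale deletion-collection morphology
    screen: ``n_strains`` deletion backgrounds (default matches the 4718
    haploid nonessential deletion strains of the real resource), each with
    mother-cell long/short axis measurements per cell type.  A planted subset
    of ``n_interactors`` strains, designated interaction partners of a focal
    gene, receives a shift of ``planted_shift`` on the log axis ratio.
    """

    n_strains: int = 4718
    n_interactors: int = 20
    planted_shift: float = 1.0
    base_log_ratio_mean: float = 0.25
    base_log_ratio_sd: float = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_tetrads: int = 20
    plasmid_retention: float = 0.9
    spore_viability: float = 0.98
    growth_params: GrowthParams = field(default_factory=GrowthParams)
    image_params: ImageParams = field(default_factory=ImageParams)
    morphdb_params: MorphdbParams = field(default_factory=MorphdbParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("plasmid_retention", "spore_viability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_tetrads < 1:
            raise ConfigurationError(f"n_tetrads must be >= 1, got {self.n_tetrads}")
        g = self.growth_params
        if g.noise_sd < 0:
            raise ConfigurationError(f"growth noise_sd must be >= 0, got {g.noise_sd}")
        if g.carrying_capacity_od <= 0 or g.initial_od <= 0:
            raise ConfigurationError("carrying_capacity_od and initial_od must be > 0")
        im = self.image_params
        if im.n_cells < 1 or im.width_px < 1 or im.height_px < 1:
            raise ConfigurationError("image n_cells and dimensions must be >= 1")
        if im.noise_sd < 0:
            raise ConfigurationError(f"image noise_sd must be >= 0, got {im.noise_sd}")
        lo, hi = im.axis_ratio_range
        if not (1.0 <= lo <= hi):
            raise ConfigurationError(
                f"axis_ratio_range must satisfy 1 <= lo <= hi, got {im.axis_ratio_range}"
            )
        m = self.morphdb_params
        if m.n_strains < 1:
            raise ConfigurationError(f"n_strains must be >= 1, got {m.n_strains}")
        if m.n_interactors >= m.n_strains:
            raise ConfigurationError(
                f"n_interactors ({m.n_interactors}) must be < n_strains ({m.n_strains})"
            )
        if m.base_log_ratio_sd < 0:
            raise ConfigurationError("base_log_ratio_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {
            "seed", "n_tetrads", "plasmid_retention", "spore_viability",
            "growth_params", "image_params", "morphdb_params",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        for key, klass in (
            ("growth_params", GrowthParams),
            ("image_params", ImageParams),
            ("morphdb_params", MorphdbParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "image_params" and "axis_ratio_range" in sub:
                    sub["axis_ratio_range"] = tuple(sub["axis_ratio_range"])
                d[key] = klass(**sub)
        return cls(**d)


def stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Named per-stage random substream.

    The stage name is hashed (CRC-32) into the seed sequence entropy, so each
    stage draws from an independent stream of the same master seed and can be
    re-run in isolation.
    """
    entropy: Sequence[int] = [int(seed) % (2**31), zlib.crc32(stage.encode()), *extra]
    return np.random.default_rng(np.random.SeedSequence(entropy))
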