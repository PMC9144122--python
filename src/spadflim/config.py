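"""Run configuration: every simulation and scan parameter in one record.

A ``RunConfig`` is a flat, JSON-serialisable view of the physical models
(laser pulse, fluorophore, background noise), the detector geometry, the
scan grids and the RNG seed.  Loading validates every sub-model invariant
before anything runs, and the exact configuration is serialised into every
output directory so results are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .detector import DetectorConfig
from .emission import FluorophoreModel, LaserPulseModel, NoiseModel
from .pileup_scan import SimParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # Laser pulse (plateau FWHM + exponential turn-off)
    fwhm_ns: float = 1.25
    turnoff_ns: float = 0.5
    # Fluorophore
    tau0_ns: float = 5.0
    # Background events per window (dark counts + stray light; calibrated so
    # the pile-up-free accuracy floor at 1000 counts is a few percent)
    noise_per_window: float = 0.001
    # Detector
    n_pixel: int = 1
    tres_ns: float = 0.3125
    tw_ns: float = 35.0
    nw: int = 30_000
    pileup_enabled: bool = True
    wrap_slow_photons: bool = False
    # Mean fluorescence photons per window (default: 1000 counts over nw)
    rate: float = 1000 / 30_000
    # Replicates and scan grids
    n_rep: int = 100
    pixel_counts: list[int] = field(default_factory=lambda: [1, 3, 10, 30, 100])
    rate_lo_per_pixel: float = 0.01
    rate_hi_per_pixel: float = 10.0
    points_per_decade: int = 16
    tres_factors: list[float] = field(
        default_factory=lambda: [0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0]
    )
    # Reproducibility / output
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Build every sub-model so each invariant is checked by its owner."""
        self.sim_params()
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.n_rep < 1:
            raise ValueError(f"n_rep must be >= 1, got {self.n_rep}")
        if not self.pixel_counts or any(n < 1 for n in self.pixel_counts):
            raise ValueError("pixel_counts must be a nonempty list of ints >= 1")
        if not 0 < self.rate_lo_per_pixel < self.rate_hi_per_pixel:
            raise ValueError("require 0 < rate_lo_per_pixel < rate_hi_per_pixel")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")
        if any(f <= 0 for f in self.tres_factors):
            raise ValueError("tres_factors must be positive")

    def sim_params(self) -> SimParams:
        return SimParams(
            pulse=LaserPulseModel(fwhm_ns=self.fwhm_ns, turnoff_ns=self.turnoff_ns),
            fluor=FluorophoreModel(tau0_ns=self.tau0_ns),
            noise=NoiseModel(noise_per_window=self.noise_per_window),
            detector=DetectorConfig(
                n_pixel=self.n_pixel,
                tres_ns=self.tres_ns,
                tw_ns=self.tw_ns,
                nw=self.nw,
                pileup_enabled=self.pileup_enabled,
                wrap_slow_photons=self.wrap_slow_photons,
            ),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON configuration file; an empty file yields all defaults."""
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a JSON object")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
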