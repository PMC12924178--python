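"""Machine and simulation configuration.

The constants here describe a compact synchrocyclotron pencil-beam-scanning
system of the Mevion S250i class: a nozzle-mounted range-modulator built from
18 degrader plates that realises 161 energy levels spaced 2.1 mm in
water-equivalent thickness, a 14-leaf adaptive aperture trimming each spot
within a 20 x 20 cm^2 field, and pulsed extraction capped at about 8 pC per
pulse with a 5 pC low-charge verification layer opening every beam.

Timing and noise parameters govern the synthetic log generator; every value
is overridable from YAML so alternative machines (or ablation studies) can be
expressed without code changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "TimingParams",
    "NoiseParams",
    "MachineConfig",
    "load_config",
    "save_config",
]


@dataclass
class TimingParams:
    """Deterministic inter-pulse timing model parameters (all in ms).

    The inter-pulse time is an additive composition of a base pulse period,
    spot-travel and charge-regulation terms, an aperture-move latency linear
    in the total leaf travel, and an energy-switch latency linear in the
    number of range-modulator plates repositioned.  Defaults place the three
    delivery regimes in their observed bands: same-layer pulses below 50 ms,
    aperture-only moves in 50-1000 ms, energy switches above 1000 ms.
    """

    t_base: float = 7.0            # synchrocyclotron pulse period
    t_spot_per_mm: float = 1.0     # scanning-magnet settling per mm of spot travel
    t_charge_per_pc: float = 1.0   # charge-regulation settling per pC of charge step
    t_aa_latency: float = 50.0     # fixed cost of any aperture move
    t_aa_per_mm: float = 2.0       # per mm of summed leaf travel
    t_energy_latency: float = 900.0  # fixed cost of any energy change
    t_plate: float = 120.0         # per range-modulator plate repositioned
    t_tx_extra: float = 400.0      # low-charge -> treatment transition surcharge
    t_first_extra: float = 200.0   # beam's first transition surcharge

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"timing parameter {f.name} must be >= 0")


@dataclass
class NoiseParams:
    """Heteroscedastic inter-fraction timing noise.

    Gaussian noise with standard deviation ``sigma_floor + sigma_rel * dt``
    plus a rare exponential outlier of mean ``outlier_scale`` (probability
    ``outlier_prob`` per transition), so the intrinsic fraction-to-fraction
    absolute error grows with the interval length.
    """

    sigma_floor: float = 0.5   # ms
    sigma_rel: float = 0.08    # fraction of the deterministic interval
    outlier_prob: float = 0.001
    outlier_scale: float = 300.0  # ms, mean of the outlier excess

    def __post_init__(self) -> None:
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be >= 0")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must be in [0, 1]")
        if self.outlier_scale < 0:
            raise ValueError("outlier_scale must be >= 0")


@dataclass
class MachineConfig:
    """Machine physics constants plus timing and noise sub-configurations."""

    n_plates: int = 18
    n_energy_levels: int = 161
    wet_spacing: float = 2.1        # mm water-equivalent per energy level
    max_pulse_charge: float = 8.0   # pC
    low_charge: float = 5.0         # pC, verification-layer pulse charge
    n_leaves: int = 14              # aperture leaves entering the leaf-travel sum
    field_half_extent: float = 10.0  # cm (20 x 20 cm^2 field)
    timing: TimingParams = field(default_factory=TimingParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if isinstance(self.timing, dict):
            self.timing = TimingParams(**self.timing)
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        if self.n_energy_levels < 1:
            raise ValueError("n_energy_levels must be >= 1")
        if not 0 < self.low_charge < self.max_pulse_charge:
            raise ValueError("require 0 < low_charge < max_pulse_charge")
        if self.wet_spacing <= 0:
            raise ValueError("wet_spacing must be > 0")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")

    @property
    def field_half_extent_mm(self) -> float:
        return self.field_half_extent * 10.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MachineConfig":
        return cls(**d)


def load_config(path: str | Path) -> MachineConfig:
    """Load a :class:`MachineConfig` from a YAML file (missing keys default)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return MachineConfig.from_dict(data)


def save_config(config: MachineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
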