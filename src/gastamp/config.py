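"""Run configuration for grid experiments (YAML/JSON loadable)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .capillary import PhysicalParams, SolverOptions
from .errors import ConfigError
from .geometry import Handedness
from .orientation import DEFAULT_SUPRADUCTION_DEG, Position

__all__ = ["RunConfig", "DEFAULT_DIAMETERS_MM", "DEFAULT_GAS_PERCENTS"]

#: axial diameters analysed, mm
DEFAULT_DIAMETERS_MM = (24.0, 25.0, 26.0, 31.0)
#: gas fill levels, percent of the cavity volume
DEFAULT_GAS_PERCENTS = tuple(range(100, -1, -10))


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one experimental grid."""

    diameters: tuple[float, ...] = DEFAULT_DIAMETERS_MM
    positions: tuple[Position, ...] = tuple(Position)
    gas_percents: tuple[int, ...] = DEFAULT_GAS_PERCENTS
    mode: str = "meniscus"
    supraduction_deg: float = DEFAULT_SUPRADUCTION_DEG
    handedness: Handedness = Handedness.RIGHT
    params: PhysicalParams = field(default_factory=PhysicalParams)
    options: SolverOptions = field(default_factory=SolverOptions)
    n_coverage_azimuth: int = 1024

    def __post_init__(self) -> None:
        if not self.diameters:
            raise ConfigError("no diameters listed")
        for d in self.diameters:
            if d <= 5.0:
                raise ConfigError(f"diameter {d} mm too small for a 2.5 mm truncation")
        if not self.positions:
            raise ConfigError("no positions listed")
        for g in self.gas_percents:
            if not 0 <= g <= 100:
                raise ConfigError(f"gas percent {g} outside [0, 100]")
        if self.mode not in ("flat", "meniscus"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.supraduction_deg < 90.0:
            raise ConfigError("supraduction angle must lie in [0, 90) deg")
        if self.options.mode != self.mode:
            object.__setattr__(self, "options", replace(self.options, mode=self.mode))

    @property
    def n_cells(self) -> int:
        return len(self.diameters) * len(self.positions) * len(self.gas_percents) * 4

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "positions" in d:
                d["positions"] = tuple(Position(p) for p in d["positions"])
            if "diameters" in d:
                d["diameters"] = tuple(float(x) for x in d["diameters"])
            if "gas_percents" in d:
                d["gas_percents"] = tuple(int(x) for x in d["gas_percents"])
            if "handedness" in d:
                d["handedness"] = Handedness(d["handedness"])
            if isinstance(d.get("params"), dict):
                d["params"] = PhysicalParams(**d["params"])
            opts = d.pop("options", {})
            if isinstance(opts, SolverOptions):
                d["options"] = replace(opts, mode=d.get("mode", opts.mode))
            elif opts or "mode" in d:
                opts = dict(opts)
                opts.setdefault("mode", d.get("mode", "meniscus"))
                d["options"] = SolverOptions(**opts)
            return cls(**d)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)
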