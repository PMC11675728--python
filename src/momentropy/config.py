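"""Structured run configuration with YAML round-tripping.

One flat mapping collects every free parameter of the pipeline; defaults
reproduce the published operating point (K = 10, <tau> = 3 ms, 40 Hz
units with a = -5 and beta = 1e-3, 40 s sampled at 500 Hz, four
sub-gamma bands, 5-SD threshold, minimum coalition 5, 200 ms windows
with 50% overlap).  Unknown keys are rejected rather than silently
ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .moms import DEFAULT_BANDS, BandSpec
from .simulation import SimulationParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _default_bands() -> list[dict]:
    return [{"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi} for b in DEFAULT_BANDS]


@dataclass
class RunConfig:
    # simulation (see SimulationParams for units and meaning)
    K: float = 10.0
    mean_delay: float = 0.003
    omega_hz: float = 40.0
    a: float = -5.0
    beta: float = 1e-3
    dt: float = 1e-4
    duration: float = 40.0
    transient: float = 1.0
    output_interval: float = 2e-3
    noise_mode: str = "sqrt_dt"
    normalize: str = "mean_all"
    # detection
    bands: list = field(default_factory=_default_bands)
    n_std: float = 5.0
    min_coalition: int = 5
    threshold_formula: str = "mean_plus_sd"
    # entropy
    window_length_s: float = 0.2
    overlap: float = 0.5
    phase_method: str = "complex_phase"
    lowpass_hz: float = 30.0
    # sweep grid
    K_grid: list = field(default_factory=lambda: [0.1, 10.0, 50.0])
    delay_grid: list = field(default_factory=lambda: [0.0, 0.003, 0.010])
    # synthetic connectome (used when no paths are given)
    n_nodes: int = 90
    density: float = 0.3
    connectome_seed: int = 0
    weights_path: str = ""
    distances_path: str = ""
    connectome_format: str = "delimited"
    # randomness
    master_seed: int = 0

    def band_specs(self) -> tuple[BandSpec, ...]:
        return tuple(BandSpec(b["name"], b["f_lo"], b["f_hi"]) for b in self.bands)

    def sim_params(self, seed: int | None = None, **overrides) -> SimulationParams:
        return SimulationParams(
            K=self.K,
            mean_delay=self.mean_delay,
            omega_hz=self.omega_hz,
            a=self.a,
            beta=self.beta,
            dt=self.dt,
            duration=self.duration,
            transient=self.transient,
            output_interval=self.output_interval,
            noise_mode=self.noise_mode,
            normalize=self.normalize,
            seed=self.master_seed if seed is None else seed,
            **overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)
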