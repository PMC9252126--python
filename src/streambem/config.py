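"""Run configuration: strict YAML loading with fail-fast validation.

Unknown keys are rejected so a typo in a scenario name or block key cannot
silently fall back to a default. Defaults mirror the standard study setup:
age-1 fish starting at 6.4 g on Julian day 1, realized consumption CP = 0.5,
activity multiplier RACT = 1.0, 500-set ensemble at +/-5% perturbation
validated at +/-2.5% relative length tolerance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import DEFAULT_PERTURBED_NAMES

__all__ = ["RunConfig", "load_config", "save_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleBlock:
    n_sets: int = 500
    perturb_fraction: float = 0.05
    tolerance: float = 0.025
    seed: int = 0
    perturbed_names: tuple[str, ...] = DEFAULT_PERTURBED_NAMES

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("ensemble.n_sets must be >= 1")
        if not 0 <= self.perturb_fraction < 1:
            raise ValueError("ensemble.perturb_fraction must lie in [0, 1)")
        if self.tolerance < 0:
            raise ValueError("ensemble.tolerance must be nonnegative")


@dataclass(frozen=True)
class SimulationBlock:
    initial_mass: float = 6.4
    RACT: float = 1.0
    lw_a: float = 4.83e-6
    lw_b: float = 3.191
    mass_floor: float = 0.01
    n_days: int = 365

    def __post_init__(self) -> None:
        if not self.initial_mass > 0:
            raise ValueError("simulation.initial_mass must be positive")
        if not self.RACT >= 1:
            raise ValueError("simulation.RACT must be >= 1")


@dataclass(frozen=True)
class ThermalBlock:
    lower_asymptote: float = 0.8
    upper_asymptote: float = 32.0
    inflection: float = 15.0
    steepness: float = 0.14

    def __post_init__(self) -> None:
        if not self.upper_asymptote > self.lower_asymptote:
            raise ValueError("thermal.upper_asymptote must exceed lower_asymptote")
        if not self.steepness > 0:
            raise ValueError("thermal.steepness must be positive")


@dataclass(frozen=True)
class ScenarioBlock:
    name: str
    climate_key: str
    CP: float

    def __post_init__(self) -> None:
        if not 0 <= self.CP <= 1:
            raise ValueError(f"scenario {self.name!r}: CP must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticBlock:
    n_reaches: int = 100
    base_mean_temp: float = 14.0
    lat_gradient: float = 0.7
    seasonal_amplitude: float = 7.5
    noise_sd: float = 0.5
    warming_offsets: dict = field(
        default_factory=lambda: {"rcp45": 2.4, "rcp85": 4.4}
    )
    validation_n_reaches: int = 5
    validation_n_years: int = 3


_DEFAULT_SCENARIOS = (
    ScenarioBlock("historical", "hist", 0.5),
    ScenarioBlock("rcp45", "rcp45", 0.5),
    ScenarioBlock("rcp85", "rcp85", 0.5),
    ScenarioBlock("rcp45_suppressed", "rcp45", 0.45),
    ScenarioBlock("rcp45_enhanced", "rcp45", 0.55),
)


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration."""

    seed: int = 0
    params_file: str | None = None
    reach_file: str | None = None
    out_dir: str = "out"
    ensemble: EnsembleBlock = field(default_factory=EnsembleBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    thermal: ThermalBlock = field(default_factory=ThermalBlock)
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    scenarios: tuple[ScenarioBlock, ...] = _DEFAULT_SCENARIOS


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"invalid {context}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    data = dict(raw)
    blocks = {}
    for key, cls in (
        ("ensemble", EnsembleBlock),
        ("simulation", SimulationBlock),
        ("thermal", ThermalBlock),
        ("synthetic", SyntheticBlock),
    ):
        if key in data:
            block = data.pop(key)
            if not isinstance(block, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            if key == "ensemble" and "perturbed_names" in block:
                block["perturbed_names"] = tuple(block["perturbed_names"])
            blocks[key] = _build(cls, block, f"config block {key!r}")
    if "scenarios" in data:
        raw_sc = data.pop("scenarios")
        if not isinstance(raw_sc, list) or not raw_sc:
            raise ValueError("config key 'scenarios' must be a nonempty list")
        blocks["scenarios"] = tuple(
            _build(ScenarioBlock, sc, f"scenario #{i}") for i, sc in enumerate(raw_sc)
        )
    cfg = _build(RunConfig, {**data, **blocks}, "config")
    log.info(
        "config loaded: initial_mass=%g g, RACT=%g, %d scenario(s), "
        "ensemble n=%d f=%g tol=%g seed=%d",
        cfg.simulation.initial_mass, cfg.simulation.RACT, len(cfg.scenarios),
        cfg.ensemble.n_sets, cfg.ensemble.perturb_fraction,
        cfg.ensemble.tolerance, cfg.ensemble.seed,
    )
    return cfg


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
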