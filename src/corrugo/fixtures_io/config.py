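"""Run configuration: strict YAML schema with per-key validation errors."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from ..biofilm_sim.state import STRAINS, PhysicsParams, desk_profile, reference_profile
from ..selection_fitness import FitnessProtocol
from ..well_geometry import WellSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_path"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


@dataclass
class RunConfig:
    well: WellSpec
    physics: PhysicsParams
    n_cells: int = 50
    strain_mix: dict = field(default_factory=lambda: {"neutralA": 1.0})
    protocol: Optional[FitnessProtocol] = None
    output_directory: str = "out"
    snapshot_every: float = 1.0
    seed: int = 0
    profile: str = "desk"


_WELL_KEYS = {"width_um", "height_um", "period_um", "amplitude_um", "flat"}
_POP_KEYS = {"n_cells", "strain_mix"}
_OUT_KEYS = {"directory", "snapshot_every"}
_TOP_KEYS = {"well", "physics", "population", "protocol", "output", "seed", "profile"}
_PHYS_KEYS = {f.name for f in dataclasses.fields(PhysicsParams)}


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{where}'")


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for '{key}': {msg}")


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "<top>")

    wd = raw.get("well", {})
    _reject_unknown(wd, _WELL_KEYS, "well")
    width = float(wd.get("width_um", 100.0))
    height = float(wd.get("height_um", 100.0))
    flat = bool(wd.get("flat", False))
    amplitude = float(wd.get("amplitude_um", 0.0))
    period = float(wd.get("period_um", math.inf))
    _require(width > 0, "well.width_um", "must be positive")
    _require(height > 0, "well.height_um", "must be positive")
    _require(amplitude >= 0, "well.amplitude_um", "must be nonnegative")
    if flat:
        amplitude, period = 0.0, math.inf
    elif amplitude > 0:
        _require(period > 0, "well.period_um", "must be positive when corrugated")
    try:
        well = WellSpec(width=width, height=height, period_T=period, amplitude_A=amplitude)
    except ValueError as e:
        raise ConfigError(f"invalid well geometry: {e}") from e

    profile = raw.get("profile", "desk")
    _require(profile in ("desk", "reference"), "profile",
             "must be 'desk' or 'reference'")
    phys_raw = raw.get("physics", {})
    _reject_unknown(phys_raw, _PHYS_KEYS, "physics")
    maker = desk_profile if profile == "desk" else reference_profile
    try:
        physics = maker(**phys_raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid physics section: {e}") from e

    pop = raw.get("population", {})
    _reject_unknown(pop, _POP_KEYS, "population")
    n_cells = int(pop.get("n_cells", 50))
    _require(n_cells >= 1, "population.n_cells", "must be >= 1")
    mix = pop.get("strain_mix", {"neutralA": 1.0})
    for name in mix:
        _require(name in STRAINS, f"population.strain_mix.{name}",
                 f"unknown strain; expected one of {STRAINS}")
    total = sum(float(v) for v in mix.values())
    _require(abs(total - 1.0) < 1e-9, "population.strain_mix", "fractions must sum to 1")

    protocol = None
    if raw.get("protocol"):
        phases = []
        for i, ph in enumerate(raw["protocol"]):
            _reject_unknown(ph, {"t_start_h", "multipliers"}, f"protocol[{i}]")
            _require("t_start_h" in ph and "multipliers" in ph, f"protocol[{i}]",
                     "needs t_start_h and multipliers")
            for name in ph["multipliers"]:
                _require(name in STRAINS, f"protocol[{i}].multipliers.{name}",
                         "unknown strain")
            phases.append((float(ph["t_start_h"]),
                           {k: float(v) for k, v in ph["multipliers"].items()}))
        try:
            protocol = FitnessProtocol(phases=phases)
        except ValueError as e:
            raise ConfigError(f"invalid protocol: {e}") from e

    out = raw.get("output", {})
    _reject_unknown(out, _OUT_KEYS, "output")
    return RunConfig(
        well=well,
        physics=physics,
        n_cells=n_cells,
        strain_mix={k: float(v) for k, v in mix.items()},
        protocol=protocol,
        output_directory=str(out.get("directory", "out")),
        snapshot_every=float(out.get("snapshot_every", 1.0)),
        seed=int(raw.get("seed", 0)),
        profile=profile,
    )


def default_config_path() -> Path:
    """Path of the shipped default run configuration."""
    return Path(resources.files("corrugo") / "data" / "default_run.yaml")
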