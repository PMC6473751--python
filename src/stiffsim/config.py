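"""Run-configuration parsing with explicit unit handling.

A run is described by a small YAML file; every dimensional value may be a
bare number (interpreted in the internal unit for that field) or a string
with an explicit unit tag, e.g. ``D: 3.58e-11 m^2/s`` or ``K_M: 580 uM``.
Internal units: m, s, mM (substrate), uM (enzyme), 1/s, m^2/s. Unknown
keys are rejected so typos fail loudly instead of silently falling back to
defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import constants as C
from .errors import ConfigError
from .kinetics import TABLE_KINETICS, KineticParams

__all__ = ["RunConfig", "load_config", "dump_config", "parse_quantity"]

log = logging.getLogger("stiffsim")

# conversion factors into the internal unit of each dimension
_UNIT_TABLES: dict[str, dict[str, float]] = {
    "m": {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
          "angstrom": 1e-10, "A": 1e-10},
    "s": {"s": 1.0, "min": 60.0, "h": 3600.0},
    "m^2/s": {"m^2/s": 1.0, "m2/s": 1.0, "cm^2/s": 1e-4, "mm^2/s": 1e-6,
              "um^2/s": 1e-12},
    "mM": {"mM": 1.0, "uM": 1e-3, "µM": 1e-3, "M": 1e3, "mol/m^3": 1.0},
    "uM": {"uM": 1.0, "µM": 1.0, "nM": 1e-3, "mM": 1e3},
    "1/s": {"1/s": 1.0, "/s": 1.0, "s^-1": 1.0, "1/min": 1 / 60.0},
    "kPa": {"kPa": 1.0, "Pa": 1e-3, "MPa": 1e3},
    "dimensionless": {"": 1.0},
}


def parse_quantity(value: Union[str, int, float], dimension: str,
                   key: str = "?") -> float:
    """Parse ``value`` into the internal unit of ``dimension``.

    Bare numbers pass through; strings must be ``"<number> <unit>"`` with a
    unit convertible to the internal one. Conversions are logged so unit
    surprises are visible in the run log.
    """
    table = _UNIT_TABLES.get(dimension)
    if table is None:
        raise ConfigError(f"unknown dimension {dimension!r} for key {key!r}")
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) == 1:
        try:
            return float(parts[0])
        except ValueError:
            raise ConfigError(f"cannot parse {value!r} for key {key!r}") from None
    if len(parts) != 2:
        raise ConfigError(f"expected '<number> <unit>' for key {key!r}, "
                          f"got {value!r}")
    try:
        number = float(parts[0])
    except ValueError:
        raise ConfigError(f"cannot parse number in {value!r} for key {key!r}"
                          ) from None
    unit = parts[1]
    if unit not in table:
        raise ConfigError(
            f"unit {unit!r} for key {key!r} is not convertible to "
            f"{dimension!r} (accepted: {sorted(table)})"
        )
    factor = table[unit]
    if factor != 1.0:
        log.info("config: %s = %s converted to %g %s", key, value,
                 number * factor, dimension)
    return number * factor


@dataclass
class RunConfig:
    """Validated, unit-normalized description of a coupled simulation."""

    # geometry / grid
    thickness_m: float = C.SLAB_THICKNESS_M
    dx_m: float = 10e-6
    dt_s: float = C.DEFAULT_DT_S
    horizon_s: float = 8 * 3600.0
    output_every: int = 60
    # transport
    diffusivity_m2_s: float = C.D_GEL_STIFF
    enzyme_surface_uM: float = C.DEFAULT_ENZYME_UM
    # kinetics
    kinetics: KineticParams = field(
        default_factory=lambda: TABLE_KINETICS["cygggyc"])
    # reaction
    substrate0_mM: float = C.DEFAULT_SUBSTRATE_MM
    exposure_mode: str = "integrated"
    conversion_threshold: float = 0.95
    # reproducibility
    seed: int = 0

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"] = {
            "k_cat": self.kinetics.k_cat,
            "K_M": self.kinetics.K_M,
        }
        if self.kinetics.K_i is not None:
            d["kinetics"]["K_i"] = self.kinetics.K_i
        return d


_SCALAR_KEYS = {
    # key -> (attribute, dimension)
    "thickness": ("thickness_m", "m"),
    "dx": ("dx_m", "m"),
    "dt": ("dt_s", "s"),
    "horizon": ("horizon_s", "s"),
    "D": ("diffusivity_m2_s", "m^2/s"),
    "enzyme_surface": ("enzyme_surface_uM", "uM"),
    "substrate0": ("substrate0_mM", "mM"),
}
# attribute-named aliases let a dumped config reload unchanged
_SCALAR_KEYS.update({
    "thickness_m": ("thickness_m", "m"),
    "dx_m": ("dx_m", "m"),
    "dt_s": ("dt_s", "s"),
    "horizon_s": ("horizon_s", "s"),
    "diffusivity_m2_s": ("diffusivity_m2_s", "m^2/s"),
    "enzyme_surface_uM": ("enzyme_surface_uM", "uM"),
    "substrate0_mM": ("substrate0_mM", "mM"),
})
_PLAIN_KEYS = {"output_every": int, "exposure_mode": str,
               "conversion_threshold": float, "seed": int}
_KINETIC_KEYS = {"k_cat": "1/s", "K_M": "mM", "K_i": "mM"}


def _parse_kinetics(value) -> KineticParams:
    if isinstance(value, str):
        preset = value.lower()
        if preset not in TABLE_KINETICS:
            raise ConfigError(
                f"unknown kinetics preset {value!r} "
                f"(available: {sorted(TABLE_KINETICS)})"
            )
        return TABLE_KINETICS[preset]
    if not isinstance(value, dict):
        raise ConfigError("kinetics must be a preset name or a mapping")
    unknown = set(value) - set(_KINETIC_KEYS)
    if unknown:
        raise ConfigError(f"unknown kinetics keys: {sorted(unknown)}")
    missing = {"k_cat", "K_M"} - set(value)
    if missing:
        raise ConfigError(f"kinetics mapping missing keys: {sorted(missing)}")
    parsed = {k: parse_quantity(v, _KINETIC_KEYS[k], key=f"kinetics.{k}")
              for k, v in value.items()}
    return KineticParams(parsed["k_cat"], parsed["K_M"], parsed.get("K_i"))


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    cfg = RunConfig()
    known = set(_SCALAR_KEYS) | set(_PLAIN_KEYS) | {"kinetics"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if key == "kinetics":
            cfg.kinetics = _parse_kinetics(value)
        elif key in _SCALAR_KEYS:
            attr, dim = _SCALAR_KEYS[key]
            setattr(cfg, attr, parse_quantity(value, dim, key=key))
        else:
            caster = _PLAIN_KEYS[key]
            try:
                setattr(cfg, key, caster(value))
            except (TypeError, ValueError):
                raise ConfigError(f"cannot cast {key}={value!r}") from None

    if cfg.exposure_mode not in ("integrated", "paper"):
        raise ConfigError("exposure_mode must be 'integrated' or 'paper'")
    if not 0 < cfg.conversion_threshold < 1:
        raise ConfigError("conversion_threshold must lie in (0, 1)")
    for attr in ("thickness_m", "dx_m", "dt_s", "horizon_s",
                 "diffusivity_m2_s", "enzyme_surface_uM", "substrate0_mM"):
        if getattr(cfg, attr) <= 0:
            raise ConfigError(f"{attr} must be positive")
    return cfg


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a config back to YAML; reloading yields an identical config."""
    Path(path).write_text(yaml.safe_dump(cfg.to_mapping(), sort_keys=True))
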