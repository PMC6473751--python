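"""Synthetic data generators for every fittable quantity in the package.

Each generator emulates one experimental readout of the stiffening-gel
study under its default conditions -- MBTH initial-velocity assays
(0.6 uM enzyme, substrate 0.25-10 mM), absorbance time courses, paired
swollen/dry gel masses, modulus-swelling pairs spanning G' ~1-4 kPa and
Q ~36-12, and imaged enzyme penetration profiles in a 1 mm slab. Noise is
multiplicative Gaussian (measurement error proportional to signal) unless
noted; every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .diffusion import Grid1D, SlabProblem, analytic_profile
from .errors import InvalidInputError
from .kinetics import TABLE_KINETICS, KineticParams, velocity
from .network import mass_swelling_from_volumetric

__all__ = [
    "DEFAULT_SUBSTRATE_LEVELS",
    "generate_velocity_data",
    "generate_timecourse",
    "generate_swelling_data",
    "generate_powerlaw_records",
    "generate_profile_data",
]

#: substrate design of the initial-velocity assays, mM
DEFAULT_SUBSTRATE_LEVELS = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
#: enzyme concentration of the initial-velocity assays, uM
DEFAULT_ASSAY_ENZYME_UM = 0.6


def _rng(seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_velocity_data(
    params: KineticParams = TABLE_KINETICS["cygggyc"],
    substrate_levels_mM: Sequence[float] = DEFAULT_SUBSTRATE_LEVELS,
    enzyme_uM: float = DEFAULT_ASSAY_ENZYME_UM,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    substrate_label: str = "synthetic",
) -> pd.DataFrame:
    """Initial-velocity observations V_P = v(C_S, C_E) * (1 + eps).

    eps ~ Normal(0, noise_sd), independently per observation; velocities
    are truncated at zero. Columns match the velocity CSV interface:
    ``substrate, C_S_mM, C_E_uM, V_P_uM_per_s, replicate``.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise sd must be non-negative")
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    rng = _rng(seed)
    cs = np.asarray(list(substrate_levels_mM), dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        v_true = np.asarray(velocity(params, cs, enzyme_uM), dtype=float)
        eps = rng.normal(0.0, noise_sd, size=cs.size) if noise_sd > 0 else 0.0
        v_obs = np.maximum(v_true * (1.0 + eps), 0.0)
        for c, v in zip(cs, v_obs):
            rows.append((substrate_label, c, enzyme_uM, v, rep))
    return pd.DataFrame(
        rows, columns=["substrate", "C_S_mM", "C_E_uM", "V_P_uM_per_s",
                       "replicate"],
    )


def generate_timecourse(
    initial_rate_au_s: float,
    saturation_au: Optional[float] = None,
    duration_s: float = 360.0,
    dt_s: float = 10.0,
    noise_sd_au: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Absorbance time course with a linear start.

    With ``saturation_au`` set, the signal is the saturating exponential
    A_inf * (1 - exp(-t / tau)) with tau chosen so the initial slope equals
    ``initial_rate_au_s``; otherwise the signal is exactly linear. Additive
    Gaussian noise in absorbance units. Columns: ``t_s, absorbance``.
    """
    if noise_sd_au < 0:
        raise InvalidInputError("noise sd must be non-negative")
    rng = _rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    if saturation_au is None:
        signal = initial_rate_au_s * t
    else:
        tau = saturation_au / initial_rate_au_s
        signal = saturation_au * (1.0 - np.exp(-t / tau))
    if noise_sd_au > 0:
        signal = signal + rng.normal(0.0, noise_sd_au, size=t.size)
    return pd.DataFrame({"t_s": t, "absorbance": signal})


def generate_swelling_data(
    Q_values: Sequence[float] = (30.0, 24.0, 18.0),
    dry_mass_mg: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Paired swollen/dry masses whose volumetric ratios equal ``Q_values``.

    Multiplicative noise on the swollen mass only. Columns match the
    swelling CSV interface: ``sample_id, swollen_mass_mg, dry_mass_mg``.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise sd must be non-negative")
    rng = _rng(seed)
    rows = []
    for i, Q in enumerate(Q_values, start=1):
        q = mass_swelling_from_volumetric(Q)
        swollen = dry_mass_mg * q
        if noise_sd > 0:
            swollen = max(swollen * (1.0 + rng.normal(0.0, noise_sd)),
                          dry_mass_mg)
        rows.append((f"gel-{i:02d}", swollen, dry_mass_mg))
    return pd.DataFrame(rows, columns=["sample_id", "swollen_mass_mg",
                                       "dry_mass_mg"])


def generate_powerlaw_records(
    prefactor_kpa: float = 500.0,
    exponent: float = 1.95,
    n_points: int = 8,
    Q_range: tuple[float, float] = (36.0, 12.0),
    enzyme_range_uM: tuple[float, float] = (0.0, 3.0),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Modulus-swelling pairs on an exact power law G' = A * (1/Q)^m.

    The default span covers the stiffening study's ranges (Q from ~36 down
    to ~12 as the enzyme dose rises, moduli of order 0.5-4 kPa).
    Multiplicative Gaussian noise on G'. Columns:
    ``Tyrase_uM, G_prime_kPa, Q``.
    """
    if n_points < 3:
        raise InvalidInputError("need at least 3 records")
    if noise_sd < 0:
        raise InvalidInputError("noise sd must be non-negative")
    rng = _rng(seed)
    Q = np.linspace(Q_range[0], Q_range[1], n_points)
    nu = 1.0 / Q
    g = prefactor_kpa * nu**exponent
    if noise_sd > 0:
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=n_points))
    dose = np.linspace(enzyme_range_uM[0], enzyme_range_uM[1], n_points)
    return pd.DataFrame({"Tyrase_uM": dose, "G_prime_kPa": g, "Q": Q})


def generate_profile_data(
    diffusivity: float = C.D_GEL_STIFF,
    thickness_m: float = C.SLAB_THICKNESS_M,
    surface_concentration: float = 1.0,
    times_h: Sequence[float] = (1.0, 3.0, 6.0),
    n_positions: int = 21,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Imaged enzyme penetration profiles at selected times.

    Analytic-series concentrations sampled across the slab with additive
    Gaussian noise (sd expressed as a fraction of the surface
    concentration). Columns: ``x_mm, t_h, C_over_C0``.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise sd must be non-negative")
    rng = _rng(seed)
    problem = SlabProblem(thickness_m=thickness_m, diffusivity=diffusivity,
                          surface_concentration=surface_concentration)
    x = np.linspace(0.0, thickness_m, n_positions)
    rows = []
    for th in times_h:
        c = np.asarray(analytic_profile(problem, x, th * 3600.0))
        ratio = c / surface_concentration
        if noise_sd > 0:
            ratio = ratio + rng.normal(0.0, noise_sd, size=x.size)
        for xi, ri in zip(x, ratio):
            rows.append((xi * 1e3, th, ri))
    return pd.DataFrame(rows, columns=["x_mm", "t_h", "C_over_C0"])
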