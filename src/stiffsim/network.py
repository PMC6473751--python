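"""Hydrogel network structure and solute transport descriptors.

Maps swelling measurements of a step-growth PEG-peptide hydrogel to its
structural state -- mass (q) and volumetric (Q) swelling ratios, polymer
volume fraction nu_2s = 1/Q, average molecular weight between crosslinks
M_c, and mesh size xi -- and from there to the in-gel diffusivity of a
solute via the Lustig-Peppas free-volume/obstruction relation

    D_gel = D_sol * (1 - R_E/xi) * exp(-Y / (Q - 1)).

Mesh size follows the Canal-Peppas form

    xi = Q^(1/3) * l * sqrt(3 * C_n * M_c / M_r)

with l the backbone bond length, C_n the Flory characteristic ratio and
M_r the repeat-unit molar mass (44 g/mol for PEG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import constants as C
from .errors import (
    ExtrapolationWarning,
    InvalidInputError,
    InvalidMeasurementError,
    MissingCalibrationError,
    NoTransportWarning,
    UnknownResidueError,
)

__all__ = [
    "MacromerSpec",
    "CrosslinkerSpec",
    "SwellingMeasurement",
    "GelState",
    "TransportSpec",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "mass_swelling_ratio",
    "volumetric_swelling_ratio",
    "mass_swelling_from_volumetric",
    "crosslinker_mw_from_sequence",
    "mw_between_crosslinks",
    "mesh_size",
    "lustig_peppas_diffusivity",
    "gel_state_from_calibration",
    "gel_state_from_swelling",
]

# Average (isotope-weighted) residue masses of the 20 standard amino acids,
# g/mol; a residue is the amino acid minus one water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.015


@dataclass(frozen=True)
class MacromerSpec:
    """Multi-arm macromer (default: 8-arm PEG-norbornene, 20 kDa)."""

    number_average_mw: float = C.PEG8NB_MW      # g/mol
    arm_functionality: int = C.PEG8NB_ARMS
    repeat_unit_mw: float = C.PEG_REPEAT_UNIT_MW  # g/mol
    polymer_density: float = C.PEG_DENSITY        # g/cm^3

    def __post_init__(self) -> None:
        if self.number_average_mw <= 0 or self.repeat_unit_mw <= 0:
            raise InvalidInputError("macromer molar masses must be positive")
        if self.polymer_density <= 0:
            raise InvalidInputError("polymer density must be positive")
        if self.arm_functionality < 2:
            raise InvalidInputError("arm functionality must be >= 2")


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Bifunctional (or higher) crosslinker, optionally defined by sequence."""

    molecular_weight: float                      # g/mol
    functionality: int = C.PEPTIDE_FUNCTIONALITY
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise InvalidInputError("crosslinker molecular weight must be positive")
        if self.functionality < 2:
            raise InvalidInputError("crosslinker functionality must be >= 2")
        if self.sequence is not None:
            expected = crosslinker_mw_from_sequence(self.sequence)
            if abs(expected - self.molecular_weight) > 0.1:
                raise InvalidInputError(
                    f"molecular_weight {self.molecular_weight} does not match "
                    f"sequence-derived mass {expected:.3f} (tolerance 0.1 g/mol)"
                )

    @classmethod
    def from_sequence(cls, sequence: str, functionality: int = C.PEPTIDE_FUNCTIONALITY
                      ) -> "CrosslinkerSpec":
        return cls(crosslinker_mw_from_sequence(sequence), functionality, sequence)


@dataclass(frozen=True)
class SwellingMeasurement:
    """Paired swollen/dry gel masses (grams, or any consistent mass unit)."""

    swollen_mass: float
    dry_mass: float
    water_density: float = C.WATER_DENSITY

    def __post_init__(self) -> None:
        if self.dry_mass <= 0:
            raise InvalidMeasurementError("dry mass must be positive")
        if self.swollen_mass < self.dry_mass:
            raise InvalidMeasurementError("swollen mass must be >= dry mass")
        if self.water_density <= 0:
            raise InvalidMeasurementError("water density must be positive")


@dataclass(frozen=True)
class GelState:
    """Derived structural state of a swollen hydrogel."""

    volumetric_swelling_ratio: float             # Q
    mesh_size_nm: float                          # xi
    mass_swelling_ratio: Optional[float] = None  # q
    mw_between_crosslinks: Optional[float] = None  # g/mol
    shear_modulus_kpa: Optional[float] = None    # G'
    polymer_volume_fraction: float = field(init=False)  # nu_2s = 1/Q

    def __post_init__(self) -> None:
        if self.volumetric_swelling_ratio < 1:
            raise InvalidInputError("volumetric swelling ratio Q must be >= 1")
        if self.mesh_size_nm <= 0:
            raise InvalidInputError("mesh size must be positive")
        if self.mass_swelling_ratio is not None and self.mass_swelling_ratio < 1:
            raise InvalidInputError("mass swelling ratio q must be >= 1")
        object.__setattr__(
            self, "polymer_volume_fraction", 1.0 / self.volumetric_swelling_ratio
        )


@dataclass(frozen=True)
class TransportSpec:
    """Solute transport parameters for the Lustig-Peppas relation."""

    solution_diffusivity: float = C.TYROSINASE_D_SOLUTION  # m^2/s
    hydrodynamic_radius_nm: float = C.TYROSINASE_RADIUS_NM
    free_volume_parameter: float = C.FREE_VOLUME_Y

    def __post_init__(self) -> None:
        if self.solution_diffusivity <= 0:
            raise InvalidInputError("solution diffusivity must be positive")
        if self.hydrodynamic_radius_nm <= 0:
            raise InvalidInputError("hydrodynamic radius must be positive")
        if self.free_volume_parameter <= 0:
            raise InvalidInputError("free-volume parameter must be positive")


def mass_swelling_ratio(m: SwellingMeasurement) -> float:
    """Mass swelling ratio q = m_swollen / m_dry."""
    return m.swollen_mass / m.dry_mass


def volumetric_swelling_ratio(
    q: float,
    polymer_density: float = C.PEG_DENSITY,
    water_density: float = C.WATER_DENSITY,
) -> float:
    """Volumetric swelling ratio from the mass ratio by volume additivity.

    Q = 1 + (rho_polymer / rho_water) * (q - 1): the absorbed water mass
    (q - 1 per unit dry mass) converted to volume relative to the dry
    polymer volume.
    """
    if q < 1:
        raise InvalidInputError("mass swelling ratio q must be >= 1")
    if polymer_density <= 0 or water_density <= 0:
        raise InvalidInputError("densities must be positive")
    return 1.0 + (polymer_density / water_density) * (q - 1.0)


def mass_swelling_from_volumetric(
    Q: float,
    polymer_density: float = C.PEG_DENSITY,
    water_density: float = C.WATER_DENSITY,
) -> float:
    """Inverse of :func:`volumetric_swelling_ratio`."""
    if Q < 1:
        raise InvalidInputError("volumetric swelling ratio Q must be >= 1")
    return 1.0 + (water_density / polymer_density) * (Q - 1.0)


def crosslinker_mw_from_sequence(sequence: str) -> float:
    """Average molar mass of a peptide: sum of residue masses plus one water."""
    if not sequence:
        raise UnknownResidueError("empty peptide sequence")
    total = WATER_MASS
    for letter in sequence.upper():
        try:
            total += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {letter!r} in sequence {sequence!r}"
            ) from None
    return total


def mw_between_crosslinks(macromer: MacromerSpec, crosslinker: CrosslinkerSpec) -> float:
    """Average molecular weight between crosslinks of an ideal step-growth net.

    M_c = 2 * (MW_A / f_A + MW_B / f_B): each elastically effective strand
    carries one macromer arm and one crosslinker half, counted twice for the
    two chain ends.
    """
    return 2.0 * (
        macromer.number_average_mw / macromer.arm_functionality
        + crosslinker.molecular_weight / crosslinker.functionality
    )


def mesh_size(
    Q: float,
    bond_length_angstrom: float = C.BOND_LENGTH_ANGSTROM,
    flory_ratio: float = C.FLORY_RATIO_PEG,
    mc: float = 5721.8,
    repeat_unit_mw: float = C.PEG_REPEAT_UNIT_MW,
) -> float:
    """Mesh size xi (nm) from the swollen-state Canal-Peppas relation.

    xi = Q^(1/3) * l * sqrt(3 * C_n * M_c / M_r), evaluated in Angstrom and
    returned in nm. 3 is the number of backbone bonds per repeat unit.
    """
    if Q <= 0 or mc <= 0:
        raise InvalidInputError("Q and M_c must be positive")
    if bond_length_angstrom <= 0 or flory_ratio <= 0 or repeat_unit_mw <= 0:
        raise InvalidInputError("structural constants must be positive")
    n_links = C.BONDS_PER_REPEAT * flory_ratio * mc / repeat_unit_mw
    xi_angstrom = Q ** (1.0 / 3.0) * bond_length_angstrom * np.sqrt(n_links)
    return xi_angstrom / 10.0


def lustig_peppas_diffusivity(
    transport: TransportSpec, mesh_size_nm: float, Q: float
) -> float:
    """In-gel solute diffusivity (m^2/s) from mesh size and swelling.

    D_gel = D_sol * (1 - R_E/xi) * exp(-Y / (Q - 1)). Returns 0 (with a
    :class:`NoTransportWarning`) when the solute radius meets or exceeds the
    mesh size: the solute is sterically excluded from the network.
    """
    if mesh_size_nm <= 0:
        raise InvalidInputError("mesh size must be positive")
    if Q <= 1:
        raise InvalidInputError("Lustig-Peppas requires a swollen gel (Q > 1)")
    if transport.hydrodynamic_radius_nm >= mesh_size_nm:
        warnings.warn(
            "solute radius >= mesh size: no transport", NoTransportWarning,
            stacklevel=2,
        )
        return 0.0
    obstruction = 1.0 - transport.hydrodynamic_radius_nm / mesh_size_nm
    free_volume = np.exp(-transport.free_volume_parameter / (Q - 1.0))
    return transport.solution_diffusivity * obstruction * free_volume


def gel_state_from_swelling(
    m: SwellingMeasurement,
    macromer: MacromerSpec | None = None,
    crosslinker: CrosslinkerSpec | None = None,
    shear_modulus_kpa: Optional[float] = None,
) -> GelState:
    """Full structural chain: masses -> q -> Q -> M_c -> xi -> GelState."""
    macromer = macromer or MacromerSpec()
    crosslinker = crosslinker or CrosslinkerSpec.from_sequence("CYGGGYC")
    q = mass_swelling_ratio(m)
    Q = volumetric_swelling_ratio(q, macromer.polymer_density, m.water_density)
    mc = mw_between_crosslinks(macromer, crosslinker)
    xi = mesh_size(Q, mc=mc, repeat_unit_mw=macromer.repeat_unit_mw)
    return GelState(
        volumetric_swelling_ratio=Q,
        mesh_size_nm=xi,
        mass_swelling_ratio=q,
        mw_between_crosslinks=mc,
        shear_modulus_kpa=shear_modulus_kpa,
    )


def gel_state_from_calibration(
    shear_modulus_kpa: float,
    calibration_table: Sequence[tuple[float, float, float]],
) -> GelState:
    """Interpolate (Q, xi) from an empirical (G', Q, xi) calibration table.

    Linear interpolation in G'; queries outside the table are clamped to the
    nearest end row with an :class:`ExtrapolationWarning`.
    """
    if not calibration_table:
        raise MissingCalibrationError("calibration table is empty")
    if len(calibration_table) < 2:
        raise MissingCalibrationError("calibration table needs >= 2 rows")
    table = sorted(calibration_table, key=lambda row: row[0])
    g = np.array([row[0] for row in table], dtype=float)
    if np.any(np.diff(g) <= 0):
        raise MissingCalibrationError("calibration table must be monotone in G'")
    if shear_modulus_kpa < g[0] or shear_modulus_kpa > g[-1]:
        warnings.warn(
            f"G' = {shear_modulus_kpa} kPa outside calibration range "
            f"[{g[0]}, {g[-1]}]; clamped to nearest row",
            ExtrapolationWarning,
            stacklevel=2,
        )
    Q = float(np.interp(shear_modulus_kpa, g, [row[1] for row in table]))
    xi = float(np.interp(shear_modulus_kpa, g, [row[2] for row in table]))
    return GelState(
        volumetric_swelling_ratio=Q,
        mesh_size_nm=xi,
        shear_modulus_kpa=shear_modulus_kpa,
    )
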