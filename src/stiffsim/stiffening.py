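"""Structure-property scaling of stiffened hydrogels.

Rubber elasticity theory predicts the shear modulus of an ideal network to
scale linearly with its polymer volume fraction nu_2s (= 1/Q). Real
step-growth and enzymatically stiffened networks deviate: fitting

    G' = A * nu_2s ** m

by ordinary least squares on (ln nu_2s, ln G') quantifies the deviation,
with m = 1 the ideal reference and larger exponents indicating network
non-ideality (dangling ends, loops, heterogeneous secondary crosslinking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, InvalidInputError

__all__ = [
    "ModulusSwellingRecord",
    "PowerLawFit",
    "ModulusSwellingPowerLaw",
    "fit_power_law",
    "ideality_assessment",
]

#: exponent band treated as consistent with ideal rubber elasticity
IDEAL_EXPONENT_BAND = (0.8, 1.2)


@dataclass(frozen=True)
class ModulusSwellingRecord:
    """One (G', Q) observation of a swollen gel, e.g. after stiffening."""

    shear_modulus_kpa: float
    volumetric_swelling_ratio: float
    enzyme_uM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shear_modulus_kpa <= 0:
            raise InvalidInputError("shear modulus must be positive")
        if self.volumetric_swelling_ratio < 1:
            raise InvalidInputError("volumetric swelling ratio must be >= 1")

    @property
    def polymer_volume_fraction(self) -> float:
        return 1.0 / self.volumetric_swelling_ratio


class PowerLawFit:
    """Results of the log-log modulus-swelling regression.

    Attributes
    ----------
    prefactor : float
        A in G' = A * nu_2s^m, in the modulus unit of the input.
    exponent : float
        Scaling exponent m (ideal rubber elasticity: 1).
    rsquared : float
        R^2 of the straight-line fit in log-log space.
    bse : dict
        Standard errors of exponent and log-prefactor.
    """

    def __init__(self, prefactor: float, exponent: float, rsquared: float,
                 bse: dict, n_points: int) -> None:
        self.prefactor = float(prefactor)
        self.exponent = float(exponent)
        self.rsquared = float(rsquared)
        self.bse = bse
        self.n_points = int(n_points)

    def predict(self, polymer_volume_fraction) -> np.ndarray | float:
        nu = np.asarray(polymer_volume_fraction, dtype=float)
        out = self.prefactor * nu**self.exponent
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "prefactor_kPa": self.prefactor,
            "exponent": self.exponent,
            "r_squared": self.rsquared,
            "n_points": self.n_points,
            "stderr": dict(self.bse),
        }

    def summary(self) -> str:
        assessment = ideality_assessment(self)
        se = self.bse.get("exponent", float("nan"))
        return "\n".join([
            "Modulus-swelling power law  G' = A * nu^m",
            "=" * 46,
            f"n points:   {self.n_points}",
            f"exponent m: {self.exponent:.4g} +/- {se:.2g}",
            f"prefactor:  {self.prefactor:.4g} kPa",
            f"R-squared:  {self.rsquared:.4f}",
            f"assessment: {assessment['label']} "
            f"(deviation from 1: {assessment['deviation']:+.3g})",
            "=" * 46,
        ])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PowerLawFit exponent={self.exponent:.4g} "
                f"prefactor={self.prefactor:.4g} R2={self.rsquared:.4f}>")


class ModulusSwellingPowerLaw:
    """Power-law scaling model between shear modulus and volume fraction.

    Built from arrays, records or a DataFrame; :meth:`fit` performs OLS on
    the log-transformed data (appropriate for multiplicative measurement
    error) and returns a :class:`PowerLawFit`.
    """

    def __init__(self, shear_modulus_kpa, polymer_volume_fraction) -> None:
        self.g = np.asarray(shear_modulus_kpa, dtype=float)
        self.nu = np.asarray(polymer_volume_fraction, dtype=float)
        if self.g.shape != self.nu.shape:
            raise InvalidInputError("modulus and volume fraction must align")
        if np.any(self.g <= 0) or np.any(self.nu <= 0):
            raise InvalidInputError("modulus and volume fraction must be positive")

    @classmethod
    def from_records(cls, records: Iterable[ModulusSwellingRecord]
                     ) -> "ModulusSwellingPowerLaw":
        records = list(records)
        return cls([r.shear_modulus_kpa for r in records],
                   [r.polymer_volume_fraction for r in records])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       modulus_col: str = "G_prime_kPa",
                       swelling_col: str = "Q") -> "ModulusSwellingPowerLaw":
        return cls(df[modulus_col], 1.0 / df[swelling_col])

    def fit(self) -> PowerLawFit:
        if np.unique(self.nu).size < 3:
            raise DesignError(
                "power-law fit needs >= 3 records with distinct volume "
                "fractions"
            )
        x, y = np.log(self.nu), np.log(self.g)
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        n = x.size
        sxx = float(np.sum((x - x.mean()) ** 2))
        if n > 2 and sxx > 0:
            s2 = ss_res / (n - 2)
            se_slope = float(np.sqrt(s2 / sxx))
            se_inter = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))
        else:
            se_slope = se_inter = float("nan")
        bse = {"exponent": se_slope, "log_prefactor": se_inter}
        return PowerLawFit(np.exp(intercept), slope, r2, bse, self.g.size)


def fit_power_law(
    records: Sequence[ModulusSwellingRecord] | pd.DataFrame,
) -> PowerLawFit:
    """Fit G' = A * nu_2s^m to modulus-swelling records (functional door)."""
    if isinstance(records, pd.DataFrame):
        mdl = ModulusSwellingPowerLaw.from_dataframe(records)
    else:
        mdl = ModulusSwellingPowerLaw.from_records(records)
    return mdl.fit()


def ideality_assessment(fit: PowerLawFit) -> dict:
    """Classify the network against the ideal rubber-elasticity exponent.

    Exponents within ``IDEAL_EXPONENT_BAND`` are labelled ``ideal-like``;
    larger are ``non-ideal (super-linear)``, smaller ``non-ideal
    (sub-linear)``. Returns the label, the exponent and its deviation
    from 1.
    """
    lo, hi = IDEAL_EXPONENT_BAND
    m = fit.exponent
    if lo <= m <= hi:
        label = "ideal-like"
    elif m > hi:
        label = "non-ideal (super-linear)"
    else:
        label = "non-ideal (sub-linear)"
    return {"label": label, "exponent": m, "deviation": m - 1.0}
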