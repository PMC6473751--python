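"""Michaelis-Menten kinetics of tyrosinase-mediated phenol oxidation.

Rate laws
---------
Standard saturable kinetics for product formation,

    V_P = k_cat * C_E * C_S / (K_M + C_S),

and the substrate-inhibited variant

    V_P = k_cat * C_E * C_S / (K_M + C_S * (1 + C_S / K_i)),

which is unimodal in C_S with an interior maximum at C_S = sqrt(K_M * K_i).
When C_S >> K_M both collapse to velocity laws linear in enzyme
concentration (V_P = k_cat * C_E, damped by 1/(1 + C_S/K_i) under
inhibition).

Fitting is exposed statsmodels-style: :class:`MichaelisMentenModel` is
constructed from observed (C_S, C_E, V_P) points and its :meth:`fit`
returns a :class:`KineticFitResults` carrying estimates, standard errors,
R^2 and a ``summary()`` table. Units throughout: C_S and K_M in mM, C_E in
uM, velocities in uM/s, k_cat in 1/s, time in s.

The integrated form of the standard law,

    k_cat * C_E * t = K_M * ln(C_S0 / C_S) + (C_S0 - C_S),

gives the exact time to reach any conversion in a well-mixed reaction and
underlies the conversion-time estimates for gel stiffening design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    FitError,
    InvalidInputError,
    LinearRangeWarning,
)

__all__ = [
    "KineticParams",
    "VelocityObservation",
    "TimeCourse",
    "KineticFitResults",
    "MichaelisMentenModel",
    "TABLE_KINETICS",
    "mm_velocity",
    "mm_inhibited_velocity",
    "velocity",
    "linear_limit_velocity",
    "inhibition_optimum",
    "velocity_from_timecourse",
    "fit_kinetics",
    "integrated_mm_time",
    "conversion_time_surface",
]


@dataclass(frozen=True)
class KineticParams:
    """Catalytic constants: k_cat (1/s), K_M (mM), optional K_i (mM)."""

    k_cat: float
    K_M: float
    K_i: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k_cat <= 0:
            raise InvalidInputError("k_cat must be positive")
        if self.K_M <= 0:
            raise InvalidInputError("K_M must be positive")
        if self.K_i is not None and self.K_i <= 0:
            raise InvalidInputError("K_i must be positive when present")

    @property
    def substrate_inhibited(self) -> bool:
        return self.K_i is not None


#: Fitted constants for mushroom tyrosinase with its three phenolic
#: substrates; only free L-tyrosine shows measurable substrate inhibition.
TABLE_KINETICS: dict[str, KineticParams] = {
    "l-tyr": KineticParams(k_cat=0.93, K_M=0.85, K_i=19.85),
    "l-dopa": KineticParams(k_cat=8.63, K_M=1.02),
    "cygggyc": KineticParams(k_cat=0.60, K_M=0.58),
}


@dataclass(frozen=True)
class VelocityObservation:
    """One initial-velocity point: C_S (mM), C_E (uM), V_P (uM/s)."""

    substrate_mM: float
    enzyme_uM: float
    velocity_uM_s: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.substrate_mM < 0 or self.enzyme_uM < 0:
            raise InvalidInputError("concentrations must be non-negative")
        if self.velocity_uM_s < 0:
            raise InvalidInputError("velocity must be non-negative")


@dataclass(frozen=True)
class TimeCourse:
    """Assay time course: absorbance signal vs time with a calibration.

    ``calibration_mM_per_au`` converts the absorbance slope (AU/s) to a
    product-formation velocity (mM/s == uM/s after the 1e3 factor applied
    by the caller choosing units; here the factor is taken as uM per AU so
    slopes come out in uM/s).
    """

    times_s: np.ndarray
    signal: np.ndarray
    calibration_uM_per_au: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.times_s.size < 3:
            raise InvalidInputError("time course needs at least 3 points")
        if self.times_s.size != self.signal.size:
            raise InvalidInputError("times and signal must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.calibration_uM_per_au <= 0:
            raise InvalidInputError("calibration factor must be positive")


def mm_velocity(params: KineticParams, substrate_mM, enzyme_uM) -> np.ndarray | float:
    """Standard Michaelis-Menten velocity V_P (uM/s); ignores any K_i."""
    cs = np.asarray(substrate_mM, dtype=float)
    ce = np.asarray(enzyme_uM, dtype=float)
    if np.any(cs < 0) or np.any(ce < 0):
        raise InvalidInputError("concentrations must be non-negative")
    v = params.k_cat * ce * cs / (params.K_M + cs)
    return float(v) if np.isscalar(substrate_mM) and np.isscalar(enzyme_uM) else v


def mm_inhibited_velocity(params: KineticParams, substrate_mM, enzyme_uM
                          ) -> np.ndarray | float:
    """Substrate-inhibited velocity V_P (uM/s); requires K_i."""
    if params.K_i is None:
        raise InvalidInputError("substrate-inhibited law requires K_i")
    cs = np.asarray(substrate_mM, dtype=float)
    ce = np.asarray(enzyme_uM, dtype=float)
    if np.any(cs < 0) or np.any(ce < 0):
        raise InvalidInputError("concentrations must be non-negative")
    v = params.k_cat * ce * cs / (params.K_M + cs * (1.0 + cs / params.K_i))
    return float(v) if np.isscalar(substrate_mM) and np.isscalar(enzyme_uM) else v


def velocity(params: KineticParams, substrate_mM, enzyme_uM) -> np.ndarray | float:
    """Dispatch to the inhibited law when K_i is present, else standard."""
    if params.substrate_inhibited:
        return mm_inhibited_velocity(params, substrate_mM, enzyme_uM)
    return mm_velocity(params, substrate_mM, enzyme_uM)


def inhibition_optimum(params: KineticParams) -> float:
    """Substrate concentration (mM) maximizing the inhibited velocity.

    dV/dC_S = 0 at C_S = sqrt(K_M * K_i).
    """
    if params.K_i is None:
        raise InvalidInputError("no interior optimum without substrate inhibition")
    return float(np.sqrt(params.K_M * params.K_i))


def linear_limit_velocity(params: KineticParams, enzyme_uM, substrate_mM
                          ) -> np.ndarray | float:
    """High-substrate linearized velocity (uM/s), linear in C_E.

    With C_S >> K_M the saturable denominator loses its K_M term:
    V_P = k_cat * C_E without inhibition, or k_cat * C_E / (1 + C_S/K_i)
    with it. Warns when C_S < 10 * K_M, where the linearization is crude.
    """
    cs = np.asarray(substrate_mM, dtype=float)
    ce = np.asarray(enzyme_uM, dtype=float)
    if np.any(cs < 0) or np.any(ce < 0):
        raise InvalidInputError("concentrations must be non-negative")
    if np.any(cs < 10.0 * params.K_M):
        warnings.warn(
            "substrate below 10*K_M: linearized rate law is inaccurate",
            LinearRangeWarning, stacklevel=2,
        )
    if params.substrate_inhibited:
        v = params.k_cat * ce / (1.0 + cs / params.K_i)
    else:
        v = params.k_cat * ce * np.ones_like(cs)
    return float(v) if np.isscalar(enzyme_uM) and np.isscalar(substrate_mM) else v


def _ols_slope_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2; a flat signal counts as a perfect fit."""
    if np.ptp(t) == 0:
        raise FitError("all time points equal: slope is undefined")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def velocity_from_timecourse(
    tc: TimeCourse,
    window: Optional[slice] = None,
    min_points: int = 4,
    r2_threshold: float = 0.9999,
) -> float:
    """Initial velocity (uM/s) from the slope of an assay time course.

    With an explicit ``window`` the OLS slope over that slice is used.
    Otherwise the window is the longest initial prefix (>= ``min_points``
    points) whose linear fit keeps R^2 >= ``r2_threshold``; if even the
    shortest prefix fails the threshold it is used anyway with a warning.

    The default threshold is deliberately strict: R^2 is very insensitive
    to the downward slope bias of a saturating signal (a linear fit to
    1 - exp(-t/tau) keeps R^2 > 0.99 out to t ~ 0.8 tau, where the slope
    is already ~30% low). At 0.9999 the window stops near 0.07 tau and the
    extracted rate is within ~5% of the true initial rate; lower the
    threshold explicitly for noisy signals that cannot reach it.
    """
    t, y = tc.times_s, tc.signal
    if window is not None:
        t, y = t[window], y[window]
        if t.size < 3:
            raise InvalidInputError("window must contain at least 3 points")
        slope, _ = _ols_slope_r2(t, y)
        return slope * tc.calibration_uM_per_au
    min_points = max(3, min_points)
    if t.size < min_points:
        raise InvalidInputError(f"time course shorter than {min_points} points")
    best_slope = None
    for n in range(min_points, t.size + 1):
        slope, r2 = _ols_slope_r2(t[:n], y[:n])
        if r2 >= r2_threshold:
            best_slope = slope
        elif best_slope is not None:
            break
    if best_slope is None:
        warnings.warn(
            "no initial prefix met the linearity threshold; using the "
            f"first {min_points} points", LinearRangeWarning, stacklevel=2,
        )
        best_slope, _ = _ols_slope_r2(t[:min_points], y[:min_points])
    return best_slope * tc.calibration_uM_per_au


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class KineticFitResults:
    """Results of a Michaelis-Menten fit.

    Attributes
    ----------
    params : KineticParams
        Point estimates (k_cat, K_M and, for the inhibited law, K_i).
    bse : dict
        Approximate standard errors per parameter (NaN when the
        covariance could not be estimated).
    rsquared : float
        Coefficient of determination on velocities.
    model_label : str
        ``"standard"`` or ``"substrate_inhibited"``.
    aicc : float
        Small-sample corrected Akaike information criterion.
    """

    def __init__(self, params: KineticParams, bse: dict, rsquared: float,
                 model_label: str, aicc: float, nobs: int,
                 fitted: np.ndarray, residuals: np.ndarray) -> None:
        self.params = params
        self.bse = bse
        self.rsquared = float(min(max(rsquared, 0.0), 1.0))
        self.model_label = model_label
        self.aicc = float(aicc)
        self.nobs = int(nobs)
        self.fittedvalues = fitted
        self.resid = residuals

    def predict(self, substrate_mM, enzyme_uM) -> np.ndarray | float:
        return velocity(self.params, substrate_mM, enzyme_uM)

    def to_dict(self) -> dict:
        d = {
            "model": self.model_label,
            "k_cat_per_s": self.params.k_cat,
            "K_M_mM": self.params.K_M,
            "r_squared": self.rsquared,
            "aicc": self.aicc,
            "n_obs": self.nobs,
            "stderr": dict(self.bse),
        }
        if self.params.K_i is not None:
            d["K_i_mM"] = self.params.K_i
        return d

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            "=" * 46,
            f"model:          {self.model_label}",
            f"n observations: {self.nobs}",
            f"R-squared:      {self.rsquared:.4f}",
            f"AICc:           {self.aicc:.2f}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
        ]
        rows = [("k_cat [1/s]", self.params.k_cat, self.bse.get("k_cat")),
                ("K_M [mM]", self.params.K_M, self.bse.get("K_M"))]
        if self.params.K_i is not None:
            rows.append(("K_i [mM]", self.params.K_i, self.bse.get("K_i")))
        for name, est, se in rows:
            se_s = f"{se:>12.4g}" if se is not None and np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<12}{est:>12.4g}{se_s}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<KineticFitResults {self.model_label} "
                f"k_cat={self.params.k_cat:.4g} K_M={self.params.K_M:.4g} "
                f"R2={self.rsquared:.4f}>")


class MichaelisMentenModel:
    """Saturable enzyme-velocity model fitted by nonlinear least squares.

    Parameters
    ----------
    substrate_mM, enzyme_uM, velocity_uM_s : array-like
        Observed initial-velocity design points.
    model : {"standard", "substrate_inhibited", "auto"}
        Rate law to fit; ``"auto"`` fits both and keeps the lower AICc.

    The objective is unweighted least squares on velocities. Starting
    values: k_cat from max(V_P)/C_E, K_M from the substrate level nearest
    half-maximal velocity, K_i from 10 * max(C_S).
    """

    MIN_LEVELS = {"standard": 4, "substrate_inhibited": 5}

    def __init__(self, substrate_mM, enzyme_uM, velocity_uM_s,
                 model: str = "auto") -> None:
        self.substrate_mM = np.asarray(substrate_mM, dtype=float)
        self.enzyme_uM = np.asarray(enzyme_uM, dtype=float)
        self.velocity_uM_s = np.asarray(velocity_uM_s, dtype=float)
        if not (self.substrate_mM.shape == self.enzyme_uM.shape
                == self.velocity_uM_s.shape):
            raise InvalidInputError("data arrays must share a shape")
        if model not in ("standard", "substrate_inhibited", "auto"):
            raise InvalidInputError(f"unknown model {model!r}")
        self.model = model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "auto",
                       substrate_col: str = "C_S_mM",
                       enzyme_col: str = "C_E_uM",
                       velocity_col: str = "V_P_uM_per_s") -> "MichaelisMentenModel":
        return cls(df[substrate_col], df[enzyme_col], df[velocity_col], model)

    @classmethod
    def from_observations(cls, obs: Iterable[VelocityObservation],
                          model: str = "auto") -> "MichaelisMentenModel":
        obs = list(obs)
        return cls([o.substrate_mM for o in obs], [o.enzyme_uM for o in obs],
                   [o.velocity_uM_s for o in obs], model)

    # -- internals ----------------------------------------------------------

    def _check_design(self, label: str) -> None:
        n_levels = np.unique(self.substrate_mM[self.substrate_mM > 0]).size
        need = self.MIN_LEVELS[label]
        if n_levels < need:
            raise DesignError(
                f"{label} fit needs >= {need} distinct positive substrate "
                f"levels, got {n_levels}"
            )

    def _initial_guess(self) -> tuple[float, float, float]:
        vmax0 = float(self.velocity_uM_s.max())
        ce_ref = float(np.median(self.enzyme_uM[self.enzyme_uM > 0]))
        k_cat0 = max(vmax0 / ce_ref, 1e-9)
        half = np.abs(self.velocity_uM_s - vmax0 / 2.0)
        K_M0 = max(float(self.substrate_mM[np.argmin(half)]), 1e-6)
        K_i0 = 10.0 * float(self.substrate_mM.max())
        return k_cat0, K_M0, K_i0

    def _fit_one(self, label: str) -> KineticFitResults:
        self._check_design(label)
        cs, ce, v = self.substrate_mM, self.enzyme_uM, self.velocity_uM_s
        k_cat0, K_M0, K_i0 = self._initial_guess()

        pars = lmfit.Parameters()
        pars.add("k_cat", value=k_cat0, min=1e-12)
        pars.add("K_M", value=K_M0, min=1e-12)
        if label == "substrate_inhibited":
            pars.add("K_i", value=K_i0, min=1e-12)

        def residual(p: lmfit.Parameters) -> np.ndarray:
            kp = KineticParams(p["k_cat"].value, p["K_M"].value,
                               p["K_i"].value if "K_i" in p else None)
            return np.asarray(velocity(kp, cs, ce)) - v

        try:
            out = lmfit.minimize(residual, pars, method="leastsq")
        except Exception as exc:  # lmfit wraps scipy failures variously
            raise FitError(f"{label} fit failed: {exc}") from exc
        if not out.success:
            raise FitError(f"{label} fit did not converge: {out.message}")

        est = KineticParams(
            out.params["k_cat"].value, out.params["K_M"].value,
            out.params["K_i"].value if "K_i" in out.params else None,
        )
        bse = {name: (out.params[name].stderr if out.params[name].stderr
                      is not None else float("nan"))
               for name in out.params}
        fitted = np.asarray(velocity(est, cs, ce))
        resid = v - fitted
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        n, k = v.size, len(out.params)
        # Gaussian log-likelihood AIC with small-sample correction
        ss = max(ss_res, 1e-300)
        aic = n * np.log(ss / n) + 2 * (k + 1)
        denom = n - k - 2
        aicc = aic + (2 * (k + 1) * (k + 2) / denom if denom > 0 else np.inf)
        return KineticFitResults(est, bse, r2, label, aicc, n, fitted, resid)

    def fit(self) -> KineticFitResults:
        if self.model != "auto":
            return self._fit_one(self.model)
        standard = self._fit_one("standard")
        try:
            inhibited = self._fit_one("substrate_inhibited")
        except (DesignError, FitError):
            return standard
        return inhibited if inhibited.aicc < standard.aicc else standard


def fit_kinetics(
    observations: Sequence[VelocityObservation] | pd.DataFrame,
    model: str = "auto",
) -> KineticFitResults:
    """Fit a rate law to velocity observations (functional front door)."""
    if isinstance(observations, pd.DataFrame):
        mdl = MichaelisMentenModel.from_dataframe(observations, model)
    else:
        mdl = MichaelisMentenModel.from_observations(observations, model)
    return mdl.fit()


# ---------------------------------------------------------------------------
# integrated rate law
# ---------------------------------------------------------------------------

def integrated_mm_time(
    params: KineticParams,
    enzyme_uM: float,
    substrate0_mM: float,
    conversion: float,
) -> float:
    """Time (s) for a well-mixed standard MM reaction to reach a conversion.

    Exact closed form of the integrated rate law:
    t = [K_M * ln(C_S0/C_S) + (C_S0 - C_S)] / (k_cat * C_E), with
    C_S = (1 - conversion) * C_S0. Substrate inhibition is not supported
    here (no closed form); K_i, if present, is ignored with the standard
    law's time being an underestimate in that case.
    """
    if not 0 < conversion < 1:
        raise InvalidInputError(
            "conversion must lie strictly in (0, 1); full conversion takes "
            "infinite time"
        )
    if enzyme_uM <= 0 or substrate0_mM <= 0:
        raise InvalidInputError("enzyme and substrate must be positive")
    cs = (1.0 - conversion) * substrate0_mM
    consumed_mM = substrate0_mM - cs
    # k_cat * C_E has units uM/s = 1e-3 mM/s
    vmax_mM_s = params.k_cat * enzyme_uM * 1e-3
    return (params.K_M * np.log(substrate0_mM / cs) + consumed_mM) / vmax_mM_s


def conversion_time_surface(
    params: KineticParams,
    enzyme_uM_grid: Sequence[float],
    substrate0_mM_grid: Sequence[float],
    conversion: float = 0.99,
) -> pd.DataFrame:
    """Conversion times over a (C_E, C_S0) design grid.

    Returns a long-format frame with columns ``C_E_uM``, ``C_S0_mM``,
    ``t_s`` and ``t_h``. Time is exactly inversely proportional to C_E,
    the hyperbolic trade-off at the heart of stiffening-protocol design.
    """
    ce = np.asarray(list(enzyme_uM_grid), dtype=float)
    cs0 = np.asarray(list(substrate0_mM_grid), dtype=float)
    if ce.size == 0 or cs0.size == 0:
        raise InvalidInputError("grids must be nonempty")
    rows = [
        (e, s, integrated_mm_time(params, e, s, conversion))
        for e in ce for s in cs0
    ]
    df = pd.DataFrame(rows, columns=["C_E_uM", "C_S0_mM", "t_s"])
    df["t_h"] = df["t_s"] / 3600.0
    return df
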