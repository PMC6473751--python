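"""One-dimensional Fickian transport of a solute into a hydrogel slab.

The slab (thickness h, initially solute-free) is bathed on both faces by a
well-stirred reservoir held at constant concentration C0, so the problem is

    dC/dt = d/dx ( D(x,t) dC/dx ),   C(x,0) = 0,   C(0,t) = C(h,t) = C0,

with, by symmetry, zero flux at the midplane x = h/2. Two solvers are
provided: the classical Fourier-series solution for constant D, and a
Crank-Nicolson finite-difference scheme (conservative face-conductance
form) that also handles D varying in space and time. The series is the
independent oracle for the finite-difference solver in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.linalg import solve_banded

from . import constants as C
from .errors import GridError, HorizonExceededError, InvalidInputError

__all__ = [
    "Diffusivity",
    "SlabProblem",
    "Grid1D",
    "ConcentrationField",
    "analytic_profile",
    "analytic_field",
    "fd_solve",
    "center_flux",
    "equilibration_time",
]

#: constant, D(x) -> array, or D(x, t) -> array (m^2/s)
Diffusivity = Union[float, Callable[..., np.ndarray]]


def _eval_diffusivity(D: Diffusivity, x: np.ndarray, t: float) -> np.ndarray:
    if callable(D):
        try:
            values = np.asarray(D(x, t), dtype=float)
        except TypeError:
            values = np.asarray(D(x), dtype=float)
        values = np.broadcast_to(values, np.shape(x)).astype(float)
    else:
        values = np.full(np.shape(x), float(D))
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise InvalidInputError("diffusivity must be finite and non-negative")
    return values


@dataclass(frozen=True)
class SlabProblem:
    """Slab geometry, diffusivity and boundary data."""

    thickness_m: float = C.SLAB_THICKNESS_M
    diffusivity: Diffusivity = C.D_GEL_STIFF
    surface_concentration: float = 1.0     # C0, any concentration unit
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_m <= 0:
            raise InvalidInputError("slab thickness must be positive")
        if isinstance(self.diffusivity, (int, float)) and self.diffusivity < 0:
            raise InvalidInputError("diffusivity must be non-negative")
        if self.surface_concentration < 0 or self.initial_concentration < 0:
            raise InvalidInputError("concentrations must be non-negative")

    def diffusivity_at(self, x: np.ndarray, t: float) -> np.ndarray:
        """Evaluate D on positions ``x`` at time ``t`` (vectorized)."""
        return _eval_diffusivity(self.diffusivity, x, t)

    @property
    def has_constant_diffusivity(self) -> bool:
        return not callable(self.diffusivity)


@dataclass(frozen=True)
class Grid1D:
    """Output discretization: spatial step, time step and horizon.

    ``output_every`` thins the stored time levels (every k-th step plus the
    final one); it affects memory only, never the time stepping itself.
    """

    dx_m: float = C.DEFAULT_DX_M
    dt_s: float = C.DEFAULT_DT_S
    horizon_s: float = 6 * 3600.0
    output_every: int = 60

    def __post_init__(self) -> None:
        if self.dx_m <= 0 or self.dt_s <= 0 or self.horizon_s <= 0:
            raise GridError("grid steps and horizon must be positive")
        if self.output_every < 1:
            raise GridError("output_every must be >= 1")

    def positions(self, thickness_m: float) -> np.ndarray:
        n = int(round(thickness_m / self.dx_m))
        if n < 2:
            raise GridError("spatial step too coarse for the slab thickness")
        if abs(n * self.dx_m - thickness_m) > self.dx_m:
            raise GridError("spatial step must divide the thickness to within one step")
        return np.linspace(0.0, thickness_m, n + 1)

    def n_steps(self) -> int:
        return int(np.ceil(self.horizon_s / self.dt_s))

    def times(self) -> np.ndarray:
        return np.arange(0, self.n_steps() + 1, dtype=float) * self.dt_s

    def output_steps(self) -> np.ndarray:
        """Indices of the stored time levels."""
        steps = np.arange(0, self.n_steps() + 1, self.output_every)
        if steps[-1] != self.n_steps():
            steps = np.append(steps, self.n_steps())
        return steps


@dataclass
class ConcentrationField:
    """Space-time concentration array C(x, t) with its axes."""

    x: np.ndarray          # positions, m (nx,)
    t: np.ndarray          # times, s (nt,)
    values: np.ndarray     # (nt, nx)
    surface_concentration: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.t.size, self.x.size):
            raise InvalidInputError("field shape must be (n_times, n_positions)")

    def profile(self, t: float) -> np.ndarray:
        """Concentration profile at the stored time nearest to ``t``."""
        return self.values[int(np.argmin(np.abs(self.t - t)))]

    def center_series(self) -> np.ndarray:
        """C at the node nearest the midplane, as a function of time."""
        return self.values[:, int(np.argmin(np.abs(self.x - self.x[-1] / 2)))]

    def normalized(self) -> np.ndarray:
        """values / C0 (dimensionless saturation)."""
        return self.values / self.surface_concentration


def _series_ratio(x: np.ndarray, t: float, D: float, h: float,
                  tolerance: float, max_terms: int) -> np.ndarray:
    """C/C0 by the odd-harmonic Fourier series; x may be an array, t > 0."""
    x = np.asarray(x, dtype=float)
    acc = np.zeros_like(x)
    for n in range(max_terms):
        k = 2 * n + 1
        amplitude = np.exp(-D * k**2 * np.pi**2 * t / h**2) / k
        acc += amplitude * np.sin(k * np.pi * x / h)
        if amplitude < tolerance:
            break
    ratio = 1.0 - (4.0 / np.pi) * acc
    return np.clip(ratio, 0.0, 1.0)


def analytic_profile(
    problem: SlabProblem,
    x: Union[float, np.ndarray],
    t: float,
    tolerance: float = 1e-12,
    max_terms: int = 10_000,
) -> Union[float, np.ndarray]:
    """Series solution C(x, t) for constant diffusivity.

    C = C0 * {1 - (4/pi) * sum_n [exp(-D (2n+1)^2 pi^2 t / h^2)
    * sin((2n+1) pi x / h) / (2n+1)]}, truncated once a term's magnitude
    drops below ``tolerance`` (relative to C0). At t = 0 the initial
    condition is returned directly to avoid Gibbs oscillation.
    """
    if not problem.has_constant_diffusivity:
        raise InvalidInputError("analytic series requires a constant diffusivity")
    h = problem.thickness_m
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > h * (1 + 1e-12)):
        raise InvalidInputError("position outside the slab [0, h]")
    if t < 0:
        raise InvalidInputError("time must be non-negative")
    C0 = problem.surface_concentration
    if t == 0:
        out = np.where((xa == 0) | (xa == h), C0, problem.initial_concentration)
        return float(out) if np.isscalar(x) else out
    ratio = _series_ratio(xa, t, float(problem.diffusivity), h, tolerance, max_terms)
    out = C0 * ratio
    return float(out) if np.isscalar(x) else out


def analytic_field(
    problem: SlabProblem,
    grid: Grid1D,
    times: Optional[np.ndarray] = None,
) -> ConcentrationField:
    """Series solution evaluated on a full space-time grid."""
    x = grid.positions(problem.thickness_m)
    if times is None:
        times = grid.times()[grid.output_steps()]
    else:
        times = np.asarray(times, dtype=float)
    values = np.stack([analytic_profile(problem, x, ti) for ti in times])
    return ConcentrationField(x, times, values, problem.surface_concentration)


def fd_solve(problem: SlabProblem, grid: Grid1D) -> ConcentrationField:
    """Crank-Nicolson solution of the slab problem on the given grid.

    Conservative discretization: face conductances are the harmonic mean of
    the nodal diffusivities evaluated at the half step, so spatially varying
    D conserves mass across material interfaces. Dirichlet faces at C0;
    second order in both steps; unconditionally stable.
    """
    x = grid.positions(problem.thickness_m)
    nx = x.size
    m = nx - 2                       # interior unknowns
    dx, dt = grid.dx_m, grid.dt_s
    C0 = problem.surface_concentration
    r = dt / (2.0 * dx**2)
    constant_D = problem.has_constant_diffusivity

    c = np.full(nx, problem.initial_concentration, dtype=float)
    c[0] = c[-1] = C0

    out_steps = grid.output_steps()
    stored = np.empty((out_steps.size, nx))
    stored[0] = c
    store_idx = 1
    next_out = out_steps[store_idx] if out_steps.size > 1 else None

    a = b = diag = None
    ab = None

    def assemble(t_mid: float) -> None:
        nonlocal a, b, diag, ab
        Dn = problem.diffusivity_at(x, t_mid)
        s = Dn[:-1] + Dn[1:]
        Df = np.where(s > 0, 2.0 * Dn[:-1] * Dn[1:] / np.where(s > 0, s, 1.0), 0.0)
        a = r * Df[:-1]              # coupling of unknown j to node j (left)
        b = r * Df[1:]               # coupling of unknown j to node j+2 (right)
        diag = 1.0 + a + b
        ab = np.zeros((3, m))
        ab[0, 1:] = -b[:-1]
        ab[1, :] = diag
        ab[2, :-1] = -a[1:]

    n_steps = grid.n_steps()
    for step in range(1, n_steps + 1):
        if ab is None or not constant_D:
            assemble((step - 0.5) * dt)
        interior = c[1:-1]
        rhs = (2.0 - diag) * interior
        rhs[1:] += a[1:] * c[1:-2]
        rhs[:-1] += b[:-1] * c[2:-1]
        rhs[0] += 2.0 * a[0] * C0    # old + new boundary level
        rhs[-1] += 2.0 * b[-1] * C0
        c[1:-1] = solve_banded((1, 1), ab, rhs)

        if next_out is not None and step == next_out:
            stored[store_idx] = c
            store_idx += 1
            next_out = out_steps[store_idx] if store_idx < out_steps.size else None

    times = out_steps[:store_idx] * dt
    return ConcentrationField(x, times, stored[:store_idx], C0)


def center_flux(
    field: ConcentrationField,
    diffusivity: Diffusivity = 1.0,
) -> np.ndarray:
    """Diffusive flux -D dC/dx at the midplane, one value per stored time.

    A symmetric field gives zero (the midplane no-flux condition); pass the
    problem's diffusivity for a dimensional flux, or leave the default 1.0
    for a pure gradient diagnostic.
    """
    if field.x.size < 3:
        raise GridError("need at least 3 nodes to form a central difference")
    h = field.x[-1]
    i = int(np.argmin(np.abs(field.x - h / 2)))
    if i == 0 or i == field.x.size - 1:
        raise GridError("midplane node lies on the boundary")
    dx = field.x[i + 1] - field.x[i - 1]
    grad = (field.values[:, i + 1] - field.values[:, i - 1]) / dx
    if callable(diffusivity):
        xc = np.array([field.x[i]])
        D = np.array([float(_eval_diffusivity(diffusivity, xc, t)[0])
                      for t in field.t])
    else:
        D = float(diffusivity)
    return -D * grad


def equilibration_time(
    problem: SlabProblem,
    grid: Grid1D,
    fraction: float,
) -> float:
    """Earliest grid time at which min_x C(x,t)/C0 >= fraction.

    For a symmetric problem the slowest node is the midplane, so for
    constant D the search reduces to the center saturation curve of the
    analytic series; a varying D falls back to the finite-difference field.
    Raises :class:`HorizonExceededError` if the fraction is never reached.
    """
    if not 0 < fraction < 1:
        raise InvalidInputError("fraction must lie in (0, 1)")
    times = grid.times()
    if problem.has_constant_diffusivity:
        D, h = float(problem.diffusivity), problem.thickness_m
        lam = D * np.pi**2 / h**2
        t_pos = times[1:]
        acc = np.zeros_like(t_pos)
        for n in range(10_000):
            k = 2 * n + 1
            sign = 1.0 if n % 2 == 0 else -1.0   # sin(k pi / 2)
            amp = np.exp(-lam * k**2 * t_pos) / k
            acc += sign * amp
            if amp.max() < 1e-12:
                break
        ratio = np.concatenate([[0.0], np.clip(1.0 - (4 / np.pi) * acc, 0.0, 1.0)])
        reached = np.nonzero(ratio >= fraction)[0]
    else:
        field = fd_solve(problem, grid)
        sat = field.normalized().min(axis=1)
        times = field.t
        reached = np.nonzero(sat >= fraction)[0]
    if reached.size == 0:
        raise HorizonExceededError(
            f"saturation fraction {fraction} not reached within "
            f"{grid.horizon_s:.0f} s"
        )
    return float(times[reached[0]])
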