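"""Closed-form kinetics of diffusion-limited adsorption at a plane interface.

This module collects the analytic backbone of the package: Fick/Gaussian
propagator quantities, the Stokes–Einstein relation, the Langmuir–Schaefer
short-time adsorption law, the Ward–Tordai back-diffusion correction, the
discrete-observation ("single-PDF") adsorption count and its mirror-doubled
form, the characteristic integration time that separates re-counted from
under-counted collisions, and the per-site rate constants used by the SAM
and biosensor experiments.

All quantities are SI.  Concentrations are number densities (molecules/m^3);
use :func:`convert_concentration` at the boundary.  Adsorbed amounts Gamma
are molecule counts on a reference area ``A``.

Conventions
-----------
* ``gamma_*`` functions return cumulative adsorbed molecules.
* Rates (``collision_rate``, ``initial_adsorption_rate``, ``sam_ideal_k2``,
  ``biosensor_k3``) are per second.
* The surface is a perfect sink unless stated otherwise; there is no
  desorption anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, BOLTZMANN

__all__ = [
    "DiffusionParams",
    "Geometry",
    "Concentration",
    "ObservationScheme",
    "RateSet",
    "SubsurfaceHistory",
    "stokes_einstein",
    "radius_from_mw",
    "gaussian_profile",
    "surface_flux_rate",
    "gamma_langmuir_schaefer",
    "gamma_ward_tordai",
    "gamma_discrete",
    "collision_rate",
    "nearest_neighbor_spacing",
    "characteristic_time",
    "initial_adsorption_rate",
    "sam_ideal_k2",
    "biosensor_k3",
    "langmuir_coverage",
    "convert_concentration",
]


def _require_positive(**kwargs: float) -> None:
    bad = [name for name, v in kwargs.items() if not np.all(np.asarray(v) > 0)]
    if bad:
        raise ValueError(f"arguments must be strictly positive: {', '.join(bad)}")


def _require_nonnegative(**kwargs: float) -> None:
    bad = [name for name, v in kwargs.items() if not np.all(np.asarray(v) >= 0)]
    if bad:
        raise ValueError(f"arguments must be nonnegative: {', '.join(bad)}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DiffusionParams:
    """Physical constants of the solute/solvent pair.

    Any subset may be set; ``D`` can be derived from (T, eta, r) via
    :func:`stokes_einstein` and ``r`` from (Mw, rho) via
    :func:`radius_from_mw`.  All fields SI: D (m^2/s), T (K), eta (Pa s),
    r (m), Mw (kg per molecule), rho (kg/m^3).
    """

    D: float | None = None
    T: float | None = None
    eta: float | None = None
    r: float | None = None
    Mw: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        for name in ("D", "T", "eta", "r", "Mw", "rho"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.r is None and self.Mw is not None and self.rho is not None:
            self.r = radius_from_mw(self.Mw, self.rho)
        if self.D is None and None not in (self.T, self.eta, self.r):
            self.D = stokes_einstein(self.T, self.eta, self.r)


@dataclass
class Geometry:
    """1D-column geometry: surface area ``A``, height ``L``, volume ``V = A*L``."""

    A: float
    L: float

    def __post_init__(self) -> None:
        _require_positive(A=self.A, L=self.L)

    @property
    def V(self) -> float:
        return self.A * self.L


@dataclass
class Concentration:
    """Bulk concentration, stored as number density (molecules/m^3)."""

    number_density: float

    def __post_init__(self) -> None:
        _require_nonnegative(number_density=self.number_density)

    @property
    def molar(self) -> float:
        """mol/m^3."""
        return self.number_density / AVOGADRO

    @classmethod
    def from_value(cls, value: float, unit: str) -> "Concentration":
        return cls(convert_concentration(value, unit))


@dataclass
class ObservationScheme:
    """Discrete observation: frame time ``dt``, sub-steps per frame, total time."""

    dt: float
    n_sub: int = 1
    t_end: float | None = None

    def __post_init__(self) -> None:
        _require_positive(dt=self.dt)
        if int(self.n_sub) != self.n_sub or self.n_sub < 1:
            raise ValueError(f"n_sub must be an integer >= 1, got {self.n_sub!r}")
        self.n_sub = int(self.n_sub)

    @property
    def dt_sub(self) -> float:
        return self.dt / self.n_sub


@dataclass
class RateSet:
    """Derived kinetic quantities for a given (A, c_b, D, dt) condition."""

    r_mean: float = 0.0
    dtc: float = 0.0
    d0: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative(
            r_mean=self.r_mean, dtc=self.dtc, d0=self.d0,
            k1=self.k1, k2=self.k2, k3=self.k3,
        )


@dataclass
class SubsurfaceHistory:
    """Sub-surface concentration history c(tau) on a time grid.

    ``times`` must be strictly increasing and start at 0; ``conc`` is the
    number density immediately adjacent to the interface.  Values between
    grid points are linearly interpolated.
    """

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise ValueError("times and conc must be 1D arrays of equal length")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing from 0")
        if np.any(self.conc < 0):
            raise ValueError("conc must be nonnegative")

    @classmethod
    def constant(cls, c: float, t_end: float) -> "SubsurfaceHistory":
        return cls(np.array([0.0, t_end]), np.array([c, c]))

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        return np.interp(tau, self.times, self.conc)


# ---------------------------------------------------------------------------
# Transport coefficients
# ---------------------------------------------------------------------------


def stokes_einstein(T: float, eta: float, r: float) -> float:
    """Diffusion constant of a sphere: D = k_B*T / (6*pi*eta*r)."""
    _require_positive(T=T, eta=eta, r=r)
    return BOLTZMANN * T / (6.0 * np.pi * eta * r)


def radius_from_mw(Mw: float, rho: float) -> float:
    """Equivalent-sphere radius from molecular mass and neat density.

    Inverts Mw = (4/3)*pi*r^3*rho, i.e. r = (3*Mw / (4*pi*rho))^(1/3).
    ``Mw`` is the mass of one molecule in kg (divide a molar mass in
    kg/mol by Avogadro's number first).
    """
    _require_positive(Mw=Mw, rho=rho)
    return (3.0 * Mw / (4.0 * np.pi * rho)) ** (1.0 / 3.0)


def gaussian_profile(x, t: float, D: float):
    """Free-diffusion propagator C(x, t) = (4*pi*D*t)^(-1/2) exp(-x^2/(4Dt)).

    A 1D Gaussian of standard deviation sqrt(2*D*t), normalized to unit
    integral over x.  The t -> 0 delta limit is not represented.
    """
    _require_positive(t=t, D=D)
    x = np.asarray(x, dtype=float)
    return np.exp(-x * x / (4.0 * D * t)) / np.sqrt(4.0 * np.pi * D * t)


# ---------------------------------------------------------------------------
# Continuum adsorption laws
# ---------------------------------------------------------------------------


def surface_flux_rate(t, A: float, c_b: float, D: float):
    """Instantaneous perfect-sink adsorption rate dGamma/dt = A*c_b*sqrt(D/(pi*t)).

    Returned as a positive magnitude; the solution-side concentration is
    being depleted at this rate.  Its integral from 0 to t is
    :func:`gamma_langmuir_schaefer`.
    """
    _require_positive(t=t, A=A, D=D)
    _require_nonnegative(c_b=c_b)
    t = np.asarray(t, dtype=float)
    return A * c_b * np.sqrt(D / (np.pi * t))


def gamma_langmuir_schaefer(t, A: float, c_b: float, D: float):
    """Short-time perfect-sink adsorbed amount Gamma(t) = 2*A*c_b*sqrt(D*t/pi).

    Valid while the sub-surface solution remains effectively semi-infinite
    and the surface captures every arriving molecule.
    """
    _require_positive(A=A, D=D)
    _require_nonnegative(t=t, c_b=c_b)
    t = np.asarray(t, dtype=float)
    return 2.0 * A * c_b * np.sqrt(D * t / np.pi)


def gamma_ward_tordai(
    t: float,
    A: float,
    c_b: float,
    D: float,
    history: SubsurfaceHistory,
    n_panels: int = 512,
) -> float:
    """Adsorbed amount with back-diffusion from a sub-surface history.

    Gamma(t) = 2*A*c_b*sqrt(D*t/pi) - A*sqrt(D/pi) * int_0^t c(tau)/sqrt(t-tau) dtau.

    The singular convolution is regularized with u = sqrt(t - tau), giving
    int_0^sqrt(t) 2*c(t - u^2) du, evaluated by composite Simpson quadrature
    with ``2*n_panels`` subintervals (>= 512 panels converges smooth
    histories well past 1e-6 relative).
    """
    _require_positive(A=A, D=D)
    _require_nonnegative(t=t, c_b=c_b)
    if history.times[-1] < t:
        raise ValueError(
            f"subsurface history covers [0, {history.times[-1]:g}] but t={t:g}"
        )
    if t == 0.0:
        return 0.0
    from scipy.integrate import simpson

    u = np.linspace(0.0, np.sqrt(t), 2 * int(n_panels) + 1)
    integrand = 2.0 * history(t - u * u)
    back = A * np.sqrt(D / np.pi) * simpson(integrand, x=u)
    return float(gamma_langmuir_schaefer(t, A, c_b, D) - back)


# ---------------------------------------------------------------------------
# Discrete-observation (single-PDF) laws and the mirror correction
# ---------------------------------------------------------------------------


def gamma_discrete(dt: float, A: float, c_b: float, D: float, mirror: bool = False):
    """Adsorbed/collided count in one discrete observation window dt.

    With ``mirror=False`` this is the single-PDF endpoint count
    A*c_b*sqrt(D*dt/pi): each molecule's Gaussian is integrated past the
    wall once, ignoring the self-similar sub-structure of the walk.  It is
    exactly half of the continuum law at t = dt.

    With ``mirror=True`` the truncated half of each step distribution is
    returned to the solution (the "mirror effect"), doubling the count to
    2*A*c_b*sqrt(D*dt/pi) and recovering the continuum value.
    """
    _require_positive(dt=dt, A=A, D=D)
    _require_nonnegative(c_b=c_b)
    base = A * c_b * np.sqrt(D * np.asarray(dt, dtype=float) / np.pi)
    return 2.0 * base if mirror else base


def collision_rate(dt: float, A: float, c_b: float, D: float):
    """Mean wall-collision rate observed at resolution dt: <r> = 2*A*c_b*sqrt(D/(pi*dt)).

    Equals ``gamma_discrete(dt, ..., mirror=True) / dt``; the rate depends on
    the observation time because finer resolution resolves more distinct
    collisions of the same molecule.
    """
    _require_positive(dt=dt, A=A, D=D)
    _require_nonnegative(c_b=c_b)
    return 2.0 * A * c_b * np.sqrt(D / (np.pi * np.asarray(dt, dtype=float)))


def nearest_neighbor_spacing(c_b: float) -> float:
    """Mean inter-molecule spacing d0 = c_b^(-1/3) in a uniform solution."""
    _require_positive(c_b=c_b)
    return float(c_b) ** (-1.0 / 3.0)


def characteristic_time(c_b: float, D: float) -> float:
    """Characteristic integration time dt_c = pi / (4*D*c_b^(2/3)).

    The observation time at which a molecule's mean diffusion distance
    sqrt(4*D*dt/pi) equals the nearest-neighbor spacing d0, i.e. departing
    molecules are exactly replaced by neighbors and the sub-surface
    concentration is self-maintained.  Shorter windows re-count the same
    molecule; longer windows under-count returning molecules.
    """
    _require_positive(c_b=c_b, D=D)
    return np.pi / (4.0 * D * float(c_b) ** (2.0 / 3.0))


def initial_adsorption_rate(A: float, c_b: float, D: float) -> float:
    """Initial diffusion-limited adsorption rate <r> = (4/pi)*A*c_b^(4/3)*D.

    Obtained by evaluating :func:`collision_rate` at the characteristic
    time dt_c, or equivalently as (A/d0^2) sites turning over once per
    dt_c.  Independent of the observation resolution; 4/3-order in
    concentration.
    """
    _require_positive(A=A, c_b=c_b, D=D)
    return (4.0 / np.pi) * A * float(c_b) ** (4.0 / 3.0) * D


def sam_ideal_k2(a: float, c_b: float, D: float) -> float:
    """Ideally stirred per-site rate constant k2 = (4/pi)*a*c_b^(4/3)*D.

    The initial adsorption rate with the ensemble area replaced by a single
    binding-site area ``a``; assumes stirring maintains the bulk
    concentration at the surface for all time.
    """
    _require_positive(a=a, c_b=c_b, D=D)
    return initial_adsorption_rate(a, c_b, D)


def biosensor_k3(a: float, c_b: float, D: float, dt: float) -> float:
    """Discrete-observation per-site rate constant k3 = 2*a*c_b*sqrt(D/(pi*dt)).

    The mirror-corrected collision rate with the ensemble area replaced by a
    single binding-site area ``a``; first-order in concentration and
    dependent on the simulation/observation step ``dt``.
    """
    _require_positive(a=a, c_b=c_b, D=D, dt=dt)
    return float(collision_rate(dt, a, c_b, D))


def langmuir_coverage(t, n_sites: float, k: float):
    """Irreversible Langmuir filling curve Gamma1(t) = n_sites*(1 - exp(-k*t)).

    ``n_sites`` is the total number of binding sites A/a; the curve
    saturates at full coverage with effective first-order rate ``k``.
    """
    _require_nonnegative(t=t, n_sites=n_sites, k=k)
    t = np.asarray(t, dtype=float)
    return n_sites * -np.expm1(-k * t)


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

_MOLAR_PER_UNIT = {
    # factor converting one unit to mol/m^3
    "M": 1e3,
    "mM": 1.0,
    "uM": 1e-3,
    "μM": 1e-3,
    "nM": 1e-6,
    "pM": 1e-9,
    "mol/m3": 1.0,
    "mol/m^3": 1.0,
}


def convert_concentration(value: float, unit: str) -> float:
    """Convert a concentration to number density (molecules/m^3).

    Supported units: M, mM, uM (μM), nM, pM, mol/m^3, per_m3 (already a
    number density).  Conversion is exact via the Avogadro constant.
    """
    if value < 0:
        raise ValueError(f"concentration must be nonnegative, got {value!r}")
    if unit in ("per_m3", "per_m^3", "#/m3", "#/m^3"):
        return float(value)
    try:
        molar = value * _MOLAR_PER_UNIT[unit]
    except KeyError:
        known = sorted(set(_MOLAR_PER_UNIT) | {"per_m3"})
        raise ValueError(f"unknown concentration unit {unit!r}; known: {known}") from None
    return molar * AVOGADRO
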