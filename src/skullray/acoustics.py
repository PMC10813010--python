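"""HU-to-acoustic-property mapping and interface transmission physics.

The skull crossing is modelled as a single effective fluid layer bounded by two
interfaces (water -> skull, skull -> brain).  Smoothed HU maps linearly onto
mass density, density maps onto sound speed through a monotone calibration
curve, and each interface follows Snell's law with oblique-incidence
plane-wave transmission coefficients.  Bulk loss inside the layer follows an
empirical solidity-absorption law quoted in dB/mm.

Intensity-mode coefficients (the default) are bounded by 1, so a per-channel
total transmission is a well-defined energy fraction; the pressure-mode
coefficient (which can exceed 1 into a stiffer medium) is kept available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityCalibration",
    "VelocityCurve",
    "MediumProperties",
    "AbsorptionParams",
    "WATER",
    "BRAIN",
    "hu_to_density",
    "density_to_velocity",
    "transmission_coefficient",
    "snell_refract",
    "absorption_fraction",
    "total_transmission",
]


@dataclass(frozen=True)
class DensityCalibration:
    """Linear HU -> density map, clamped to [rho_min, rho_max] kg/m^3."""

    rho_min: float = 1000.0
    rho_max: float = 2200.0
    hu_min: float = 300.0
    hu_max: float = 2000.0

    def __post_init__(self) -> None:
        if not self.rho_min < self.rho_max:
            raise ValueError("rho_min must be < rho_max")
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be < hu_max")


@dataclass(frozen=True)
class VelocityCurve:
    """Monotone piecewise-linear density (kg/m^3) -> sound speed (m/s) curve.

    The default is anchored at water (1000, 1500) and rises, mildly convex, to
    3000 m/s at the default maximum skull density; it stands in for an
    experimentally calibrated curve and is fully replaceable via configuration.
    Evaluation clamps to the endpoint speeds outside the knot range.
    """

    densities: tuple[float, ...] = (1000.0, 1600.0, 2000.0, 2200.0)
    speeds: tuple[float, ...] = (1500.0, 2100.0, 2750.0, 3000.0)

    def __post_init__(self) -> None:
        if len(self.densities) == 0 or len(self.densities) != len(self.speeds):
            raise ValueError("curve needs equal, nonzero numbers of density and speed knots")
        d = np.asarray(self.densities, dtype=float)
        s = np.asarray(self.speeds, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("density knots must be strictly increasing")
        if np.any(np.diff(s) < 0):
            raise ValueError("speed knots must be nondecreasing")
        if np.any((s < 1400.0) | (s > 4000.0)):
            raise ValueError("speeds must lie within [1400, 4000] m/s")

    def __call__(self, rho: float) -> float:
        return float(np.interp(rho, self.densities, self.speeds))


@dataclass(frozen=True)
class MediumProperties:
    """A fluid medium: density rho (kg/m^3), speed c (m/s), impedance za = rho*c."""

    rho: float
    c: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.c <= 0:
            raise ValueError("rho and c must be > 0")

    @property
    def za(self) -> float:
        return self.rho * self.c


WATER = MediumProperties(rho=1000.0, c=1500.0)
BRAIN = MediumProperties(rho=1040.0, c=1560.0)


@dataclass(frozen=True)
class AbsorptionParams:
    """Solidity-absorption law: a(mu) = a_min + (a_max - a_min) * mu**beta, dB/mm.

    ``exponent_base`` selects whether the exponentiated quantity is the
    solidity mu itself (default) or the porosity 1 - mu, for sensitivity
    analysis of the empirical law's convention.
    """

    a_min: float = 0.2
    a_max: float = 8.0
    beta: float = 0.5
    exponent_base: str = "solidity"

    def __post_init__(self) -> None:
        if not 0 < self.a_min < self.a_max:
            raise ValueError("need 0 < a_min < a_max")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.exponent_base not in ("solidity", "porosity"):
            raise ValueError("exponent_base must be 'solidity' or 'porosity'")


def hu_to_density(hu_bar: float, cal: DensityCalibration = DensityCalibration()) -> float:
    """Linear HU -> density (kg/m^3), clamped to the calibration range."""
    rho = cal.rho_min + (cal.rho_max - cal.rho_min) * (hu_bar - cal.hu_min) / (cal.hu_max - cal.hu_min)
    return float(np.clip(rho, cal.rho_min, cal.rho_max))


def density_to_velocity(rho: float, curve: VelocityCurve = VelocityCurve()) -> float:
    """Sound speed (m/s) at a density via the monotone calibration curve."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    return curve(rho)


def critical_angle(c1: float, c2: float) -> float:
    """Critical incidence angle (rad) entering a faster medium; pi/2 if none."""
    if c2 <= c1:
        return np.pi / 2
    return float(np.arcsin(c1 / c2))


def transmission_coefficient(
    theta_i: float,
    m1: MediumProperties,
    m2: MediumProperties,
    mode: str = "intensity",
) -> float:
    """Plane-wave transmission coefficient across a fluid-fluid interface.

    Snell's law gives sin(theta_t) = (c2/c1) sin(theta_i).  Intensity mode
    (default) returns 4 Za1 Za2 cos(ti) cos(tt) / (Za2 cos(ti) + Za1 cos(tt))^2,
    bounded by [0, 1]; pressure mode returns
    2 Za2 cos(ti) / (Za2 cos(ti) + Za1 cos(tt)).  At or beyond the critical
    angle the coefficient is 0 (the channel is deactivated upstream).
    """
    if not 0 <= theta_i < np.pi / 2:
        raise ValueError("theta_i must lie in [0, pi/2)")
    if mode not in ("intensity", "pressure"):
        raise ValueError("mode must be 'intensity' or 'pressure'")
    sin_t = (m2.c / m1.c) * np.sin(theta_i)
    if sin_t >= 1.0:
        return 0.0
    cos_i = np.cos(theta_i)
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    denom = m2.za * cos_i + m1.za * cos_t
    if mode == "pressure":
        return float(2.0 * m2.za * cos_i / denom)
    return float(4.0 * m1.za * m2.za * cos_i * cos_t / denom**2)


def snell_refract(direction, normal, c1: float, c2: float) -> np.ndarray | None:
    """Refract a unit direction across an interface with unit normal.

    The normal must oppose the incoming ray (dot(direction, normal) < 0).
    Returns the refracted unit vector in the incidence plane, or None on total
    internal reflection ((c2/c1) sin(theta_i) > 1).
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9 or abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("direction and normal must be unit vectors")
    cos_i = -float(np.dot(d, n))
    if cos_i <= 0:
        raise ValueError("normal must be oriented against the incoming ray")
    eta = c2 / c1
    k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if k < 0:
        return None  # total internal reflection
    r = eta * d + (eta * cos_i - np.sqrt(k)) * n
    return r / np.linalg.norm(r)


def absorption_fraction(mu: float, t: float, params: AbsorptionParams = AbsorptionParams()):
    """Bulk absorption across a skull layer of thickness t (mm) at solidity mu.

    Returns (a_db, ap): the total attenuation in dB and the absorbed intensity
    fraction ap = 1 - 10**(-a_db/10).
    """
    if not 0 < mu <= 1:
        raise ValueError(f"solidity must lie in (0, 1], got {mu}")
    if t < 0:
        raise ValueError("thickness must be >= 0")
    base = mu if params.exponent_base == "solidity" else 1.0 - mu
    a_db = (params.a_min + (params.a_max - params.a_min) * base**params.beta) * t
    ap = 1.0 - 10.0 ** (-a_db / 10.0)
    return float(a_db), float(ap)


def total_transmission(t_ws: float, ap: float, t_sb: float) -> float:
    """Total transmission T = Tws * (1 - Ap) * Tsb, an energy fraction in [0, 1]."""
    for name, v in (("t_ws", t_ws), ("ap", ap), ("t_sb", t_sb)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(t_ws * (1.0 - ap) * t_sb)
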