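"""Closed-form operating-point calculations for shaken and stirred reactors.

Shaken flasks
-------------
Orbitally shaken flasks only receive the nominal power input while the bulk
liquid rotates *in phase* with the shaker table.  Two dimensionless criteria
gate this regime:

* axial Froude number ``Fra = (2*pi*n)**2 * (d0/2) / g > 0.4``,
* phase number ``Ph = (d0/d) * (1 + 3*log10(Re_film)) > 1.26``, with the
  film Reynolds number
  ``Re_film = (rho*n*d**2/eta) * (1 - sqrt(1 - (4/pi)*(V**(1/3)/d)**2))**2``.

For unbaffled flasks in phase, the empirical power correlation of Buechs
and co-workers applies:

    ``P/V = Ne' * rho * n**3 * d**4 / V**(2/3)`` with
    ``Ne' = 70*Re**-1 + 25*Re**-0.6 + 1.5*Re**-0.2``, ``Re = rho*n*d**2/eta``.

No such correlation exists for baffled flasks.

Stirred tanks
-------------
Modified impeller Reynolds number ``Re_m = rho*N*ds**2/eta``, Newton (power)
number ``Ne = P / (rho*N**3*ds**5)``, tip speed ``v_tip = pi*ds*N``, and a
vessel-specific power correlation ``P/V = a * v_tip**b`` (defaults fitted
for a 3-blade segment impeller, 85 mm, 4 L working volume).

Oxygen ceiling
--------------
Balancing oxygen transfer ``OTR = kLa*(cO2_sat - cO2)`` against uptake
``OUR = cx*qO2`` bounds the supportable viable cell density.  Oxygen
solubility in water follows the Tromans thermodynamic correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import exp, log, log10, pi, sqrt

from .hydro import FluidProperties

__all__ = [
    "STANDARD_GRAVITY",
    "ShakenSpec",
    "StirredSpec",
    "OxygenSpec",
    "axial_froude",
    "phase_number",
    "in_phase",
    "buchs_power_unbaffled",
    "reynolds_stirred",
    "newton_number",
    "tip_speed",
    "maschke_power",
    "max_supported_vcd",
    "o2_solubility",
    "water_vapor_pressure",
]

STANDARD_GRAVITY = 9.80665  # [m/s^2]

#: In-phase thresholds for orbitally shaken flasks.
PHASE_NUMBER_THRESHOLD = 1.26
AXIAL_FROUDE_THRESHOLD = 0.4


@dataclass(frozen=True)
class ShakenSpec:
    """Shaken-flask operating point (SI units).

    ``shaking_frequency`` n [1/s], ``shaking_amplitude`` d0 [m] (orbit
    diameter), ``max_inner_diameter`` d [m], ``fill_volume`` V [m^3].
    """

    shaking_frequency: float
    shaking_amplitude: float
    max_inner_diameter: float
    fill_volume: float
    fluid: FluidProperties
    nominal_volume: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "shaking_frequency",
            "shaking_amplitude",
            "max_inner_diameter",
            "fill_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nominal_volume is not None and self.fill_volume >= self.nominal_volume:
            raise ValueError("fill_volume must be below the flask nominal volume")


@dataclass(frozen=True)
class StirredSpec:
    """Stirred-tank operating point: speed N [1/s], stirrer diameter ds [m],
    fill volume V [m^3]."""

    stirrer_speed: float
    stirrer_diameter: float
    fill_volume: float
    fluid: FluidProperties

    def __post_init__(self) -> None:
        if self.stirrer_speed < 0:
            raise ValueError("stirrer_speed must be >= 0")
        for name in ("stirrer_diameter", "fill_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class OxygenSpec:
    """Oxygen mass-transfer balance inputs.

    ``kla`` [1/h]; ``qo2`` specific uptake [mol O2 / (h cell)]; ``c_star``
    interface (saturation) concentration [mol/L]; ``c_bulk`` dissolved
    concentration in the bulk [mol/L], 0 for the worst case.
    """

    kla: float
    qo2: float
    c_star: float
    c_bulk: float = 0.0

    def __post_init__(self) -> None:
        if self.kla <= 0 or self.qo2 <= 0 or self.c_star <= 0:
            raise ValueError("kla, qo2 and c_star must be > 0")
        if not 0 <= self.c_bulk < self.c_star:
            raise ValueError("need 0 <= c_bulk < c_star (no driving force otherwise)")


def axial_froude(
    n: float, d0: float, g: float = STANDARD_GRAVITY
) -> float:
    """Axial Froude number ``(2*pi*n)**2 * (d0/2) / g``.

    ``Fra > 0.4`` is required for in-phase operation of a shaken flask.
    """
    if n < 0:
        raise ValueError("shaking frequency must be >= 0")
    return (2.0 * pi * n) ** 2 * (d0 / 2.0) / g


def film_reynolds(spec: ShakenSpec) -> float:
    """Film Reynolds number of the rotating liquid sickle in a shaken flask."""
    d = spec.max_inner_diameter
    arg = (4.0 / pi) * (spec.fill_volume ** (1.0 / 3.0) / d) ** 2
    if arg >= 1.0:
        raise ValueError(
            "flask overfilled for the phase-number model: "
            "(4/pi)*(V^(1/3)/d)^2 >= 1"
        )
    re_bulk = (
        spec.fluid.density
        * spec.shaking_frequency
        * d**2
        / spec.fluid.dynamic_viscosity
    )
    return re_bulk * (1.0 - sqrt(1.0 - arg)) ** 2


def phase_number(spec: ShakenSpec) -> float:
    """Phase number ``Ph = (d0/d) * (1 + 3*log10(Re_film))``.

    ``Ph > 1.26`` (together with ``Fra > 0.4``) marks in-phase liquid
    motion; out-of-phase flasks receive far less power than nominal.
    """
    re_film = film_reynolds(spec)
    return (spec.shaking_amplitude / spec.max_inner_diameter) * (
        1.0 + 3.0 * log10(re_film)
    )


def in_phase(spec: ShakenSpec, g: float = STANDARD_GRAVITY) -> dict:
    """Joint in-phase verdict: both Ph and Fra criteria, with values."""
    ph = phase_number(spec)
    fra = axial_froude(spec.shaking_frequency, spec.shaking_amplitude, g)
    return {
        "phase_number": ph,
        "axial_froude": fra,
        "in_phase": ph > PHASE_NUMBER_THRESHOLD and fra > AXIAL_FROUDE_THRESHOLD,
    }


def buchs_power_unbaffled(spec: ShakenSpec) -> float:
    """Empirical specific power input [W/m^3] of an unbaffled shaken flask.

    ``P/V = Ne' * rho * n**3 * d**4 / V**(2/3)`` with the modified power
    number ``Ne' = 70/Re + 25/Re**0.6 + 1.5/Re**0.2``.  Valid in phase only;
    a warning is emitted otherwise.  At high Re the correlation scales
    roughly as ``n**2.8``.
    """
    verdict = in_phase(spec)
    if not verdict["in_phase"]:
        warnings.warn(
            "operating point is out of phase; the unbaffled-flask power "
            "correlation is not valid there",
            stacklevel=2,
        )
    n, d = spec.shaking_frequency, spec.max_inner_diameter
    re = spec.fluid.density * n * d**2 / spec.fluid.dynamic_viscosity
    if re <= 0:
        raise ValueError("flask Reynolds number must be > 0")
    ne_mod = 70.0 / re + 25.0 / re**0.6 + 1.5 / re**0.2
    return ne_mod * spec.fluid.density * n**3 * d**4 / spec.fill_volume ** (2.0 / 3.0)


def reynolds_stirred(spec: StirredSpec) -> float:
    """Modified impeller Reynolds number ``rho*N*ds**2/eta`` (= N*ds**2/nu)."""
    return (
        spec.fluid.density
        * spec.stirrer_speed
        * spec.stirrer_diameter**2
        / spec.fluid.dynamic_viscosity
    )


def newton_number(power: float, spec: StirredSpec) -> float:
    """Newton (power) number ``Ne = P / (rho * N**3 * ds**5)``."""
    if spec.stirrer_speed == 0:
        raise ValueError("stirrer speed must be nonzero")
    return power / (
        spec.fluid.density * spec.stirrer_speed**3 * spec.stirrer_diameter**5
    )


def tip_speed(n: float, ds: float) -> float:
    """Stirrer tip speed ``pi * ds * N`` [m/s]."""
    if n < 0 or ds <= 0:
        raise ValueError("need n >= 0 and ds > 0")
    return pi * ds * n


def maschke_power(
    vtip: float, coefficient: float = 131.79, exponent: float = 2.7670
) -> float:
    """Specific power input from tip speed, ``P/V = a * v_tip**b`` [W/m^3].

    Default coefficients are the published fit for a 3-blade segment
    impeller (ds = 85 mm) at 4 L working volume.
    """
    if vtip < 0:
        raise ValueError("tip speed must be >= 0")
    if vtip == 0:
        return 0.0
    return coefficient * vtip**exponent


def max_supported_vcd(spec: OxygenSpec) -> float:
    """Oxygen-transfer-limited viable cell density [cells/mL].

    Equates OTR and OUR: ``cx = kLa * (c_star - c_bulk) / qO2``; the
    mol/L-based quotient gives cells per litre, converted to cells/mL.
    """
    cells_per_litre = spec.kla * (spec.c_star - spec.c_bulk) / spec.qo2
    return cells_per_litre / 1000.0


def water_vapor_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water [atm] (Buck equation)."""
    t_c = temperature - 273.15
    p_kpa = 0.61121 * exp((18.678 - t_c / 234.5) * (t_c / (257.14 + t_c)))
    return p_kpa / 101.325


def o2_solubility(
    temperature: float,
    po2: float = 0.2095,
    x_co2: float = 0.0,
    relative_humidity: float = 0.0,
    total_pressure: float = 1.0,
) -> float:
    """Oxygen solubility in water [mol/L] at ``po2`` [atm] partial pressure.

    Henry-law solubility with the Tromans temperature correlation

        c = p_eff * exp{[0.046*T^2 + 203.357*T*ln(T/298)
                         - (299.378 + 0.092*T)*(T - 298) - 20591] / (8.3144*T)}

    valid for 273 K < T < 373 K; strictly linear in the effective partial
    pressure.  The default gas phase is dry air at 1 atm
    (``po2 = 0.2095`` atm).  Head-space humidity and CO2 enrichment dilute
    the oxygen: with nonzero ``x_co2`` / ``relative_humidity`` the partial
    pressure becomes
    ``(1 - x_co2 - RH * p_H2O(T) / P_total) * po2 / 0.2095 * 0.2095``,
    i.e. the dry mole fraction is scaled down by the diluents.
    """
    t = temperature
    if not 273.0 < t < 373.0:
        raise ValueError("temperature must be within (273, 373) K")
    if po2 < 0:
        raise ValueError("po2 must be >= 0")
    if not 0 <= x_co2 < 1 or not 0 <= relative_humidity <= 1:
        raise ValueError("x_co2 in [0, 1) and relative_humidity in [0, 1] required")
    dilution = 1.0 - x_co2 - relative_humidity * water_vapor_pressure(t) / total_pressure
    if dilution <= 0:
        raise ValueError("diluents leave no room for oxygen in the gas phase")
    p_eff = po2 * dilution
    exponent = (
        0.046 * t**2
        + 203.357 * t * log(t / 298.0)
        - (299.378 + 0.092 * t) * (t - 298.0)
        - 20.591e3
    ) / (8.3144 * t)
    return p_eff * exp(exponent)
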