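"""Aqueductal hydrodynamics: Womersley number and Hagen-Poiseuille relations.

Oscillatory CSF flow through the aqueduct of Sylvius is governed by the
dimensionless Womersley number ``Wo = d_h * sqrt(rho * omega / mu)``, and the
steady pressure-flow relation of a narrow duct by the Hagen-Poiseuille law
``Q = pi R^4 dP / (8 eta L)``, whose hydraulic resistance is
``R_hyd = 8 eta L / (pi R^4)``.  These explain why the aqueductal stroke
volume need not track ventricular volume: it depends on the duct's own
section, not on the ventricles upstream.

All quantities are in SI units (``d_h`` is the hydraulic *diameter*, m); any
other self-consistent unit system yields the same dimensionless Womersley
number.  The resistance is named ``R_hyd``/"hydraulic resistance" to avoid
collision with the Reynolds number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "WomersleyParams",
    "AqueductModel",
    "womersley",
    "poiseuille_flow",
    "aqueduct_resistance",
    "pressure_gradient",
]


@dataclass(frozen=True)
class WomersleyParams:
    """Inputs of the Womersley number, SI units."""

    d_h: float  # hydraulic diameter, m
    rho: float  # fluid density, kg/m^3
    omega: float  # angular cardiac frequency, rad/s
    mu: float  # dynamic viscosity, Pa s

    def __post_init__(self) -> None:
        for name in ("d_h", "rho", "omega", "mu"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


def womersley(params: WomersleyParams) -> float:
    """``Wo = d_h * sqrt(rho * omega / mu)`` (dimensionless)."""
    return params.d_h * math.sqrt(params.rho * params.omega / params.mu)


@dataclass(frozen=True)
class AqueductModel:
    """A straight circular duct: radius, length, fluid viscosity (SI)."""

    radius: float  # m
    length: float  # m
    viscosity: float  # Pa s

    def __post_init__(self) -> None:
        for name in ("radius", "length", "viscosity"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    def resistance(self) -> float:
        return aqueduct_resistance(self)

    def flow(self, pressure_drop: float) -> float:
        return poiseuille_flow(self, pressure_drop)

    def pressure_gradient(self, flow_rate: float) -> float:
        return pressure_gradient(self, flow_rate)


def poiseuille_flow(model: AqueductModel, pressure_drop: float) -> float:
    """Hagen-Poiseuille flow rate ``Q = pi R^4 dP / (8 eta L)`` (m^3/s)."""
    return math.pi * model.radius**4 * pressure_drop / (8.0 * model.viscosity * model.length)


def aqueduct_resistance(model: AqueductModel) -> float:
    """Hydraulic resistance ``R_hyd = 8 eta L / (pi R^4)`` (Pa s/m^3)."""
    return 8.0 * model.viscosity * model.length / (math.pi * model.radius**4)


def pressure_gradient(model: AqueductModel, flow_rate: float) -> float:
    """Pressure loss ``dP = Q * R_hyd`` (Pa) needed to drive ``flow_rate``."""
    return flow_rate * aqueduct_resistance(model)
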