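"""Pure electromechanical relations for planar lipid bilayers.

A free-standing planar bilayer is modeled as a parallel-plate capacitor
whose dielectric is the hydrophobic acyl-chain core:

.. math:: C = \\varepsilon_0 \\varepsilon_r A / d

An applied potential :math:`\\psi` compresses the film (electrostriction)
and, on oil-stabilized platforms, also grows its area by recruiting lipid
from the surrounding Plateau border.  The voltage-dependent capacitance
:math:`C_\\psi = C_0(1 + \\alpha\\psi^2)` then mixes both effects; recasting
the measured capacitance at the membrane's *initial volume*
(:func:`constant_volume_capacitance`) isolates the thickness change, and the
fitted proportionality constant :math:`\\alpha` yields the transverse
Young's modulus

.. math:: E_\\perp = C_m / (\\alpha d_0)

Thin-plate linear elasticity finally converts the modulus to an
area-expansion modulus :math:`K_A = E_\\perp d/(1-v)` and bending rigidity
:math:`k_c = K_A d^2 / (24(1+v))`.

All functions are pure, operate in SI units, and accept floats or numpy
arrays (broadcasting elementwise).  Unit conversions (mV, pF, nm, ...)
belong at I/O boundaries, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Vacuum permittivity, F/m (CODATA, 5 significant figures).
VACUUM_PERMITTIVITY = 8.8542e-12

#: Default relative permittivity of the hydrophobic bilayer core.
DEFAULT_DIELECTRIC_CONSTANT = 2.5

#: Default Poisson ratio (incompressible material).
DEFAULT_POISSON_RATIO = 0.5

#: Default factor relating fitted slope to alpha: alpha = m / (factor * C0).
DEFAULT_SLOPE_FACTOR = 3.0


def _require_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise DomainError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class MembraneGeometry:
    """Static geometry of a planar bilayer capacitor.

    Parameters
    ----------
    area:
        Bilayer area ``A`` in m².
    thickness:
        Hydrophobic thickness ``d`` in m.
    dielectric_constant:
        Relative permittivity of the acyl-chain core (dimensionless).
    vacuum_permittivity:
        ``epsilon_0`` in F/m; fixed by default.
    """

    area: float
    thickness: float
    dielectric_constant: float = DEFAULT_DIELECTRIC_CONSTANT
    vacuum_permittivity: float = VACUUM_PERMITTIVITY

    def __post_init__(self) -> None:
        _require_positive("area", self.area)
        _require_positive("thickness", self.thickness)
        _require_positive("dielectric_constant", self.dielectric_constant)


@dataclass(frozen=True)
class ElasticConstants:
    """Elastic constants of a bilayer treated as a thin plate.

    ``young_modulus`` is the transverse modulus E⊥ in Pa,
    ``area_expansion_modulus`` K_A in N/m, ``bending_rigidity`` k_c in J.
    """

    young_modulus: float
    poisson_ratio: float = DEFAULT_POISSON_RATIO
    area_expansion_modulus: float | None = None
    bending_rigidity: float | None = None

    def __post_init__(self) -> None:
        _require_positive("young_modulus", self.young_modulus)
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise DomainError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio!r}"
            )


@dataclass(frozen=True)
class ElectrostrictionConstants:
    """Zero-field reference quantities and the electrostriction constant.

    ``specific_capacitance`` is C_m = C0/A0 in F/m²; ``alpha`` the
    voltage-dependence constant in V⁻²; ``slope`` the fitted slope m of
    capacitance against ψ² in F/V²; ``slope_factor`` relates them as
    alpha = m / (slope_factor * C0).
    """

    specific_capacitance: float
    alpha: float
    zero_field_capacitance: float
    zero_field_thickness: float
    zero_field_volume: float
    slope: float | None = None
    slope_factor: float = DEFAULT_SLOPE_FACTOR

    def __post_init__(self) -> None:
        _require_positive("specific_capacitance", self.specific_capacitance)
        _require_positive("zero_field_capacitance", self.zero_field_capacitance)
        _require_positive("zero_field_thickness", self.zero_field_thickness)
        _require_positive("zero_field_volume", self.zero_field_volume)


def capacitance_planar(geometry: MembraneGeometry):
    """Parallel-plate capacitance ``epsilon_0 * epsilon_r * A / d`` in F."""
    return (
        geometry.vacuum_permittivity
        * geometry.dielectric_constant
        * geometry.area
        / geometry.thickness
    )


def thickness_from_capacitance(
    capacitance,
    area,
    dielectric_constant: float = DEFAULT_DIELECTRIC_CONSTANT,
):
    """Invert the plate-capacitor relation: ``d = epsilon_0 epsilon_r A / C``.

    Exact inverse of :func:`capacitance_planar` for matching area and
    dielectric constant.
    """
    _require_positive("capacitance", capacitance)
    _require_positive("area", area)
    _require_positive("dielectric_constant", dielectric_constant)
    return VACUUM_PERMITTIVITY * dielectric_constant * area / capacitance


def capacitance_from_volume(
    volume,
    thickness,
    dielectric_constant: float = DEFAULT_DIELECTRIC_CONSTANT,
):
    """Capacitance in the volume form ``epsilon_0 epsilon_r V / d**2``.

    With ``V = A*d`` this is algebraically identical to
    :func:`capacitance_planar`; writing it in terms of volume makes the
    constant-volume correction a one-line substitution.
    """
    _require_positive("volume", volume)
    _require_positive("thickness", thickness)
    _require_positive("dielectric_constant", dielectric_constant)
    return VACUUM_PERMITTIVITY * dielectric_constant * volume / thickness**2


def constant_volume_capacitance(
    zero_field_volume,
    field_thickness,
    dielectric_constant: float = DEFAULT_DIELECTRIC_CONSTANT,
):
    """Capacitance the membrane would have if only thickness had changed.

    ``C_psi = epsilon_0 epsilon_r V0 / d_psi**2`` evaluates the volume form
    at the *zero-field* volume ``V0`` and the measured field thickness
    ``d_psi``; area growth under the field is thereby excluded from the
    capacitance change.  Equals the zero-field capacitance when
    ``d_psi == d0``.
    """
    return capacitance_from_volume(
        zero_field_volume, field_thickness, dielectric_constant
    )


def young_modulus_hianik(
    specific_capacitance,
    applied_potential,
    thickness_decrease,
):
    """Legacy modulus estimator from a single compression step.

    From the electrostriction balance ``delta_d = C_m psi**2 / (2 E)``,
    so ``E = C_m psi**2 / (2 delta_d)`` in Pa.  Assumes constant membrane
    volume implicitly; the constant-volume route corrects that assumption.
    """
    _require_positive("specific_capacitance", specific_capacitance)
    _require_positive("thickness_decrease", thickness_decrease)
    if np.any(np.asarray(applied_potential) == 0):
        raise DomainError("applied_potential must be non-zero")
    return (
        specific_capacitance * np.asarray(applied_potential) ** 2
        / (2.0 * thickness_decrease)
    )


def alpha_from_slope(
    slope,
    zero_field_capacitance,
    slope_factor: float = DEFAULT_SLOPE_FACTOR,
):
    """Electrostriction constant from the fitted slope: ``m / (factor * C0)``.

    The slope ``m`` comes from regressing constant-volume capacitance on the
    squared potential.  ``slope_factor`` defaults to 3.
    """
    _require_positive("zero_field_capacitance", zero_field_capacitance)
    _require_positive("slope_factor", slope_factor)
    return slope / (slope_factor * zero_field_capacitance)


def young_modulus_alvarez(
    specific_capacitance,
    alpha,
    zero_field_thickness,
):
    """Constant-volume Young's modulus ``E = C_m / (alpha * d0)`` in Pa.

    (F/m²) / (V⁻² · m) = F·V²/m³ = J/m³ = Pa.
    """
    _require_positive("specific_capacitance", specific_capacitance)
    _require_positive("zero_field_thickness", zero_field_thickness)
    if not np.all(np.asarray(alpha) > 0):
        raise DomainError(
            "alpha must be positive (capacitance did not increase with voltage)"
        )
    return specific_capacitance / (np.asarray(alpha) * zero_field_thickness)


def area_expansion_modulus(
    young_modulus,
    thickness,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
):
    """Thin-plate area-expansion modulus ``K_A = E * d / (1 - v)`` in N/m."""
    _require_positive("young_modulus", young_modulus)
    _require_positive("thickness", thickness)
    if np.any(np.asarray(poisson_ratio) >= 1):
        raise DomainError(f"poisson_ratio must be < 1, got {poisson_ratio!r}")
    return np.asarray(young_modulus) * thickness / (1.0 - poisson_ratio)


def bending_rigidity(
    area_expansion_modulus,
    thickness,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
):
    """Bending rigidity ``k_c = K_A * d**2 / (24 (1 + v))`` in J.

    Composed with :func:`area_expansion_modulus` this is
    ``k_c = E d**3 / (24 (1 - v)(1 + v))``, i.e. ``E d**3 / 18`` for an
    incompressible plate (v = 0.5).
    """
    _require_positive("area_expansion_modulus", area_expansion_modulus)
    _require_positive("thickness", thickness)
    return (
        np.asarray(area_expansion_modulus)
        * thickness**2
        / (24.0 * (1.0 + poisson_ratio))
    )
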