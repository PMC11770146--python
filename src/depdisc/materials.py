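"""Dielectric materials, particles and suspensions.

These are the inputs to the Clausius–Mossotti factor and the drag/centrifugal
terms of the trajectory model.  A material is characterised by its real
relative permittivity ``epsilon_r`` and its conductivity ``sigma`` (S/m); the
frequency-dependent complex permittivity is derived from the two in
:func:`depdisc.dep.complex_permittivity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import InvalidGeometryError

#: Vacuum permittivity, F/m (CODATA 2018).
EPSILON_0 = 8.8541878128e-12


@dataclass(frozen=True)
class DielectricMaterial:
    """A homogeneous linear dielectric with ohmic loss.

    Parameters
    ----------
    epsilon_r :
        Relative permittivity (dimensionless, ≥ 1 for ordinary media; values
        below 1 trigger a warning but are accepted, since *effective* media
        can fall outside the physical range).
    sigma :
        Electrical conductivity in S/m.  For colloidal particles this is the
        effective conductivity including surface conduction, which for
        micron-scale beads in low-ionic-strength water dominates the bulk value.
    name :
        Optional human-readable label.
    """

    epsilon_r: float
    sigma: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.epsilon_r < 1.0:
            warnings.warn(
                f"relative permittivity {self.epsilon_r} < 1 is unphysical for a "
                "passive medium; proceeding (may be an effective value)",
                stacklevel=2,
            )
        if self.sigma < 0.0:
            raise InvalidGeometryError(f"conductivity must be >= 0, got {self.sigma}")

    @property
    def epsilon(self) -> float:
        """Absolute real permittivity ε = ε_r·ε0, F/m."""
        return self.epsilon_r * EPSILON_0


@dataclass(frozen=True)
class SphericalParticle:
    """A homogeneous dielectric sphere of radius ``radius`` (m)."""

    radius: float
    material: DielectricMaterial

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise InvalidGeometryError(f"particle radius must be > 0, got {self.radius}")

    @property
    def volume(self) -> float:
        """Particle volume (4/3)πr³, m³."""
        import math

        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class Suspension:
    """A particle suspended in a viscous liquid medium.

    ``viscosity`` is the dynamic viscosity of the medium (Pa·s); the densities
    (kg/m³) set the buoyant mass used by the centrifugal body force.
    """

    particle: SphericalParticle
    medium: DielectricMaterial
    viscosity: float = 1.0e-3
    density_particle: float = 1050.0
    density_medium: float = 1000.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0.0:
            raise InvalidGeometryError(f"viscosity must be > 0, got {self.viscosity}")
        if self.density_particle <= 0.0 or self.density_medium <= 0.0:
            raise InvalidGeometryError("densities must be > 0")

    @property
    def drag_coefficient(self) -> float:
        """Stokes drag coefficient 6πµr, N·s/m."""
        import math

        return 6.0 * math.pi * self.viscosity * self.particle.radius

    @property
    def buoyant_mass_factor(self) -> float:
        """(4/3)πr³·(ρ_p − ρ_m), kg — multiplies ω²R to give the centrifugal force."""
        return self.particle.volume * (self.density_particle - self.density_medium)


# Material presets used by the shipped fixtures. Only the bead diameter is a
# measured quantity; the dielectric values are standard/effective numbers chosen
# once and documented in docs/methods.md.
WATER_DI = DielectricMaterial(epsilon_r=80.0, sigma=2.0e-4, name="DI water (practical)")
POLYSTYRENE_BEAD = DielectricMaterial(
    epsilon_r=2.55, sigma=0.1, name="polystyrene bead (effective, surface-conduction dominated)"
)
YEAST_EFFECTIVE = DielectricMaterial(
    epsilon_r=60.0, sigma=0.25, name="baker's yeast (effective homogeneous placeholder)"
)
FR4 = DielectricMaterial(epsilon_r=4.5, sigma=0.0, name="FR4 substrate")
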