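"""Dielectrophoresis physics: complex permittivity, Clausius–Mossotti factor, DEP force.

The time-averaged dielectrophoretic force on a homogeneous dielectric sphere
of radius r in a medium of permittivity ε_m is

    F_DEP = 2π r³ ε_m Re[K(f)] ∇|E|²

where K(f) = (ε_p* − ε_m*)/(ε_p* + 2 ε_m*) is the Clausius–Mossotti factor
built from the complex permittivities ε*(f) = ε − jσ/(2πf).  Re[K] lies in
[−1/2, 1] for homogeneous spheres: positive values (pDEP) pull the particle
toward field maxima at electrode edges, negative values (nDEP) push it toward
field minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .materials import DielectricMaterial, SphericalParticle

__all__ = [
    "CMSpectrum",
    "complex_permittivity",
    "clausius_mossotti",
    "cm_spectrum",
    "crossover_frequency",
    "dep_force",
]


@dataclass(frozen=True)
class CMSpectrum:
    """Clausius–Mossotti factor sampled over a frequency grid."""

    frequencies: np.ndarray  # Hz
    k_complex: np.ndarray

    @property
    def re_k(self) -> np.ndarray:
        return self.k_complex.real

    @property
    def im_k(self) -> np.ndarray:
        return self.k_complex.imag

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"frequency_hz": self.frequencies, "re_k": self.re_k, "im_k": self.im_k}
        )


def complex_permittivity(material: DielectricMaterial, f):
    """Complex permittivity ε*(f) = ε − jσ/(2πf), in F/m.

    ``f`` may be a scalar or array of frequencies in Hz (all > 0).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0.0):
        raise DomainError("frequency must be > 0")
    eps = material.epsilon - 1j * material.sigma / (2.0 * np.pi * f_arr)
    return complex(eps) if f_arr.ndim == 0 else eps


def clausius_mossotti(particle: SphericalParticle, medium: DielectricMaterial, f):
    """Complex Clausius–Mossotti factor K(f) = (ε_p* − ε_m*)/(ε_p* + 2 ε_m*)."""
    ep = complex_permittivity(particle.material, f)
    em = complex_permittivity(medium, f)
    denom = ep + 2.0 * em
    if np.any(np.abs(np.asarray(denom)) == 0.0):
        raise DomainError("singular Clausius–Mossotti denominator (ε_p* + 2ε_m* = 0)")
    return (ep - em) / denom


def cm_spectrum(
    particle: SphericalParticle,
    medium: DielectricMaterial,
    f_min: float,
    f_max: float,
    n_points: int = 200,
) -> CMSpectrum:
    """Sample K(f) on a log-spaced grid over [f_min, f_max]."""
    if not (0.0 < f_min < f_max):
        raise DomainError("need 0 < f_min < f_max")
    if n_points < 2:
        raise DomainError("need n_points >= 2")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    k = clausius_mossotti(particle, medium, freqs)
    return CMSpectrum(frequencies=freqs, k_complex=np.asarray(k))


def _re_k_plateaus(particle: SphericalParticle, medium: DielectricMaterial) -> tuple[float, float]:
    """Low- and high-frequency limits of Re[K]: conductivity- and permittivity-dominated."""
    sp, sm = particle.material.sigma, medium.sigma
    ep, em = particle.material.epsilon, medium.epsilon
    low = (sp - sm) / (sp + 2.0 * sm) if (sp + 2.0 * sm) > 0.0 else 0.0
    high = (ep - em) / (ep + 2.0 * em)
    return low, high


def crossover_frequency(
    particle: SphericalParticle,
    medium: DielectricMaterial,
    f_min: float = 1e2,
    f_max: float = 1e12,
    rtol: float = 1e-6,
) -> float | None:
    """Frequency at which Re[K(f)] changes sign, or None if it never does.

    The single-relaxation (Maxwell–Wagner) form of K(f) for homogeneous
    spheres is monotone between its two plateaus, so a sign change between
    the plateau values implies exactly one root; it is bracketed on a coarse
    log grid and refined by bisection in log-frequency.
    """
    low, high = _re_k_plateaus(particle, medium)
    if low == 0.0 and high == 0.0:
        return None
    if np.sign(low) == np.sign(high) or low == 0.0 or high == 0.0:
        return None

    grid = np.logspace(np.log10(f_min), np.log10(f_max), 256)
    re = np.asarray(clausius_mossotti(particle, medium, grid)).real
    sign_change = np.nonzero(np.diff(np.sign(re)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    lo, hi = np.log10(grid[i]), np.log10(grid[i + 1])
    f_lo = re[i]
    while (hi - lo) > rtol:
        mid = 0.5 * (lo + hi)
        v = clausius_mossotti(particle, medium, 10.0**mid).real
        if np.sign(v) == np.sign(f_lo):
            lo = mid
        else:
            hi = mid
    return float(10.0 ** (0.5 * (lo + hi)))


def dep_force(
    particle: SphericalParticle,
    medium: DielectricMaterial,
    f: float,
    grad_e_sq,
) -> np.ndarray:
    """Time-averaged DEP force vector F = 2πr³ε_m·Re[K(f)]·∇|E|², in N.

    ``grad_e_sq`` is the gradient of the squared field magnitude (V²/m³),
    any shape with the vector components on the last axis.  The force is
    parallel to ∇|E|² for Re[K] > 0 and antiparallel for Re[K] < 0.
    """
    re_k = clausius_mossotti(particle, medium, f).real
    prefactor = 2.0 * np.pi * particle.radius**3 * medium.epsilon * re_k
    return prefactor * np.asarray(grad_e_sq, dtype=float)
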