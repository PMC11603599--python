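"""Analytic pair potentials with closed-form second virial coefficients.

These potentials supply the ground truth for the synthetic-data route: in
the low-density (dilute) limit the radial distribution function of a pair
potential ``u(r)`` is ``g(r) = exp(-beta * u(r))``, for which the
McMillan-Mayer integral

    B2 = -2 pi N_A \\int_0^inf [g(r) - 1] r^2 dr

reduces exactly to the potential's second virial coefficient.  Hard-sphere
and square-well potentials have textbook closed forms; the Lennard-Jones
value is obtained by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import integrate

from .units import DEFAULT_BETA, NM3_TO_L_PER_MOL

__all__ = [
    "PotentialKind",
    "PairPotentialModel",
    "IntegrationFailure",
    "closed_form_b2",
]


class PotentialKind(str, Enum):
    HARD_SPHERE = "hard_sphere"
    SQUARE_WELL = "square_well"
    LENNARD_JONES = "lennard_jones"


class IntegrationFailure(RuntimeError):
    """Raised when the quadrature for a virial integral does not converge."""


@dataclass(frozen=True)
class PairPotentialModel:
    """Spherically symmetric pair potential.

    Parameters
    ----------
    kind:
        One of ``hard_sphere``, ``square_well``, ``lennard_jones``.
    sigma:
        Particle diameter / LJ size parameter in nm.
    epsilon:
        Interaction energy in kJ/mol (well depth; 0 for hard spheres).
    well_range:
        Outer range of the square well as a multiple of ``sigma``
        (square well only; must exceed 1).
    beta:
        Inverse temperature in mol/kJ.  Defaults to 300 K.
    """

    kind: PotentialKind
    sigma: float
    epsilon: float = 0.0
    well_range: float | None = None
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        kind = PotentialKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if kind is PotentialKind.SQUARE_WELL:
            if self.well_range is None or self.well_range <= 1:
                raise ValueError(
                    "square_well requires well_range > 1, got "
                    f"{self.well_range}"
                )
        if kind is PotentialKind.LENNARD_JONES and self.epsilon < 0:
            raise ValueError("lennard_jones epsilon must be >= 0")

    def energy(self, r: np.ndarray) -> np.ndarray:
        """Potential energy u(r) in kJ/mol; +inf inside a hard core."""
        r = np.asarray(r, dtype=float)
        if self.kind is PotentialKind.HARD_SPHERE:
            return np.where(r < self.sigma, np.inf, 0.0)
        if self.kind is PotentialKind.SQUARE_WELL:
            u = np.zeros_like(r)
            u[r < self.sigma * self.well_range] = -self.epsilon
            u[r < self.sigma] = np.inf
            return u
        # Lennard-Jones; u diverges at r=0.
        with np.errstate(divide="ignore", over="ignore"):
            sr6 = (self.sigma / r) ** 6
            u = 4.0 * self.epsilon * (sr6 * sr6 - sr6)
        return np.where(r > 0, u, np.inf)

    def boltzmann_factor(self, r: np.ndarray) -> np.ndarray:
        """exp(-beta u(r)); zero inside a hard core."""
        u = self.energy(r)
        with np.errstate(over="ignore"):
            out = np.exp(-self.beta * np.asarray(u, dtype=float))
        return np.where(np.isinf(u), 0.0, out)


def closed_form_b2(potential: PairPotentialModel, rtol: float = 1e-8) -> float:
    """Second virial coefficient of a pair potential, in L/mol.

    Hard-sphere and square-well values use the closed forms

        B2_HS = (2 pi / 3) N_A sigma^3
        B2_SW = B2_HS * [1 - (e^{beta eps} - 1)(lambda^3 - 1)]

    (``lambda`` the well range in units of sigma).  For Lennard-Jones the
    integral ``-2 pi N_A \\int (e^{-beta u} - 1) r^2 dr`` is evaluated by
    adaptive quadrature to relative tolerance ``rtol``.

    Raises
    ------
    IntegrationFailure
        If the Lennard-Jones quadrature reports an error estimate above
        the requested tolerance.
    """
    sigma = potential.sigma
    hs = (2.0 * math.pi / 3.0) * sigma**3 * NM3_TO_L_PER_MOL
    if potential.kind is PotentialKind.HARD_SPHERE:
        return hs
    if potential.kind is PotentialKind.SQUARE_WELL:
        be = potential.beta * potential.epsilon
        lam3 = potential.well_range**3
        return hs * (1.0 - math.expm1(be) * (lam3 - 1.0))

    def integrand(r: float) -> float:
        return (float(potential.boltzmann_factor(np.array(r))) - 1.0) * r * r

    # Split at sigma where the integrand turns over; the tail decays ~r^-4.
    val1, err1 = integrate.quad(integrand, 0.0, sigma, epsrel=rtol, epsabs=0.0, limit=200)
    val2, err2 = integrate.quad(
        integrand, sigma, np.inf, epsrel=rtol, epsabs=0.0, limit=200
    )
    total = val1 + val2
    err = err1 + err2
    if not np.isfinite(total) or (total != 0 and err > 10 * rtol * abs(total)):
        raise IntegrationFailure(
            f"virial quadrature did not converge: value={total}, "
            f"error={err}, rtol={rtol}"
        )
    return -2.0 * math.pi * total * NM3_TO_L_PER_MOL
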