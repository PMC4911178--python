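"""Pairwise nucleus-nucleus and nucleus-membrane interaction potential.

Distances are measured centre-to-centre in units of one nuclear diameter, so
two nuclei touch at separation 1.  The potential has three regimes:

* ``x < 1`` — overlapping nuclei, strong harmonic repulsion;
* ``1 <= x <= 1 + R`` — the adhesive shell of width ``R`` in which nuclei
  stick together, a quadratic well of depth ``S``;
* ``x > 1 + R`` — no interaction.

The potential is continuous everywhere (the well branch meets the repulsive
branch at ``V(1) = -S``); its derivative has a kink at ``x = 1``, which is
acceptable because only the three force regimes matter for the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PotentialSpec", "pair_potential", "pair_force", "membrane_force"]


@dataclass(frozen=True)
class PotentialSpec:
    """Parameters of the contact potential.

    Parameters
    ----------
    repulsion_stiffness : float
        Harmonic stiffness of the overlap repulsion (energy per squared
        nuclear diameter).  Default 100, two orders of magnitude above the
        default well depth so the hard core dominates adhesion.
    adhesion_strength : float
        Well depth ``S`` ("stickiness") holding two contacting nuclei
        together.  ``S = 0`` removes the adhesive well entirely.
    shell_width : float
        Width ``R`` of the adhesive shell in nuclear diameters; nuclei whose
        centres are within ``1 + R`` of each other interact (and are counted
        as connected by the clustering stage).
    """

    repulsion_stiffness: float = 100.0
    adhesion_strength: float = 1.0
    shell_width: float = 0.05

    def __post_init__(self) -> None:
        if not self.repulsion_stiffness > 0:
            raise ValueError("repulsion_stiffness must be positive")
        if not self.shell_width > 0:
            raise ValueError("shell_width must be positive")
        if self.adhesion_strength < 0:
            raise ValueError("adhesion_strength must be non-negative")

    @property
    def cutoff(self) -> float:
        """Interaction radius ``1 + R`` beyond which the potential vanishes."""
        return 1.0 + self.shell_width


def _check_separation(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("separation must be positive (centres cannot coincide)")
    return x


def pair_potential(separation, spec: PotentialSpec = PotentialSpec()):
    """Pair potential V(x) at centre-to-centre separation x (diameters).

    Piecewise: ``k_rep*(1-x)^2 - S`` for ``x < 1``;
    ``-S*(1 - (x-1)/R)^2`` for ``1 <= x <= 1+R``; ``0`` beyond.
    Vectorised over ``separation``.
    """
    x = _check_separation(separation)
    k, S, R = spec.repulsion_stiffness, spec.adhesion_strength, spec.shell_width
    v = np.zeros_like(x)
    core = x < 1.0
    shell = (x >= 1.0) & (x <= 1.0 + R)
    v = np.where(core, k * (1.0 - x) ** 2 - S, v)
    v = np.where(shell, -S * (1.0 - (x - 1.0) / R) ** 2, v)
    return v if v.ndim else float(v)


def pair_force(separation, spec: PotentialSpec = PotentialSpec()):
    """Signed radial force ``-dV/dx``; positive = repulsive.

    Repulsive (``2*k_rep*(1-x)``) inside the core, attractive
    (``-(2S/R)*(1-(x-1)/R)``) in the adhesive shell, zero beyond ``1+R``.
    """
    x = _check_separation(separation)
    k, S, R = spec.repulsion_stiffness, spec.adhesion_strength, spec.shell_width
    f = np.zeros_like(x)
    core = x < 1.0
    shell = (x >= 1.0) & (x <= 1.0 + R)
    f = np.where(core, 2.0 * k * (1.0 - x), f)
    f = np.where(shell, -(2.0 * S / R) * (1.0 - (x - 1.0) / R), f)
    return f if f.ndim else float(f)


def membrane_force(nucleus_centre, domain, spec: PotentialSpec = PotentialSpec()):
    """Harmonic wall repulsion on a nucleus centre from the domain boundaries.

    A force of stiffness ``repulsion_stiffness`` acts along the inward normal
    whenever the clearance to a boundary (flat lower membrane ``y = 0``,
    corrugated upper membrane ``y = T + h(x)``, or the end walls at
    ``x = 0`` and ``x = L``) drops below the nuclear radius 0.5.  The
    clearance to the upper membrane is taken as the vertical distance — an
    approximation justified by the slow variation of the boundary profile
    (bounded by 0.75 diameters over a 250-diameter domain).

    Parameters
    ----------
    nucleus_centre : (2,) array-like
        Centre position in nuclear diameters.
    domain : synclust.boundary.SyncytiumDomain
        Geometry providing ``length`` and ``height_at(x)``.

    Returns
    -------
    (2,) ndarray of the force vector.
    """
    x, y = float(nucleus_centre[0]), float(nucleus_centre[1])
    k = spec.repulsion_stiffness
    fx = fy = 0.0
    if y < 0.5:  # lower membrane
        fy += k * (0.5 - y)
    upper = domain.height_at(x)
    if upper - y < 0.5:  # upper membrane (vertical clearance)
        fy -= k * (0.5 - (upper - y))
    if x < 0.5:  # end walls
        fx += k * (0.5 - x)
    if domain.length - x < 0.5:
        fx -= k * (0.5 - (domain.length - x))
    return np.array([fx, fy])
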