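"""Cosine-transform coefficients of the circular source and sink disks.

The lateral dependence of the concentration field is expanded in the even
periodic basis cos(2*l*pi*x/Lx) cos(2*m*pi*y/Ly).  The boundary conditions
involve the indicator function of a disk of radius r centred in the cell,
whose expansion coefficients are

    c_lm = (4 eps_l eps_m / (Lx Ly)) * Int_{rho<r} cos(2 l pi x/Lx)
                                                    cos(2 m pi y/Ly) dx dy

with eps_0 = 1/2 and eps_l = 1 for l > 0.  Two independent routes are
provided: quadrature after analytic y-integration (the production path) and
a Bessel-function closed form (the oracle).  The stored table entries are
the c_lm above, i.e. they include the 4*eps_l*eps_m/(Lx*Ly) prefactor;
formulas that need the bare eps weights divide them back out explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j1

from .params import CleftGeometry, GeometryError

__all__ = [
    "CoefficientTable",
    "disk_cosine_coefficients",
    "closed_form_disk_coefficient",
    "epsilon_weight",
    "epsilon_grid",
]


def epsilon_weight(l: int) -> float:
    """Series weight eps_l: 1/2 for l = 0, 1 otherwise."""
    return 0.5 if l == 0 else 1.0


def epsilon_grid(lmax: int) -> np.ndarray:
    """(lmax+1, lmax+1) grid of the products eps_l * eps_m."""
    e = np.ones(lmax + 1)
    e[0] = 0.5
    return np.outer(e, e)


@dataclass(frozen=True)
class CoefficientTable:
    """Table of disk-indicator cosine coefficients c_lm, 0 <= l,m <= lmax.

    ``values[l, m]`` is the full coefficient including the
    4*eps_l*eps_m/(Lx*Ly) prefactor, so ``values[0, 0]`` equals the disk
    area divided by the cell area.
    """

    radius: float
    lmax: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.lmax + 1, self.lmax + 1):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with lmax={self.lmax}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient table contains non-finite entries")

    def to_dict(self) -> dict:
        """JSON-serialisable representation (debugging aid)."""
        return {
            "radius": self.radius,
            "lmax": self.lmax,
            "values": self.values.tolist(),
        }


def disk_cosine_coefficients(
    radius: float,
    geometry: CleftGeometry,
    lmax: int,
    quad_order: int = 64,
) -> CoefficientTable:
    """Compute the coefficient table for a centred disk by quadrature.

    The y-integration is done analytically: over the quarter disk the inner
    integral is sqrt(r^2 - x^2) for m = 0 and
    (Ly/(2 m pi)) sin(2 m pi sqrt(r^2 - x^2)/Ly) for m > 0.  The remaining
    x-integral is evaluated by Gauss-Legendre quadrature after the
    substitution x = r sin(theta), which removes the square-root branch
    point at x = r and makes the integrand entire, so the quadrature
    converges geometrically in ``quad_order``.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius!r}")
    if lmax < 0:
        raise ValueError(f"lmax must be >= 0, got {lmax}")
    if quad_order < 2:
        raise ValueError(f"quad_order must be >= 2, got {quad_order}")
    if 2 * radius > min(geometry.Lx, geometry.Ly):
        raise GeometryError(
            f"disk of radius {radius} nm does not fit in the unit cell"
        )

    Lx, Ly = geometry.Lx, geometry.Ly
    nodes, weights = leggauss(quad_order)
    theta = 0.25 * np.pi * (nodes + 1.0)  # theta in (0, pi/2)
    wq = 0.25 * np.pi * weights
    x = radius * np.sin(theta)
    h = radius * np.cos(theta)  # sqrt(r^2 - x^2), also the Jacobian dx/dtheta / cos...
    # dx = r cos(theta) dtheta, so the quadrature weight for f(x) dx is wq * h.

    ls = np.arange(lmax + 1)
    # cosx[l, q] = cos(2 l pi x_q / Lx)
    cosx = np.cos(2.0 * np.pi * np.outer(ls, x) / Lx)

    # inner[m, q] = integral over y in (0, sqrt(r^2-x^2)) of cos(2 m pi y/Ly)
    inner = np.empty((lmax + 1, quad_order))
    inner[0] = h
    if lmax > 0:
        ms = np.arange(1, lmax + 1)
        arg = 2.0 * np.pi * np.outer(ms, h) / Ly
        inner[1:] = (Ly / (2.0 * np.pi * ms))[:, None] * np.sin(arg)

    # quarter-disk integral, times 4 for the full disk, times the prefactor
    quarter = (cosx * (wq * h)) @ inner.T  # shape (l, m)
    values = (16.0 / (Lx * Ly)) * epsilon_grid(lmax) * quarter
    return CoefficientTable(radius=radius, lmax=lmax, values=values)


def closed_form_disk_coefficient(
    l: int, m: int, radius: float, geometry: CleftGeometry
) -> float:
    """Bessel closed form for a single coefficient c_lm (independent oracle).

    Writing the basis product as a sum of two plane waves and using
    Int_{rho<r} cos(k.r) dA = 2 pi r J1(|k| r)/|k| gives, for
    (l, m) != (0, 0),

        c_lm = 8 pi eps_l eps_m r J1(k_lm r) / (Lx Ly k_lm),
        k_lm = sqrt((2 pi l/Lx)^2 + (2 pi m/Ly)^2),

    and the area fraction pi r^2/(Lx Ly) for (l, m) = (0, 0).
    """
    if l < 0 or m < 0:
        raise ValueError("l and m must be nonnegative")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius!r}")
    Lx, Ly = geometry.Lx, geometry.Ly
    if l == 0 and m == 0:
        return np.pi * radius**2 / (Lx * Ly)
    k = 2.0 * np.pi * np.hypot(l / Lx, m / Ly)
    eps = epsilon_weight(l) * epsilon_weight(m)
    return 8.0 * np.pi * eps * radius * j1(k * radius) / (Lx * Ly * k)


@lru_cache(maxsize=128)
def cached_table(
    radius: float, geometry: CleftGeometry, lmax: int, quad_order: int
) -> CoefficientTable:
    """Memoised :func:`disk_cosine_coefficients` (tables are reused heavily
    when scanning parameters; callers must not mutate the result)."""
    return disk_cosine_coefficients(radius, geometry, lmax, quad_order)
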