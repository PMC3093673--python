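"""Parameter containers shared across the package.

Units are fixed package-wide: lengths in nm, times in ms, so diffusivities
are nm^2/ms and reactivities nm/ms.  The release amplitude u(t) is carried
in arbitrary units; fluxes J(t) inherit the same arbitrary amplitude factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional


class GeometryError(ValueError):
    """A geometric invariant of the periodic cleft model is violated."""


@dataclass(frozen=True)
class CleftGeometry:
    """Unit cell of the periodic two-membrane cleft.

    The cleft is the space between two parallel membranes a distance ``Lz``
    apart, periodic in the lateral directions with periods ``Lx`` and ``Ly``.
    Each unit cell carries one circular release opening of radius ``R``
    centred on the pre-synaptic face (z = 0) and one circular absorbing sink
    of radius ``a`` centred on the post-synaptic face (z = Lz).  Both disks
    sit at the lateral centre of the cell; off-centre or multiple disks are
    outside the model.

    All lengths in nm.
    """

    Lx: float = 500.0
    Ly: float = 500.0
    Lz: float = 50.0
    R: float = 20.0
    a: float = 10.0

    def __post_init__(self) -> None:
        for name in ("Lx", "Ly", "Lz", "R", "a"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise GeometryError(f"{name} must be strictly positive, got {v!r}")
        lat = min(self.Lx, self.Ly)
        if 2 * self.R > lat:
            raise GeometryError(
                f"release disk (diameter {2 * self.R} nm) does not fit in the "
                f"unit cell (min lateral period {lat} nm)"
            )
        if 2 * self.a > lat:
            raise GeometryError(
                f"sink disk (diameter {2 * self.a} nm) does not fit in the "
                f"unit cell (min lateral period {lat} nm)"
            )

    @property
    def cell_area(self) -> float:
        """Lateral area Lx*Ly of the unit cell (nm^2)."""
        return self.Lx * self.Ly

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TransportParams:
    """Transport and release parameters.

    D     diffusion constant of the ligand in the cleft (nm^2/ms)
    t0    decay constant of the exponential release flux u(t)=exp(-t/t0) (ms)
    kappa optional surface reactivity for the partial-absorption rate
          calculators (nm/ms); ``math.inf`` means fully absorbing.  It does
          not enter the series solution.
    """

    D: float = 1.0e5
    t0: float = 1.0
    kappa: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.D > 0 and math.isfinite(self.D)):
            raise ValueError(f"D must be strictly positive, got {self.D!r}")
        if not (self.t0 > 0 and math.isfinite(self.t0)):
            raise ValueError(f"t0 must be strictly positive, got {self.t0!r}")
        if self.kappa is not None and not self.kappa >= 0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SeriesConfig:
    """Numerical knobs of the series solution.

    lmax        truncation order of the double cosine series (l, m <= lmax)
    quad_order  Gauss-Legendre order for the disk-coefficient quadrature
    stehfest_N  number of terms in the Stehfest inversion (even)
    small_s     Laplace abscissa used for s -> 0 limits (1/ms)
    rel_tol     generic relative tolerance for internal consistency checks
    """

    lmax: int = 40
    quad_order: int = 64
    stehfest_N: int = 14
    small_s: float = 1.0e-8
    rel_tol: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.lmax < 0:
            raise ValueError(f"lmax must be >= 0, got {self.lmax}")
        if self.quad_order < 2:
            raise ValueError(f"quad_order must be >= 2, got {self.quad_order}")
        if self.stehfest_N < 2 or self.stehfest_N % 2:
            raise ValueError(
                f"stehfest_N must be a positive even integer, got {self.stehfest_N}"
            )
        if not self.small_s > 0:
            raise ValueError("small_s must be > 0")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)
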