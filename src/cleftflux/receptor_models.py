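"""Closed-form links between receptor microphysics and the sink parameters.

The absorbing disk of radius ``a`` stands in for a patch of discrete
receptors.  These calculators translate between the two pictures:

* the diffusion-influenced bimolecular rate constant of a single partially
  absorbing disk, 1/k = 1/(4 D a) + 1/(pi kappa a^2);
* the equivalent-disk radius a ~= N_rec a0 matching the capture rate of
  N_rec small absorbing disks (valid for small N_rec, where the rate is
  additive, k ~= 4 N_rec D a0);
* the effective uniform reactivity K of a face homogeneously covered by
  N_rec partially absorbing receptors of radius a0,
  K = N_rec k0 / (S (1 - f_rec)) with
  1/k0 = 1/(4 D a0) + 1/(pi kappa a0^2 (1 - f_rec)).

None of these feed back into the series solution, which keeps the sink
perfectly absorbing; they are parameterisation aids (e.g. matching k to a
measured ligand-receptor binding rate constant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .params import CleftGeometry, GeometryError

__all__ = [
    "ReceptorPatch",
    "binding_rate_constant",
    "equivalent_disk_radius",
    "effective_reactivity",
]


@dataclass(frozen=True)
class ReceptorPatch:
    """A post-synaptic face of area S carrying N_rec receptor disks.

    N_rec  receptors per unit cell
    a0     single-receptor disk radius (nm)
    kappa  intrinsic receptor reactivity (nm/ms); math.inf = fully absorbing
    S      face area Lx*Ly (nm^2)
    """

    N_rec: int
    a0: float
    kappa: float
    S: float

    def __post_init__(self) -> None:
        if self.N_rec < 1:
            raise ValueError(f"N_rec must be >= 1, got {self.N_rec}")
        if not self.a0 > 0:
            raise ValueError(f"a0 must be > 0, got {self.a0}")
        if not self.kappa >= 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not self.S > 0:
            raise ValueError(f"S must be > 0, got {self.S}")
        if not self.f_rec < 1:
            raise GeometryError(
                f"receptor coverage f_rec={self.f_rec:.3f} must be < 1"
            )

    @property
    def f_rec(self) -> float:
        """Fraction of the face covered by receptors, N_rec pi a0^2 / S."""
        return self.N_rec * math.pi * self.a0**2 / self.S


def binding_rate_constant(D: float, a: float, kappa: float) -> float:
    """Bimolecular rate constant k of a partially absorbing disk (nm^3/ms).

    1/k = 1/(4 D a) + 1/(pi kappa a^2).  kappa = inf gives the fully
    absorbing (Hill) limit k = 4 D a; kappa = 0 gives a reflecting disk,
    k = 0 (binding cannot occur), returned rather than raised.
    """
    if not D > 0:
        raise ValueError(f"D must be > 0, got {D}")
    if not a > 0:
        raise ValueError(f"a must be > 0, got {a}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if kappa == 0:
        return 0.0
    inv = 1.0 / (4.0 * D * a)
    if not math.isinf(kappa):
        inv += 1.0 / (math.pi * kappa * a**2)
    return 1.0 / inv


def equivalent_disk_radius(
    N_rec: int, a0: float, geometry: Optional[CleftGeometry] = None
) -> float:
    """Radius of the single absorbing disk equivalent to N_rec receptors.

    Implements the small-N_rec linearisation a = N_rec * a0, which matches
    capture rates since 4 D (N_rec a0) = N_rec (4 D a0).  The growth of a
    saturates at large N_rec, but no closed form is available for that
    regime, so a validity warning is emitted when the equivalent disk
    approaches the unit-cell dimensions.
    """
    if N_rec < 1:
        raise ValueError(f"N_rec must be >= 1, got {N_rec}")
    if not a0 > 0:
        raise ValueError(f"a0 must be > 0, got {a0}")
    a = N_rec * a0
    if geometry is not None and 2.0 * a > 0.5 * min(geometry.Lx, geometry.Ly):
        warnings.warn(
            f"equivalent disk radius {a} nm approaches the unit-cell size; the "
            "linear rule a = N_rec a0 overestimates a in this regime",
            stacklevel=2,
        )
    return a


def effective_reactivity(patch: ReceptorPatch, D: float) -> float:
    """Effective uniform reactivity K of a homogeneously receptor-covered face.

    K = N_rec k0 / (S (1 - f_rec)),
    1/k0 = 1/(4 D a0) + 1/(pi kappa a0^2 (1 - f_rec))   (nm/ms).
    kappa = 0 gives K = 0; kappa = inf gives the diffusion-limited
    k0 = 4 D a0.
    """
    if not D > 0:
        raise ValueError(f"D must be > 0, got {D}")
    one_minus_f = 1.0 - patch.f_rec
    if patch.kappa == 0:
        return 0.0
    inv_k0 = 1.0 / (4.0 * D * patch.a0)
    if not math.isinf(patch.kappa):
        inv_k0 += 1.0 / (math.pi * patch.kappa * patch.a0**2 * one_minus_f)
    k0 = 1.0 / inv_k0
    return patch.N_rec * k0 / (patch.S * one_minus_f)
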