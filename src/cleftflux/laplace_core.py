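"""Laplace-space solution of the periodic two-membrane cleft model.

The concentration transform is expanded as

    C^(r, s) = sum_lm [alpha_lm e^{gamma z} + beta_lm e^{-gamma z}]
               cos(2 l pi x/Lx) cos(2 m pi y/Ly),

    gamma_lm(s) = sqrt(s/D + (2 l pi/Lx)^2 + (2 m pi/Ly)^2).

The release boundary condition at z = 0 fixes D gamma (alpha - beta) =
u^(s) q_lm; the sink is handled by the constant-flux closure: an unknown
uniform flux density Q(s) over the sink disk, fixed by requiring the
disk-averaged concentration at z = Lz to vanish.  That yields

    Q(s) = u^(s) * [sum q_lm p_lm / (eps_l eps_m gamma sinh(gamma Lz))]
                 / [sum p_lm^2 coth(gamma Lz) / (eps_l eps_m gamma)]

and the total sink flux transform J^(s) = pi a^2 Q(s).

All hyperbolic ratios are evaluated through decaying exponentials
(1/sinh x = 2 e^{-x}/(1 - e^{-2x}), coth x = (1 + e^{-2x})/(1 - e^{-2x}))
so no overflow occurs however large gamma*Lz grows; the small-x end uses
expm1 for full precision.  Only real s > 0 is supported — every Stehfest
abscissa is real and positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .coefficients import CoefficientTable, epsilon_grid
from .params import CleftGeometry, SeriesConfig, TransportParams

__all__ = [
    "LaplaceState",
    "gamma_lm",
    "uhat_exponential",
    "Qhat",
    "Jhat",
    "solve_series_coefficients",
    "concentration_hat",
    "disk_average_concentration_hat",
]

ArrayLike = Union[float, np.ndarray]

# u^(s) evaluator: maps real s > 0 (scalar or array) to the release transform
ReleaseTransform = Callable[[ArrayLike], ArrayLike]


def gamma_lm(
    l: int, m: int, s: float, D: float, geometry: CleftGeometry
) -> float:
    """Decay constant gamma_lm(s) of lateral mode (l, m) (1/nm).

    gamma = sqrt(s/D + (2 l pi/Lx)^2 + (2 m pi/Ly)^2); the printed form of
    the eigenvalue carries a stray factor of y inside the m-term, which is
    dimensionally impossible and is dropped here.
    """
    if l < 0 or m < 0:
        raise ValueError("mode indices must be nonnegative")
    if not D > 0:
        raise ValueError("D must be > 0")
    if s < 0:
        raise ValueError("gamma_lm requires s >= 0")
    if s == 0 and l == 0 and m == 0:
        raise ValueError(
            "gamma_00(0) = 0; use the analytic s -> 0 limit instead of the series"
        )
    return float(
        np.sqrt(
            s / D
            + (2.0 * np.pi * l / geometry.Lx) ** 2
            + (2.0 * np.pi * m / geometry.Ly) ** 2
        )
    )


def uhat_exponential(s: ArrayLike, t0: float) -> ArrayLike:
    """Laplace transform of the exponential release flux u(t) = e^{-t/t0}."""
    if not t0 > 0:
        raise ValueError("t0 must be > 0")
    return 1.0 / (np.asarray(s, dtype=float) + 1.0 / t0)


def _gamma_grid(
    s: np.ndarray, D: float, geometry: CleftGeometry, lmax: int
) -> np.ndarray:
    """gamma_lm(s) for all modes; shape s.shape + (lmax+1, lmax+1)."""
    ls = np.arange(lmax + 1)
    kx2 = (2.0 * np.pi * ls / geometry.Lx) ** 2
    ky2 = (2.0 * np.pi * ls / geometry.Ly) ** 2
    k2 = kx2[:, None] + ky2[None, :]
    return np.sqrt(s[..., None, None] / D + k2)


def _mode_weights(g: np.ndarray, Lz: float, lmax: int):
    """Shared stable pieces: w = 1/(eps_l eps_m gamma (1 - e^{-2 gamma Lz}))
    together with e^{-gamma Lz} and e^{-2 gamma Lz}."""
    x = g * Lz
    ex = np.exp(-x)
    one_minus_e2 = -np.expm1(-2.0 * x)
    w = 1.0 / (epsilon_grid(lmax) * g * one_minus_e2)
    return w, ex


def Qhat(
    s: ArrayLike,
    geometry: CleftGeometry,
    params: TransportParams,
    q: CoefficientTable,
    p: CoefficientTable,
    config: Optional[SeriesConfig] = None,
    release: Optional[ReleaseTransform] = None,
) -> ArrayLike:
    """Constant-flux closure Q(s): uniform sink flux density in Laplace space.

    ``q`` must be the source-disk table (radius R) and ``p`` the sink-disk
    table (radius a), built with the same lmax.  ``release`` defaults to
    the exponential model with params.t0; any callable accepting real
    s > 0 (scalar or array) may be substituted.  Accepts scalar or array s.
    """
    if q.lmax != p.lmax:
        raise ValueError("q and p tables must share the same truncation order")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if not np.all(s_arr > 0):
        raise ValueError("Qhat requires real s > 0")
    if release is None:
        release = lambda ss: uhat_exponential(ss, params.t0)  # noqa: E731

    lmax = q.lmax
    g = _gamma_grid(s_arr, params.D, geometry, lmax)
    w, ex = _mode_weights(g, geometry.Lz, lmax)
    # numerator terms: q p / (eps eps gamma sinh) = q p * 2 e^{-x} * w
    num = np.sum(q.values * p.values * 2.0 * ex * w, axis=(-2, -1))
    # denominator terms: p^2 coth / (eps eps gamma) = p^2 (1 + e^{-2x}) * w
    den = np.sum(p.values**2 * (1.0 + ex * ex) * w, axis=(-2, -1))
    if not np.all(den > 0):
        raise RuntimeError(
            "constant-flux denominator not positive; series evaluation is inconsistent"
        )
    out = np.asarray(release(s_arr), dtype=float) * num / den
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out[0])
    return out


def Jhat(
    s: ArrayLike,
    geometry: CleftGeometry,
    params: TransportParams,
    q: CoefficientTable,
    p: CoefficientTable,
    config: Optional[SeriesConfig] = None,
    release: Optional[ReleaseTransform] = None,
) -> ArrayLike:
    """Transform of the total sink flux: J^(s) = pi a^2 Q(s)."""
    return np.pi * geometry.a**2 * Qhat(s, geometry, params, q, p, config, release)


@dataclass(frozen=True)
class LaplaceState:
    """Series coefficients of C^(r, s) at one abscissa s.

    To avoid overflow, ``alpha`` is stored as the scaled product
    alpha_lm e^{gamma Lz} (finite for all gamma); ``beta`` is stored
    unscaled (it decays with gamma).  The unscaled alpha_lm, when needed,
    is alpha * e^{-gamma Lz}.
    """

    s: float
    gamma: np.ndarray  # gamma_lm(s)
    alpha: np.ndarray  # alpha_lm e^{gamma Lz}
    beta: np.ndarray  # beta_lm
    uhat: float
    Q: float


def solve_series_coefficients(
    s: float,
    geometry: CleftGeometry,
    params: TransportParams,
    q: CoefficientTable,
    p: CoefficientTable,
    Qvalue: float,
    release: Optional[ReleaseTransform] = None,
) -> LaplaceState:
    """Solve for the mode coefficients alpha_lm(s), beta_lm(s).

    In stable (decaying-exponential) form,

        alpha e^{gamma Lz} = [-q u^ e^{-x} + p Q] / (D gamma (1 - e^{-2x}))
        beta               = [-q u^ + p Q e^{-x}] / (D gamma (1 - e^{-2x}))

    with x = gamma Lz.  These satisfy the release identity
    D gamma (alpha - beta) = u^ q and the sink identity
    D gamma (alpha e^{x} - beta e^{-x}) = Q p exactly.
    """
    if not s > 0:
        raise ValueError("solve_series_coefficients requires s > 0")
    if release is None:
        release = lambda ss: uhat_exponential(ss, params.t0)  # noqa: E731
    uh = float(release(s))
    lmax = q.lmax
    g = _gamma_grid(np.atleast_1d(s), params.D, geometry, lmax)[0]
    x = g * geometry.Lz
    ex = np.exp(-x)
    denom = params.D * g * (-np.expm1(-2.0 * x))
    alpha_scaled = (-q.values * uh * ex + p.values * Qvalue) / denom
    beta = (-q.values * uh + p.values * Qvalue * ex) / denom
    return LaplaceState(
        s=float(s), gamma=g, alpha=alpha_scaled, beta=beta, uhat=uh, Q=float(Qvalue)
    )


def _mode_profile(state: LaplaceState, z: float, Lz: float) -> np.ndarray:
    """C_lm(z) = alpha e^{gamma z} + beta e^{-gamma z}, evaluated stably."""
    g = state.gamma
    return state.alpha * np.exp(g * (z - Lz)) + state.beta * np.exp(-g * z)


def concentration_hat(
    x: float,
    y: float,
    z: float,
    s: float,
    state: LaplaceState,
    geometry: CleftGeometry,
) -> float:
    """Truncated-series value of the concentration transform C^(x,y,z,s)."""
    if not 0.0 <= z <= geometry.Lz:
        raise ValueError(f"z={z} outside the cleft [0, {geometry.Lz}]")
    lmax = state.gamma.shape[0] - 1
    prof = _mode_profile(state, z, geometry.Lz)
    ls = np.arange(lmax + 1)
    cx = np.cos(2.0 * np.pi * ls * x / geometry.Lx)
    cy = np.cos(2.0 * np.pi * ls * y / geometry.Ly)
    return float(cx @ prof @ cy)


def disk_average_concentration_hat(
    z: float,
    state: LaplaceState,
    geometry: CleftGeometry,
    disk: CoefficientTable,
) -> float:
    """Average of C^ over the centred disk described by ``disk``, at height z.

    Uses the identity (pi r^2)^{-1} Int_{rho<r} cos cos dA =
    (Lx Ly / (4 pi r^2)) * c_lm / (eps_l eps_m), so the average is a
    weighted sum of mode profiles with the disk's own table.
    """
    if not 0.0 <= z <= geometry.Lz:
        raise ValueError(f"z={z} outside the cleft [0, {geometry.Lz}]")
    prof = _mode_profile(state, z, geometry.Lz)
    weights = disk.values / epsilon_grid(disk.lmax)
    pref = geometry.cell_area / (4.0 * np.pi * disk.radius**2)
    return float(pref * np.sum(prof * weights))


def release_bc_residual(state: LaplaceState, params: TransportParams,
                        q: CoefficientTable, geometry: CleftGeometry) -> np.ndarray:
    """Residual of the release identity D gamma (alpha - beta) = u^ q."""
    g = state.gamma
    ex = np.exp(-g * geometry.Lz)
    lhs = params.D * g * (state.alpha * ex - state.beta)
    return lhs - state.uhat * q.values


def sink_bc_residual(state: LaplaceState, params: TransportParams,
                     p: CoefficientTable, geometry: CleftGeometry) -> np.ndarray:
    """Residual of the sink identity D gamma (alpha e^x - beta e^-x) = Q p."""
    g = state.gamma
    ex = np.exp(-g * geometry.Lz)
    lhs = params.D * g * (state.alpha - state.beta * ex)
    return lhs - state.Q * p.values
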