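"""Numerical inverse Laplace transform by the Gaver-Stehfest algorithm.

The Stehfest method approximates f(t) by a weighted sum of transform values
at real abscissas s_k = k ln2 / t:

    f(t) ~= (ln2/t) * sum_{k=1}^{N} V_k F(k ln2 / t)

with signed weights V_k built from factorials.  It is exact (up to
round-off) for F(s) = s^{-n}, n = 1..N/2, and very accurate for smooth,
non-oscillatory originals such as the cleft response function.  The weights
alternate in sign and grow combinatorially, so N is capped in double
precision; N = 14 is the default sweet spot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Callable

import numpy as np

__all__ = ["StehfestWeights", "stehfest_weights", "invert_laplace"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class StehfestWeights:
    """Stehfest weights V_1..V_N for an even term count N."""

    N: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != self.N:
            raise ValueError("weight vector length inconsistent with N")


@lru_cache(maxsize=16)
def _weights_tuple(N: int) -> tuple:
    half = N // 2
    fact = math.factorial
    out = []
    for k in range(1, N + 1):
        acc = Fraction(0)
        for j in range((k + 1) // 2, min(k, half) + 1):
            acc += Fraction(
                j**half * fact(2 * j),
                fact(half - j) * fact(j) * fact(j - 1) * fact(k - j) * fact(2 * j - k),
            )
        sign = -1 if (k + half) % 2 else 1
        out.append(sign * acc)
    return tuple(float(v) for v in out)


def stehfest_weights(N: int) -> StehfestWeights:
    """Compute the N Stehfest weights exactly (rational arithmetic).

    N must be even; values above 20 are allowed but emit a precision
    warning because weight cancellation then exceeds what double-precision
    transform evaluations can support.
    """
    if N < 2 or N % 2:
        raise ValueError(f"Stehfest term count must be a positive even integer, got {N}")
    if N > 20:
        warnings.warn(
            f"Stehfest N={N} exceeds the double-precision sweet spot (<=20); "
            "expect severe cancellation",
            stacklevel=2,
        )
    return StehfestWeights(N=N, weights=np.array(_weights_tuple(N)))


def invert_laplace(F: Callable[[float], float], t: float, N: int = 14) -> float:
    """Invert the Laplace transform ``F`` at time ``t`` (Stehfest).

    ``F`` must be defined and finite at the real abscissas k ln2/t,
    k = 1..N.  ``t`` must be strictly positive.
    """
    if not t > 0:
        raise ValueError(f"Stehfest inversion requires t > 0, got {t!r}")
    w = stehfest_weights(N).weights
    s = np.arange(1, N + 1) * (LN2 / t)
    vals = np.array([F(sk) for sk in s], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = s[~np.isfinite(vals)]
        raise ValueError(f"transform evaluator returned non-finite values at s={bad}")
    return (LN2 / t) * float(w @ vals)


def invert_laplace_grid(
    F_vectorized: Callable[[np.ndarray], np.ndarray],
    times: np.ndarray,
    N: int = 14,
) -> np.ndarray:
    """Stehfest inversion on a whole time grid with one batched transform call.

    ``F_vectorized`` maps an array of abscissas to an array of transform
    values; all N * len(times) evaluations are performed in a single call,
    which is what makes dense response curves cheap.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or not np.all(times > 0):
        raise ValueError("times must be a 1-D array of strictly positive values")
    w = stehfest_weights(N).weights
    k = np.arange(1, N + 1)
    s = (LN2 / times)[:, None] * k[None, :]  # (nt, N)
    vals = np.asarray(F_vectorized(s.ravel()), dtype=float).reshape(s.shape)
    if not np.all(np.isfinite(vals)):
        raise ValueError("transform evaluator returned non-finite values")
    return (LN2 / times) * (vals @ w)
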