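"""Numerically stable special-function helpers used by the Laplace engine.

Everything here operates on non-negative real arguments and is vectorized.
"""
from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["ein", "ein_deficit", "guarded_exp"]

_EXP_MAX = 700.0  # log of largest double


def ein(x):
    """Complementary exponential integral Ein(x) = ∫_0^x (1 - e^(-t))/t dt, x >= 0.

    Entire function; Ein(x) = γ + log(x) + E1(x) for x > 0.  A truncated
    power series is used below x = 1 where the log/E1 form loses digits.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("ein requires x >= 0")
    out = np.empty_like(x)
    small = x < 1.0
    xs = x[small]
    # sum_{k>=1} (-1)^(k+1) x^k / (k * k!)
    acc = np.zeros_like(xs)
    term = np.ones_like(xs)
    for k in range(1, 25):
        term = term * (-xs) / k
        acc -= term / k
    out[small] = acc
    xl = x[~small]
    out[~small] = np.euler_gamma + np.log(xl) + special.exp1(xl)
    return out[0] if scalar else out


def ein_deficit(x):
    """x - Ein(x), computed without cancellation for small x.

    This is the quantity entering log Z0 when the mean synaptic drift is
    absorbed into the effective input: it vanishes quadratically at 0
    (x^2/4 - x^3/18 + ...), so the naive difference loses all digits in the
    diffusion limit of vanishing kick amplitude.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = x < 1.0
    xs = x[small]
    # x - Ein(x) = sum_{k>=2} (-1)^k x^k/(k*k!)
    acc = np.zeros_like(xs)
    term = -xs  # (-x)^1/1!
    for k in range(2, 26):
        term = term * (-xs) / k
        acc += term / k
    out[small] = acc
    xl = x[~small]
    out[~small] = xl - (np.euler_gamma + np.log(xl) + special.exp1(xl))
    return out[0] if scalar else out


def guarded_exp(e):
    """exp(e) with overflow clipped to exp(700) and deep underflow set to 0."""
    e = np.asarray(e, dtype=float)
    return np.where(e > -_EXP_MAX, np.exp(np.minimum(e, _EXP_MAX)), 0.0)
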