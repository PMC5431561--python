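"""Synaptic-weight (PSP amplitude) distributions and their Laplace kernels.

Four inhibitory amplitude laws are supported — delta (DD), exponential (ED),
uniform (UD) and upper-truncated Gaussian (TGD) — plus the excitatory
exponential law.  Each distribution provides

* closed-form moments (mean, variance, skewness),
* a seeded sampler,
* the Laplace kernel Q(s)/R = E[(e^{sa} - 1)/s], whose integral from 0 to s
  enters the generating function log Z0 of the sub-threshold voltage,
* the kernel antiderivative psi(s) = ∫_0^s Q(c)/R dc in closed form where one
  exists (DD/ED/UD) and by amplitude-space quadrature for the TGD.

All amplitudes are in mV; the Laplace variable s is in 1/mV.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from ._special import ein, ein_deficit

__all__ = [
    "AmplitudeDistribution",
    "DeltaDist",
    "ExponentialDist",
    "UniformDist",
    "TruncGaussDist",
    "laplace_kernel_Q",
    "parse_dist",
]

# below |s * scale| = this, kernels switch to their Taylor forms; the series
# truncation error (~m4 (s*scale)^3/24) and the cancellation error of the
# direct form (~eps/(s*scale)) cross near 1e-3
_SMALL = 1e-3

from functools import lru_cache


@lru_cache(maxsize=32)
def _tg_nodes(a_p: float, sigma_G: float, n: int):
    """Gauss-Legendre nodes/weights for averaging over an upper-truncated
    Gaussian amplitude law: the density is analytic on [a_p - 14 sigma, 0],
    so fixed-order GL converges to machine precision; the weights are
    renormalized so that E[1] = 1 exactly."""
    x, w = np.polynomial.legendre.leggauss(n)
    lo = a_p - 14.0 * sigma_G
    a = lo + (x + 1.0) * 0.5 * (0.0 - lo)
    phi = np.exp(-0.5 * ((a - a_p) / sigma_G) ** 2)
    wts = w * phi
    wts /= wts.sum()
    return a, wts


class AmplitudeDistribution:
    """Interface shared by all amplitude laws."""

    @property
    def mean(self) -> float:
        raise NotImplementedError

    @property
    def variance(self) -> float:
        raise NotImplementedError

    @property
    def skewness(self) -> float:
        raise NotImplementedError

    def moments(self) -> tuple[float, float, float]:
        """(mean, variance, skewness)."""
        return (self.mean, self.variance, self.skewness)

    def raw_moments(self) -> tuple[float, float, float]:
        """First three raw moments E[a], E[a^2], E[a^3]."""
        m, v, g = self.moments()
        m2 = v + m * m
        m3 = g * v**1.5 + 3 * m * m2 - 2 * m**3
        return (m, m2, m3)

    @property
    def abs_mean(self) -> float:
        return abs(self.mean)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def pdf(self, a):
        raise NotImplementedError

    def kernel(self, s):
        """Q(s)/R = E[(e^{sa} - 1)/s]; tends to E[a] as s -> 0."""
        raise NotImplementedError

    def kernel_integral(self, s):
        """psi(s) = ∫_0^s Q(c)/R dc = E[-Ein(-a s)] (for support a <= 0)."""
        raise NotImplementedError

    def _kernel_series(self, s):
        m1, m2, m3 = self.raw_moments()
        return m1 + s * m2 / 2 + s * s * m3 / 6

    def _kernel_integral_series(self, s):
        m1, m2, m3 = self.raw_moments()
        return m1 * s + m2 * s * s / 4 + m3 * s**3 / 18

    def kernel_centered(self, s):
        """Q(s)/R - E[a]; the series branch of ``kernel`` makes the
        subtraction exact for small s."""
        return self.kernel(s) - self.mean

    def kernel_integral_centered(self, s):
        """psi(s) - E[a] s; subclasses override where a cancellation-free
        closed form exists (needed deep in the diffusion limit)."""
        return self.kernel_integral(s) - self.mean * np.asarray(s, dtype=float)

    def spec_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.spec_string()!r})"


@dataclass(frozen=True)
class DeltaDist(AmplitudeDistribution):
    """All kicks share one fixed amplitude a_i (< 0 for inhibition)."""

    a_i: float

    def __post_init__(self):
        if self.a_i == 0:
            raise ValueError("delta amplitude must be nonzero")

    @property
    def mean(self):
        return self.a_i

    @property
    def variance(self):
        return 0.0

    @property
    def skewness(self):
        return 0.0

    def sample(self, n, rng):
        return np.full(n, self.a_i)

    def kernel(self, s):
        s = np.asarray(s, dtype=float)
        small = np.abs(s * self.a_i) < _SMALL
        safe = np.where(small, 1.0, s)
        val = np.expm1(safe * self.a_i) / safe
        return np.where(small, self._kernel_series(s), val)

    def kernel_integral(self, s):
        # ∫_0^s (e^{a c}-1)/c dc = -Ein(-a s), requires a < 0
        if self.a_i >= 0:
            raise ValueError("closed-form kernel integral requires a_i < 0")
        return -ein(-self.a_i * np.asarray(s, dtype=float))

    def kernel_integral_centered(self, s):
        """psi(s) - mean*s, stable in the small-amplitude (diffusion) limit."""
        return ein_deficit(-self.a_i * np.asarray(s, dtype=float))

    def spec_string(self):
        return f"delta:a={self.a_i:g}"


@dataclass(frozen=True)
class ExponentialDist(AmplitudeDistribution):
    """Exponentially distributed magnitudes with mean a_scale.

    ``sign=-1`` gives the inhibitory law on (-inf, 0]; ``sign=+1`` the
    excitatory law on [0, inf), whose kernel has a pole at s = 1/a_scale.
    """

    a_scale: float
    sign: int = -1

    def __post_init__(self):
        if self.a_scale <= 0:
            raise ValueError("a_scale must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")

    @property
    def mean(self):
        return self.sign * self.a_scale

    @property
    def variance(self):
        return self.a_scale**2

    @property
    def skewness(self):
        return 2.0 * self.sign

    def sample(self, n, rng):
        return self.sign * rng.exponential(self.a_scale, n)

    def pdf(self, a):
        a = np.asarray(a, dtype=float)
        x = self.sign * a
        return np.where(x >= 0, np.exp(-x / self.a_scale) / self.a_scale, 0.0)

    def kernel(self, s):
        a = self.mean
        s = np.asarray(s, dtype=float)
        if self.sign > 0 and np.any(s * self.a_scale >= 1.0):
            raise ValueError("excitatory exponential kernel evaluated at/beyond its pole s = 1/a_e")
        return a / (1.0 - s * a)

    def kernel_integral(self, s):
        a = self.mean
        s = np.asarray(s, dtype=float)
        return -np.log1p(-s * a)

    def spec_string(self):
        return f"exp:a={self.mean:g}"


@dataclass(frozen=True)
class UniformDist(AmplitudeDistribution):
    """Uniform on [l1, l2] with l1 < l2 <= 0."""

    l1: float
    l2: float

    def __post_init__(self):
        if not (self.l1 < self.l2 <= 0):
            raise ValueError("require l1 < l2 <= 0")

    @property
    def mean(self):
        return 0.5 * (self.l1 + self.l2)

    @property
    def variance(self):
        return (self.l2 - self.l1) ** 2 / 12.0

    @property
    def skewness(self):
        return 0.0

    def sample(self, n, rng):
        return rng.uniform(self.l1, self.l2, n)

    def pdf(self, a):
        a = np.asarray(a, dtype=float)
        inside = (a >= self.l1) & (a <= self.l2)
        return np.where(inside, 1.0 / (self.l2 - self.l1), 0.0)

    def kernel(self, s):
        s = np.asarray(s, dtype=float)
        width = self.l2 - self.l1
        scale = max(abs(self.l1), abs(self.l2))
        small = np.abs(s * scale) < _SMALL
        safe = np.where(small, 1.0, s)
        val = -((np.exp(self.l1 * safe) - np.exp(self.l2 * safe)) / safe**2 + width / safe) / width
        return np.where(small, self._kernel_series(s), val)

    @staticmethod
    def _g(l, s):
        # ∫_0^s (e^{lc} - 1 - lc)/c^2 dc for l <= 0
        if l == 0:
            return np.zeros_like(s)
        x = -l * s  # >= 0
        small = x < _SMALL
        safe_s = np.where(small, 1.0, s)
        main = -(np.expm1(l * safe_s) - l * safe_s) / safe_s - l * ein(x)
        series = l * l * s / 2 + l**3 * s * s / 12 + l**4 * s**3 / 72
        return np.where(small, series, main)

    def kernel_integral(self, s):
        s = np.asarray(s, dtype=float)
        width = self.l2 - self.l1
        return -(self._g(self.l1, s) - self._g(self.l2, s)) / width

    def spec_string(self):
        return f"uniform:l1={self.l1:g},l2={self.l2:g}"


@dataclass(frozen=True)
class TruncGaussDist(AmplitudeDistribution):
    """Gaussian with peak a_p (<= 0) and width sigma_G, truncated to (-inf, 0].

    Moments follow the standard upper-truncated-normal formulas with
    beta = -a_p/sigma_G and lambda = phi(beta)/Phi(beta); the third moment
    uses the recursion E[Z^n | Z<=beta] = (n-1)E[Z^(n-2)] - beta^(n-1)*lambda.
    """

    a_p: float
    sigma_G: float
    _n_nodes: int = 400

    def __post_init__(self):
        if self.sigma_G <= 0:
            raise ValueError("sigma_G must be positive")
        if self.a_p > 0:
            raise ValueError("peak must satisfy a_p <= 0 for an inhibitory law")

    @property
    def _beta(self):
        return -self.a_p / self.sigma_G

    @property
    def _lam(self):
        b = self._beta
        # phi(b)/Phi(b), stable for any b >= 0 (b < 0 never occurs here)
        return np.exp(-0.5 * b * b) / (np.sqrt(2 * np.pi) * special.ndtr(b))

    def _z_moments(self):
        b, lam = self._beta, self._lam
        z1 = -lam
        z2 = 1.0 - b * lam
        z3 = 2.0 * z1 - b * b * lam
        return z1, z2, z3

    @property
    def mean(self):
        return self.a_p + self.sigma_G * self._z_moments()[0]

    @property
    def variance(self):
        z1, z2, _ = self._z_moments()
        return self.sigma_G**2 * (z2 - z1 * z1)

    @property
    def skewness(self):
        z1, z2, z3 = self._z_moments()
        mu2 = z2 - z1 * z1
        mu3 = z3 - 3 * z2 * z1 + 2 * z1**3
        return mu3 / mu2**1.5

    def sample(self, n, rng):
        z = stats.truncnorm.rvs(-np.inf, self._beta, size=n, random_state=rng)
        return self.a_p + self.sigma_G * z

    def pdf(self, a):
        a = np.asarray(a, dtype=float)
        phi = np.exp(-0.5 * ((a - self.a_p) / self.sigma_G) ** 2) / (
            np.sqrt(2 * np.pi) * self.sigma_G
        )
        return np.where(a <= 0, phi / special.ndtr(self._beta), 0.0)

    def kernel(self, s):
        s = np.asarray(s, dtype=float)
        sg, ap = self.sigma_G, self.a_p
        small = np.abs(s) * max(abs(ap), sg) < _SMALL
        safe = np.where(small, 1.0, s)
        y = (safe * sg * sg + ap) / (np.sqrt(2.0) * sg)
        # exact overflow-free rewriting of ½erfc(y)·e^{s(sσ²+2a_p)/2}:
        # the exponent equals y² - a_p²/(2σ²), so the product is
        # ½·erfcx(y)·e^{-a_p²/(2σ²)}
        h = 0.5 * special.erfcx(y) * np.exp(-0.5 * (ap / sg) ** 2) / special.ndtr(self._beta)
        val = -(1.0 - h) / safe
        return np.where(small, self._kernel_series(s), val)

    def kernel_eq46(self, s):
        """Literal evaluation of the flux-kernel expression (overflows for
        large s*sigma_G; kept for cross-checking the erfcx form)."""
        s = np.asarray(s, dtype=float)
        sg, ap = self.sigma_G, self.a_p
        y = (s * sg * sg + ap) / (np.sqrt(2.0) * sg)
        term = 0.5 * special.erfc(y) * np.exp(s * (s * sg * sg + 2 * ap) / 2)
        return -(1.0 - term / special.ndtr(self._beta)) / s

    def kernel_asymptotic(self, s):
        """Large-argument branch using erfc(y) ≈ e^{-y²}/(√π y), valid for
        s, sigma_G > 1; ½erfc(y)e^{...} becomes σ e^{-a_p²/2σ²}/(√(2π)(σ²s+a_p))."""
        s = np.asarray(s, dtype=float)
        sg, ap = self.sigma_G, self.a_p
        h = sg * np.exp(-0.5 * (ap / sg) ** 2) / (
            np.sqrt(2 * np.pi) * (sg * sg * s + ap) * special.ndtr(self._beta)
        )
        return -(1.0 - h) / s

    def _nodes(self):
        return _tg_nodes(self.a_p, self.sigma_G, self._n_nodes)

    def _node_average(self, s, fn):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        a, w = self._nodes()
        out = np.empty_like(s)
        for lo in range(0, s.size, 4096):  # bound transient memory
            chunk = s[lo : lo + 4096]
            x = np.clip(-a[None, :] * chunk[:, None], 0.0, None)
            out[lo : lo + 4096] = (fn(x.ravel()).reshape(x.shape) * w[None, :]).sum(axis=1)
        return out

    def kernel_integral(self, s):
        # psi(s) = E[-Ein(-a s)] over the amplitude law
        val = -self._node_average(s, ein)
        return val if val.size > 1 else val[0]

    def kernel_integral_centered(self, s):
        # psi(s) - E[a] s = E[(-a s) - Ein(-a s)], cancellation-free
        val = self._node_average(s, ein_deficit)
        return val if val.size > 1 else val[0]

    def spec_string(self):
        return f"tgauss:ap={self.a_p:g},sg={self.sigma_G:g}"


def laplace_kernel_Q(dist: AmplitudeDistribution, rate_per_ms: float, s):
    """Laplace kernel Q(s) of the synaptic flux, J~ = P~ * Q(s).

    ``rate_per_ms`` is the Poisson arrival rate in 1/ms; Q(s)/R -> E[a] as
    s -> 0 for every amplitude law.
    """
    return rate_per_ms * dist.kernel(s)


def parse_dist(text: str) -> AmplitudeDistribution:
    """Parse a distribution spec string.

    Examples: ``delta:a=-1``, ``exp:a=-1``, ``uniform:l1=-2,l2=0``,
    ``tgauss:ap=-0.7766,sg=0.7766``.
    """
    name, _, rest = text.partition(":")
    kv = {}
    if rest:
        for item in rest.split(","):
            k, _, v = item.partition("=")
            kv[k.strip()] = float(v)
    name = name.strip().lower()
    try:
        if name in ("delta", "dd"):
            return DeltaDist(a_i=kv["a"] if "a" in kv else kv["a_i"])
        if name in ("exp", "ed"):
            a = kv["a"]
            return ExponentialDist(a_scale=abs(a), sign=-1 if a < 0 else 1)
        if name in ("uniform", "ud"):
            return UniformDist(l1=kv["l1"], l2=kv["l2"])
        if name in ("tgauss", "tgd"):
            return TruncGaussDist(a_p=kv["ap"], sigma_G=kv["sg"])
    except KeyError as exc:
        raise ValueError(f"missing parameter {exc} in distribution spec {text!r}") from exc
    raise ValueError(f"unknown distribution family {name!r}")
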