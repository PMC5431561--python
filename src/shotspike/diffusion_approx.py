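"""Gaussian diffusion-approximation baseline.

In the diffusion approximation the synaptic input is replaced by Gaussian
white noise with matched mean mu_T and intensity sigma^2; the amplitude
distribution is irrelevant by construction.  With the reduced boundaries
y_th = (v_th - mu_T)/sigma and y_r = (v_re - mu_T)/sigma,

    1/r0  = tau sqrt(pi) ∫_{y_r}^{y_th} e^{x^2} (1 + erf x) dx
    CV^2  = 2 pi (r0 tau)^2 ∫_{y_r}^{y_th} dx e^{x^2}
            ∫_{-infty}^{x} dy e^{y^2} (1 + erf y)^2.

Both integrands are evaluated through the scaled complementary error
function: e^{x^2}(1 + erf x) = erfcx(-x), which never overflows, and the
inner CV integral is recast with y = x - t so that the product
e^{x^2 - y^2} = e^{2xt - t^2} stays bounded for the sub-threshold
(x <= y_th <~ few) regimes of interest.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate, special

from .core_model import NeuronParams

__all__ = ["da_rate", "da_cv", "reduced_boundaries"]


def reduced_boundaries(mu_T: float, sigma2: float, neuron: NeuronParams):
    """(y_r, y_th): reset and threshold in noise units."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    sigma = np.sqrt(sigma2)
    return (neuron.v_re - mu_T) / sigma, (neuron.v_th - mu_T) / sigma


def da_rate(mu_T: float, sigma2: float, neuron: NeuronParams = NeuronParams()) -> float:
    """Diffusion-approximation firing rate in Hz."""
    y_r, y_th = reduced_boundaries(mu_T, sigma2, neuron)
    val, _ = integrate.quad(lambda x: special.erfcx(-x), y_r, y_th, limit=200)
    return 1000.0 / (neuron.tau * np.sqrt(np.pi) * val)


def _inner(x: float) -> float:
    """e^{x^2} ∫_{-inf}^x e^{y^2}(1+erf y)^2 dy, via y = x - t."""

    def f(t):
        return special.erfcx(t - x) ** 2 * np.exp((2.0 * x - t) * t)

    val, _ = integrate.quad(f, 0.0, np.inf, limit=200)
    return val


def da_cv(mu_T: float, sigma2: float, neuron: NeuronParams = NeuronParams()) -> float:
    """Diffusion-approximation coefficient of variation."""
    y_r, y_th = reduced_boundaries(mu_T, sigma2, neuron)
    if y_th > 25.0:
        raise ValueError("configuration too deeply sub-threshold for the CV integral")
    r0_ms = da_rate(mu_T, sigma2, neuron) / 1000.0
    val, _ = integrate.quad(_inner, y_r, y_th, limit=200)
    cv2 = 2.0 * np.pi * (r0_ms * neuron.tau) ** 2 * val
    return float(np.sqrt(cv2))
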