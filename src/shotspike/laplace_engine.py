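"""The Laplace-space function bundle behind all exact firing statistics.

For a neuron configuration (constants, excitatory drive, inhibitory stream)
this module assembles the generating function of the free sub-threshold
voltage,

    Z0(s) = H_e(s) * exp(mu0*s + tau * ∫_0^s Q_i(c) dc),

together with the boundary function F(s), the ratios A(s) = e^{s v_re}/Z0 and
B(s) = F(s)/Z0, and the upper integration limit x_bar at which 1/Z0 vanishes
(1/a_e for exponential excitatory kicks, +inf for a supra-threshold DC drive).

All work is done on log Z0 — Z0 itself grows like e^{mu0 s} and would
overflow — and log Z0 is assembled in the *centered* form

    log Z0(s) = mu_T * s + tau*R_i*(psi(s) - <a_i> s) + (excitatory part),

which remains accurate arbitrarily deep in the diffusion (small-kick) limit
where mu0 and tau*R_i*<a_i> individually diverge.

Sign conventions (fixed by requiring a positive rate from the stationary
solution and validated against event-driven simulation):

    F(s) = e^{s v_th} - e^{s v_re}            (DC drive)
    F(s) = e^{s v_th}/(1 - s a_e) - e^{s v_re} (exponential excitation)

so that 1/(tau*r0) = ∫_0^x_bar F(c)/(c Z0(c)) dc and F(c)/c -> v_th - v_re
as c -> 0.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._special import guarded_exp
from .amplitude_distributions import DeltaDist, UniformDist
from .core_model import (
    EffectiveInput,
    ExcitatoryDrive,
    InhibitoryInput,
    NeuronParams,
    effective_input,
)

__all__ = ["Validity", "LaplaceFunctions", "build", "evaluate_integrand_rate"]


class Validity(enum.Enum):
    OK = "ok"
    SILENT_DC = "silent_dc"  # DC-only drive at/below threshold: rate is 0
    UNSUPPORTED_SUPRA_DC_WITH_SHOT = "unsupported_supra_dc_with_shot"


@dataclass
class LaplaceFunctions:
    neuron: NeuronParams
    drive: ExcitatoryDrive
    inh: InhibitoryInput
    eff: EffectiveInput
    x_bar: float
    validity: Validity
    C0: Optional[float] = None  # closed-form normalization (delta/uniform laws)

    # -- generating function ------------------------------------------------
    def log_Z0(self, s):
        s = np.asarray(s, dtype=float)
        tau = self.neuron.tau
        out = self.eff.mu_T * s
        Ri = self.inh.R_i_per_ms
        if Ri > 0:
            out = out + tau * Ri * self.inh.dist.kernel_integral_centered(s)
        if self.drive.kind == "exp_shot" and self.drive.R_e > 0:
            ae, Re = self.drive.a_e, self.drive.R_e_per_ms
            out = out + tau * Re * (-np.log1p(-s * ae) - s * ae)
        return out

    def dlog_Z0(self, s):
        s = np.asarray(s, dtype=float)
        tau = self.neuron.tau
        out = np.full_like(s, self.eff.mu_T)
        Ri = self.inh.R_i_per_ms
        if Ri > 0:
            out = out + tau * Ri * self.inh.dist.kernel_centered(s)
        if self.drive.kind == "exp_shot" and self.drive.R_e > 0:
            ae, Re = self.drive.a_e, self.drive.R_e_per_ms
            out = out + tau * Re * (ae / (1.0 - s * ae) - ae)
        return out

    # -- boundary functions ---------------------------------------------------
    def S_e(self, s):
        """Excitatory boundary term; 0 for a pure DC drive."""
        s = np.asarray(s, dtype=float)
        if self.drive.kind != "exp_shot":
            return np.zeros_like(s)
        ae = self.drive.a_e
        return ae * np.exp(s * self.neuron.v_th) / (1.0 - s * ae)

    def F(self, s):
        s = np.asarray(s, dtype=float)
        vth, vre = self.neuron.v_th, self.neuron.v_re
        if self.drive.kind == "exp_shot":
            return np.exp(s * vth) / (1.0 - s * self.drive.a_e) - np.exp(s * vre)
        return np.exp(s * vth) - np.exp(s * vre)

    def A(self, s):
        s = np.asarray(s, dtype=float)
        return guarded_exp(s * self.neuron.v_re - self.log_Z0(s))

    def B(self, s):
        """F(s)/Z0(s), evaluated in log space (stable for large s)."""
        s = np.asarray(s, dtype=float)
        lz = self.log_Z0(s)
        vth, vre = self.neuron.v_th, self.neuron.v_re
        top = guarded_exp(s * vth - lz)
        if self.drive.kind == "exp_shot":
            top = top / (1.0 - s * self.drive.a_e)
        return top - guarded_exp(s * vre - lz)

    def dA(self, s):
        """A'(s) = A(s) (v_re - dlog Z0)."""
        return self.A(s) * (self.neuron.v_re - self.dlog_Z0(s))

    def dB(self, s):
        """B'(s), expanded termwise in log space."""
        s = np.asarray(s, dtype=float)
        lz = self.log_Z0(s)
        dlz = self.dlog_Z0(s)
        vth, vre = self.neuron.v_th, self.neuron.v_re
        eth = guarded_exp(s * vth - lz)
        ere = guarded_exp(s * vre - lz)
        if self.drive.kind == "exp_shot":
            ae = self.drive.a_e
            om = 1.0 - s * ae
            return eth * (vth / om + ae / om**2 - dlz / om) - ere * (vre - dlz)
        return eth * (vth - dlz) - ere * (vre - dlz)


def _closed_form_C0(neuron: NeuronParams, inh: InhibitoryInput) -> Optional[float]:
    tau_Ri = neuron.tau * inh.R_i_per_ms
    d = inh.dist
    if isinstance(d, DeltaDist):
        return float(np.exp(tau_Ri * (np.euler_gamma + np.log(abs(d.a_i)))))
    if isinstance(d, UniformDist):
        l1, l2 = d.l1, d.l2

        def piece(l):
            return l * (1.0 - np.euler_gamma - np.log(abs(l))) if l != 0 else 0.0

        return float(np.exp(tau_Ri / (l2 - l1) * (piece(l1) - piece(l2))))
    return None


def build(
    neuron: NeuronParams, drive: ExcitatoryDrive, inh: InhibitoryInput
) -> LaplaceFunctions:
    """Assemble the Laplace-function bundle for a configuration."""
    eff = effective_input(drive, inh, neuron)
    if drive.kind == "exp_shot" and drive.R_e > 0:
        validity = (
            Validity.UNSUPPORTED_SUPRA_DC_WITH_SHOT
            if drive.mu0 > neuron.v_th
            else Validity.OK
        )
        x_bar = 1.0 / drive.a_e
    else:
        validity = Validity.OK if drive.mu0 > neuron.v_th else Validity.SILENT_DC
        x_bar = np.inf
    return LaplaceFunctions(
        neuron=neuron,
        drive=drive,
        inh=inh,
        eff=eff,
        x_bar=x_bar,
        validity=validity,
        C0=_closed_form_C0(neuron, inh),
    )


def evaluate_integrand_rate(lf: LaplaceFunctions, c):
    """Integrand F(c)/(c Z0(c)) of the stationary-rate formula.

    Tends to v_th - v_re as c -> 0.  For a DC-only drive at or below
    threshold the integrand grows without bound at large c (the neuron is
    silent); a ValueError flags that divergence.
    """
    if lf.validity is Validity.SILENT_DC:
        raise ValueError("rate integrand diverges: DC-only drive at or below threshold")
    c = np.asarray(c, dtype=float)
    small = np.abs(c) < 1e-12
    safe = np.where(small, 1.0, c)
    val = lf.B(safe) / safe
    limit = lf.neuron.v_th - lf.neuron.v_re
    return np.where(small, limit, val)
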