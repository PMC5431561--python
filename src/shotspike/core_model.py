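"""Neuron constants, drive specification and the effective-input calculus.

A leaky integrate-and-fire neuron with membrane time constant tau relaxes
toward the DC input mu0 and receives instantaneous post-synaptic kicks from
Poisson streams.  Different input configurations are compared at matched
effective mean input

    mu_T = mu_e + tau * R_i * <a_i>,   mu_e = mu0 (+ tau * R_e * <a_e>)

and total noise intensity

    sigma^2 = sum_x R_x * tau * (<a_x>^2 + var[a_x]),   x in {e, i}.

Units: mV and ms internally; Poisson rates cross the public interface in Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .amplitude_distributions import AmplitudeDistribution, ExponentialDist

__all__ = [
    "NeuronParams",
    "ExcitatoryDrive",
    "InhibitoryInput",
    "EffectiveInput",
    "DriveSolution",
    "effective_input",
    "solve_drive",
    "tonic_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants: tau (ms), firing threshold and reset potential (mV)."""

    tau: float = 20.0
    v_th: float = 10.0
    v_re: float = 5.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.v_th <= self.v_re:
            raise ValueError("v_th must exceed v_re")


@dataclass(frozen=True)
class ExcitatoryDrive:
    """Excitatory input: DC current mu0, optionally plus an exponential-
    amplitude Poisson stream (kind='exp_shot') with mean EPSP a_e (mV) and
    rate R_e (Hz)."""

    kind: str = "dc"  # 'dc' | 'exp_shot'
    mu0: float = 0.0
    a_e: Optional[float] = None
    R_e: float = 0.0

    def __post_init__(self):
        if self.kind not in ("dc", "exp_shot"):
            raise ValueError("drive kind must be 'dc' or 'exp_shot'")
        if self.kind == "exp_shot":
            if self.a_e is None or self.a_e <= 0:
                raise ValueError("exp_shot drive requires a_e > 0")
            if self.R_e < 0:
                raise ValueError("R_e must be >= 0")

    @property
    def R_e_per_ms(self) -> float:
        return self.R_e / 1000.0 if self.kind == "exp_shot" else 0.0

    def epsp_dist(self) -> Optional[ExponentialDist]:
        if self.kind == "exp_shot":
            return ExponentialDist(a_scale=self.a_e, sign=1)
        return None


@dataclass(frozen=True)
class InhibitoryInput:
    """Inhibitory Poisson stream: amplitude law (support <= 0) and rate R_i (Hz)."""

    dist: AmplitudeDistribution
    R_i: float

    def __post_init__(self):
        if self.R_i < 0:
            raise ValueError("R_i must be >= 0")
        if self.R_i > 0 and self.dist.mean >= 0:
            raise ValueError("inhibitory amplitude law must have negative mean")

    @property
    def R_i_per_ms(self) -> float:
        return self.R_i / 1000.0


@dataclass(frozen=True)
class EffectiveInput:
    mu_T: float
    sigma2: float
    mu_e: float
    mu_i: float


@dataclass(frozen=True)
class DriveSolution:
    """Result of inverting (mu_T, sigma^2) for a given amplitude law."""

    drive: ExcitatoryDrive
    inhibition: InhibitoryInput
    silent: bool  # DC-only with mu0 <= v_th: the neuron can never fire


def effective_input(
    drive: ExcitatoryDrive, inh: InhibitoryInput, neuron: NeuronParams
) -> EffectiveInput:
    """Effective mean input mu_T and noise intensity sigma^2 of a configuration."""
    tau = neuron.tau
    mi, vi = inh.dist.mean, inh.dist.variance
    Ri = inh.R_i_per_ms
    mu_i = tau * Ri * mi
    sigma2 = Ri * tau * (mi * mi + vi)
    mu_e = drive.mu0
    if drive.kind == "exp_shot":
        Re = drive.R_e_per_ms
        mu_e += tau * Re * drive.a_e
        sigma2 += Re * tau * 2.0 * drive.a_e**2  # <a>^2 + var = 2 a_e^2
    return EffectiveInput(mu_T=mu_e + mu_i, sigma2=sigma2, mu_e=mu_e, mu_i=mu_i)


def solve_drive(
    mu_T: float,
    sigma2: float,
    dist: AmplitudeDistribution,
    neuron: NeuronParams = NeuronParams(),
    drive_kind: str = "dc",
    a_e: Optional[float] = None,
) -> DriveSolution:
    """Invert (mu_T, sigma^2) to concrete drive parameters.

    For DC drive the solution (R_i, mu0) is unique.  For 'exp_shot' the
    balanced convention R_e = R_i with <a_e> = <|a_i|> (unless ``a_e`` is
    given) closes the system.  Configurations whose DC drive ends up at or
    below threshold are flagged ``silent`` rather than rejected.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    tau = neuron.tau
    mi, vi = dist.mean, dist.variance
    m2i = mi * mi + vi
    if sigma2 == 0:
        drive = ExcitatoryDrive(kind="dc", mu0=mu_T)
        inh = InhibitoryInput(dist=dist, R_i=0.0)
        return DriveSolution(drive, inh, silent=mu_T <= neuron.v_th)
    if m2i <= 0:
        raise ValueError("amplitude law with zero second moment cannot carry noise")
    if drive_kind == "dc":
        Ri = sigma2 / (tau * m2i)  # per ms
        mu0 = mu_T - tau * Ri * mi
        drive = ExcitatoryDrive(kind="dc", mu0=mu0)
        inh = InhibitoryInput(dist=dist, R_i=1000.0 * Ri)
        return DriveSolution(drive, inh, silent=mu0 <= neuron.v_th)
    if drive_kind == "exp_shot":
        ae = a_e if a_e is not None else abs(mi)
        # balanced: R_e = R_i = R;  sigma2 = R tau (2 ae^2 + m2i)
        R = sigma2 / (tau * (2.0 * ae * ae + m2i))
        mu0 = mu_T - tau * R * (ae + mi)
        if mu0 > neuron.v_th:
            raise ValueError(
                "exp_shot drive with supra-threshold DC is outside the method's validity"
            )
        drive = ExcitatoryDrive(kind="exp_shot", mu0=mu0, a_e=ae, R_e=1000.0 * R)
        inh = InhibitoryInput(dist=dist, R_i=1000.0 * R)
        return DriveSolution(drive, inh, silent=False)
    raise ValueError(f"unknown drive kind {drive_kind!r}")


def tonic_rate(mu_T: float, neuron: NeuronParams = NeuronParams()) -> float:
    """Noise-free (tonic) firing rate in Hz; 0 at or below threshold."""
    if mu_T <= neuron.v_th:
        return 0.0
    return 1000.0 / (neuron.tau * np.log((mu_T - neuron.v_re) / (mu_T - neuron.v_th)))
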