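"""Heterogeneous sparse inhibitory networks: direct event-driven simulation
and the self-consistent mean field.

Each of N neurons has its own excitability mu(j) (uniform on a configured
interval) and receives input from exactly K randomly chosen presynaptic
neurons; a spike of presynaptic neuron k delivers an instantaneous kick
a_i(k) = -g(k)/K < 0 to all its targets, with one coupling magnitude g(k)
drawn per neuron at construction.

The mean field closes the loop by assuming each neuron sees a Poisson train:
with active fraction n* (taken from simulation, as in the reference
protocol) the pooled presynaptic rate onto any neuron is R_i = K n* rbar,
where rbar is the average rate of the active (top-excitability) neurons.
rbar then solves the fixed point rbar = <r0(mu; R_i(rbar))>_active, and the
population CV follows by averaging the single-neuron CV over the same set.

Validity requires asynchronous collective dynamics; no synchrony detection
is attempted beyond what the caller inspects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .amplitude_distributions import AmplitudeDistribution, DeltaDist
from .core_model import ExcitatoryDrive, InhibitoryInput, NeuronParams
from . import firing_statistics as fs
from . import laplace_engine
from .diffusion_approx import da_cv, da_rate

__all__ = [
    "NetworkConfig",
    "BuiltNetwork",
    "NetworkSimResult",
    "MeanFieldResult",
    "build_network",
    "simulate_network",
    "mean_field_rate",
]


@dataclass(frozen=True)
class NetworkConfig:
    N: int = 400
    K: int = 20
    g_dist: AmplitudeDistribution = DeltaDist(a_i=-0.8)  # law of -g(k), mV scale
    mu_min: float = 10.0
    mu_max: float = 11.0
    neuron: NeuronParams = NeuronParams()
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.K < self.N):
            raise ValueError("require 0 < K < N")
        if self.g_dist.mean >= 0:
            raise ValueError("coupling law must be inhibitory (negative mean)")

    def amplitude_dist(self) -> AmplitudeDistribution:
        """Law of the post-synaptic kick a = g/K."""
        return _scale_dist(self.g_dist, 1.0 / self.K)


def _scale_dist(dist: AmplitudeDistribution, c: float) -> AmplitudeDistribution:
    from .amplitude_distributions import ExponentialDist, TruncGaussDist, UniformDist

    if isinstance(dist, DeltaDist):
        return DeltaDist(a_i=dist.a_i * c)
    if isinstance(dist, ExponentialDist):
        return ExponentialDist(a_scale=dist.a_scale * c, sign=dist.sign)
    if isinstance(dist, UniformDist):
        return UniformDist(l1=dist.l1 * c, l2=dist.l2 * c)
    if isinstance(dist, TruncGaussDist):
        return TruncGaussDist(a_p=dist.a_p * c, sigma_G=dist.sigma_G * c)
    raise TypeError(f"cannot rescale {type(dist).__name__}")


@dataclass
class BuiltNetwork:
    cfg: NetworkConfig
    presyn: np.ndarray  # (N, K) indices of inputs to each neuron
    targets: list[np.ndarray]  # out-neighbours of each neuron
    kick: np.ndarray  # (N,) kick amplitude a_i(k) = -g(k)/K delivered by k
    mu: np.ndarray  # (N,) excitabilities


@dataclass
class NetworkSimResult:
    spike_times: np.ndarray
    spike_ids: np.ndarray
    duration: float
    rates: np.ndarray  # per neuron, Hz (nan for silent)
    cvs: np.ndarray  # per neuron (nan where < 3 spikes)
    n_star: float
    r_bar: float  # average over active neurons, Hz
    cv_bar: float


@dataclass
class MeanFieldResult:
    r_bar: float  # Hz
    cv_bar: float
    n_star: float
    Delta: float  # probability mass of the active excitability set
    mu_grid: np.ndarray
    rate_profile: np.ndarray  # r0(mu), Hz
    residual: float
    iterations: int


def build_network(cfg: NetworkConfig) -> BuiltNetwork:
    rng = np.random.default_rng(cfg.seed)
    N, K = cfg.N, cfg.K
    presyn = np.empty((N, K), dtype=np.int64)
    for j in range(N):
        pool = np.concatenate([np.arange(j), np.arange(j + 1, N)])
        presyn[j] = rng.choice(pool, size=K, replace=False)
    kick = cfg.amplitude_dist().sample(N, rng)
    mu = rng.uniform(cfg.mu_min, cfg.mu_max, N)
    # invert the presynaptic lists into per-sender target lists
    rows = np.repeat(np.arange(N), K)
    flat_pre = presyn.ravel()
    order = np.argsort(flat_pre, kind="stable")
    tgt_sorted = rows[order]
    bounds = np.searchsorted(flat_pre[order], np.arange(N + 1))
    targets = [tgt_sorted[bounds[k] : bounds[k + 1]] for k in range(N)]
    return BuiltNetwork(cfg=cfg, presyn=presyn, targets=targets, kick=kick, mu=mu)


def simulate_network(
    net: BuiltNetwork,
    n_spikes: int,
    discard: int = 0,
) -> NetworkSimResult:
    """Event-driven network simulation for a total spike budget.

    The first ``discard`` network spikes are treated as transient and
    excluded from the statistics; silent neurons (no spike in the retained
    window) are excluded from the population averages.
    """
    cfg = net.cfg
    nrn = cfg.neuron
    tau, v_th, v_re = nrn.tau, nrn.v_th, nrn.v_re
    mu = net.mu
    N = cfg.N
    v = np.full(N, v_re)
    supra = mu > v_th
    with np.errstate(divide="ignore", invalid="ignore"):
        t_next = np.where(supra & (v < v_th), tau * np.log((mu - v) / (mu - v_th)), np.inf)
    t_now = 0.0
    rec_t = np.empty(n_spikes)
    rec_id = np.empty(n_spikes, dtype=np.int64)
    total = discard + n_spikes
    count = 0
    while count < total:
        j = int(np.argmin(t_next))
        tj = t_next[j]
        if not np.isfinite(tj):
            raise RuntimeError("network went silent before reaching the spike budget")
        # advance everyone analytically to tj
        dt = tj - t_now
        v = mu + (v - mu) * np.exp(-dt / tau)
        t_now = tj
        v[j] = v_re
        tg = net.targets[j]
        v[tg] += net.kick[j]  # inhibitory: cannot cross threshold
        changed = np.concatenate(([j], tg))
        vv = v[changed]
        mm = mu[changed]
        ok = (mm > v_th) & (vv < v_th)
        with np.errstate(divide="ignore", invalid="ignore"):
            tc = np.where(ok, tau * np.log((mm - vv) / (mm - v_th)), np.inf)
        t_next[changed] = t_now + tc
        # untouched neurons keep their absolute crossing times (drift-only)
        if count >= discard:
            rec_t[count - discard] = t_now
            rec_id[count - discard] = j
        count += 1
    t0 = rec_t[0]
    duration = rec_t[-1] - t0
    rates = np.full(N, np.nan)
    cvs = np.full(N, np.nan)
    for k in range(N):
        tk = rec_t[rec_id == k]
        if len(tk) >= 2:
            rates[k] = 1000.0 * (len(tk) - 1) / (tk[-1] - tk[0])
        if len(tk) >= 3:
            d = np.diff(tk)
            cvs[k] = d.std() / d.mean()
    active = ~np.isnan(rates)
    n_star = float(active.mean())
    r_bar = float(np.nanmean(rates))
    cv_bar = float(np.nanmean(cvs))
    return NetworkSimResult(
        spike_times=rec_t,
        spike_ids=rec_id,
        duration=duration,
        rates=rates,
        cvs=cvs,
        n_star=n_star,
        r_bar=r_bar,
        cv_bar=cv_bar,
    )


def _single_rate_cv(
    mu0: float,
    R_i_hz: float,
    dist: AmplitudeDistribution,
    neuron: NeuronParams,
    want_cv: bool,
    use_da: bool,
):
    if use_da:
        m, var = dist.mean, dist.variance
        Ri = R_i_hz / 1000.0
        mu_T = mu0 + neuron.tau * Ri * m
        sigma2 = Ri * neuron.tau * (m * m + var)
        if sigma2 <= 0:
            from .core_model import tonic_rate

            return tonic_rate(mu_T, neuron), 0.0
        r = da_rate(mu_T, sigma2, neuron)
        c = da_cv(mu_T, sigma2, neuron) if want_cv else np.nan
        return r, c
    drive = ExcitatoryDrive(kind="dc", mu0=mu0)
    inh = InhibitoryInput(dist=dist, R_i=R_i_hz)
    lf = laplace_engine.build(neuron, drive, inh)
    if lf.validity is not laplace_engine.Validity.OK:
        return 0.0, np.nan
    if want_cv:
        st = fs.first_passage_moments(lf, du=0.004)
        return st.r0, st.cv
    return fs.firing_rate(lf, du=0.004), np.nan


def mean_field_rate(
    cfg: NetworkConfig,
    n_star: float,
    use_da: bool = False,
    n_mu: int = 64,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 0.5,
) -> MeanFieldResult:
    """Self-consistent population rate and CV for a given active fraction.

    The excitability average runs over the active set (the top n* fraction
    of the uniform excitability law) with Gauss-Legendre nodes; the fixed
    point rbar = <r0(mu; R_i = K n* rbar)> is solved by damped iteration,
    warm-started from the diffusion approximation of the same loop when the
    shot-noise engine is requested.
    """
    if not (0.0 < n_star <= 1.0):
        raise ValueError("n_star must be in (0, 1]")
    width = cfg.mu_max - cfg.mu_min
    mu_lo = cfg.mu_max - n_star * width
    x, w = np.polynomial.legendre.leggauss(n_mu)
    mu_grid = mu_lo + (x + 1.0) / 2.0 * (cfg.mu_max - mu_lo)
    w = w / w.sum()  # average (P(mu)/Delta weighting on the active set)
    dist = cfg.amplitude_dist()
    neuron = cfg.neuron

    def rhs(rbar_hz: float, want_cv: bool = False):
        R_i = cfg.K * n_star * rbar_hz
        vals = [
            _single_rate_cv(m, R_i, dist, neuron, want_cv, use_da) for m in mu_grid
        ]
        rates = np.array([v[0] for v in vals])
        cvs = np.array([v[1] for v in vals])
        return float(np.dot(w, rates)), rates, cvs

    # initial guess: tonic rates at zero coupling
    from .core_model import tonic_rate

    r = float(np.dot(w, [tonic_rate(m, neuron) for m in mu_grid]))
    if not use_da:
        da = mean_field_rate(cfg, n_star, use_da=True, n_mu=n_mu, tol=max(tol, 1e-6))
        r = da.r_bar
    resid = np.inf
    for it in range(1, max_iter + 1):
        target, rates, _ = rhs(r)
        resid = abs(target - r)
        r = (1.0 - damping) * r + damping * target
        if resid < tol:
            break
    else:
        raise RuntimeError(f"mean-field iteration did not converge (residual {resid:.2e})")
    _, rates, cvs = rhs(r, want_cv=True)
    cv_bar = float(np.dot(w, np.nan_to_num(cvs, nan=0.0)))
    return MeanFieldResult(
        r_bar=r,
        cv_bar=cv_bar,
        n_star=n_star,
        Delta=n_star,
        mu_grid=mu_grid,
        rate_profile=rates,
        residual=float(resid),
        iterations=it,
    )
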